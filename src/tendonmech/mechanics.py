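"""Tendon mechanical properties from the staged-loading protocol.

Elongation at each contraction level is the mean loaded length minus the
mean resting length.  Stiffness is the slope of an ordinary least-squares
line fitted to the (elongation, force) points across the three levels
(35/55/75% MVIC), with a free intercept.  Normalizing force by the resting
mean CSA (stress, MPa) and elongation by the resting length (strain) gives
Young's modulus as the slope of the stress-strain line; for linear fits on
the same points the exact identity E = k * L0 / A0 holds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StagedTrialSet",
    "StiffnessResult",
    "ModulusResult",
    "elongation",
    "stiffness",
    "stress_strain",
    "youngs_modulus",
    "analyze_staged_set",
]


def elongation(level_length_mm: float, resting_length_mm: float) -> float:
    """Tendon elongation (mm) at a contraction level.

    Small negative values can arise from measurement noise; they are
    flagged with a warning but returned unclamped.
    """
    if level_length_mm <= 0 or resting_length_mm <= 0:
        raise ValueError("lengths must be positive")
    e = level_length_mm - resting_length_mm
    if e < 0:
        warnings.warn(
            f"negative elongation ({e:.3f} mm): loaded length below resting "
            "length, likely within measurement noise",
            stacklevel=2,
        )
    return e


def _ols_slope(x: np.ndarray, y: np.ndarray):
    """Free-intercept OLS slope, intercept and R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need >= 2 matched points")
    if np.ptp(x) == 0:
        raise ValueError("x values are identical; slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum((y - pred) ** 2) / ss_tot
    return float(slope), float(intercept), float(r2)


@dataclass(frozen=True)
class StiffnessResult:
    """Slope of the force-elongation line (N/mm) with fit diagnostics."""

    stiffness_Nmm: float
    intercept_N: float
    r_squared: float
    n_points: int


def stiffness(points) -> StiffnessResult:
    """Tendon stiffness from (force_N, elongation_mm) points.

    OLS line force = k * elongation + c across all levels; the slope k is
    the individual stiffness.  The intercept is free, not forced through
    the origin.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (N, 2) array of (force_N, elongation_mm)")
    forces, elongs = pts[:, 0], pts[:, 1]
    k, c, r2 = _ols_slope(elongs, forces)
    return StiffnessResult(k, c, r2, len(pts))


def stress_strain(points, mean_csa_mm2: float, resting_length_mm: float) -> np.ndarray:
    """Convert (force_N, elongation_mm) points to (stress_MPa, strain) pairs.

    Stress = force / resting mean CSA (N/mm^2 = MPa); strain = elongation /
    resting length, stored as a fraction (rendered as % only in reports).
    """
    if mean_csa_mm2 <= 0:
        raise ValueError("mean CSA must be positive")
    if resting_length_mm <= 0:
        raise ValueError("resting length must be positive")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (N, 2) array of (force_N, elongation_mm)")
    return np.column_stack([pts[:, 0] / mean_csa_mm2, pts[:, 1] / resting_length_mm])


@dataclass(frozen=True)
class ModulusResult:
    """Slope of the stress-strain line (MPa) with the normalizing geometry."""

    modulus_MPa: float
    intercept_MPa: float
    r_squared: float
    mean_csa_mm2: float
    resting_length_mm: float


def youngs_modulus(points, mean_csa_mm2: float, resting_length_mm: float) -> ModulusResult:
    """Young's modulus (MPa): slope of the OLS stress-strain line.

    Because stress and strain are linear rescalings of force and elongation,
    the identity E = k * L0 / A0 holds exactly against :func:`stiffness`
    fitted on the same points.
    """
    ss = stress_strain(points, mean_csa_mm2, resting_length_mm)
    e, c, r2 = _ols_slope(ss[:, 1], ss[:, 0])
    return ModulusResult(e, c, r2, float(mean_csa_mm2), float(resting_length_mm))


@dataclass(frozen=True)
class StagedTrialSet:
    """Averaged staged-protocol measurements for one subject/session.

    ``level_lengths_mm`` and ``level_forces_N`` are keyed by the MVIC
    fraction (0.35, 0.55, 0.75); lengths are the mean of the two repeat
    scans per state, forces the co-contraction-corrected tendon force.
    """

    resting_length_mm: float
    level_lengths_mm: dict
    level_forces_N: dict
    mean_csa_mm2: float | None = None

    def __post_init__(self):
        if set(self.level_lengths_mm) != set(self.level_forces_N):
            raise ValueError("length and force levels differ")
        if len(self.level_lengths_mm) < 2:
            raise ValueError("need at least 2 contraction levels")
        fr = sorted(self.level_forces_N)
        forces = [self.level_forces_N[f] for f in fr]
        if any(b <= a for a, b in zip(forces, forces[1:])):
            raise ValueError("forces must increase strictly with MVIC level")

    def points(self) -> np.ndarray:
        """(force_N, elongation_mm) points ordered by level."""
        return np.array(
            [
                [
                    self.level_forces_N[f],
                    elongation(self.level_lengths_mm[f], self.resting_length_mm),
                ]
                for f in sorted(self.level_forces_N)
            ]
        )


@dataclass(frozen=True)
class StagedMechanics:
    """Stiffness + modulus summary for one staged trial set."""

    stiffness: StiffnessResult
    modulus: ModulusResult | None


def analyze_staged_set(trial_set: StagedTrialSet) -> StagedMechanics:
    """Stiffness (always) and Young's modulus (when a mean CSA is supplied)."""
    pts = trial_set.points()
    k = stiffness(pts)
    mod = None
    if trial_set.mean_csa_mm2 is not None:
        mod = youngs_modulus(pts, trial_set.mean_csa_mm2, trial_set.resting_length_mm)
    return StagedMechanics(k, mod)
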