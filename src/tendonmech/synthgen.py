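"""Synthetic-data generation for the tendon-loading pipeline.

Everything the measurement chain consumes can be generated here with known
ground truth: tapering tubular tendon phantoms with closed-form volume,
tracked ultrasound sweeps of those phantoms, dynamometer torque plus
surface-EMG trials (dorsiflexion ramps for the antagonist co-contraction
regression, staged plantarflexion holds at 35/55/75% MVIC), and a full
subjects x interventions x pre/post crossover outcome table.

Units are fixed at generation: mm, mm^2, ml (1 ml = 1000 mm^3), N, N*m, s.
All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .recon3d import CalibrationTransform, Frame, Pose, TrackedSweep

__all__ = [
    "TendonPhantom",
    "SimulatedSubject",
    "EffectSpec",
    "InterventionEffect",
    "make_phantom",
    "simulate_sweep",
    "simulate_emg_torque_trial",
    "simulate_subject",
    "simulate_staged_session",
    "simulate_crossover_dataset",
    "TrialSignals",
    "DEFAULT_EFFECTS",
    "STAGED_FRACTIONS",
]

#: staged-protocol contraction intensities, as fractions of plantarflexion MVIC
STAGED_FRACTIONS = (0.35, 0.55, 0.75)

_IMG_CENTER_PX = 200.0  # contour centred on this pixel in both axes
_PX_SPACING_MM = 0.1


# ---------------------------------------------------------------------------
# tendon phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TendonPhantom:
    """Tubular phantom standing in for the free Achilles tendon.

    The cross-sectional area profile is a polynomial in normalized
    arclength s in [0, 1]; its integral times the length gives the exact
    volume, so reconstruction accuracy can be scored against truth.
    """

    length_mm: float
    area_coeffs: tuple  # polynomial coefficients (c0, c1, c2, ...) in s
    true_volume_ml: float

    def area_profile(self, s):
        s = np.asarray(s, dtype=float)
        return sum(c * s**k for k, c in enumerate(self.area_coeffs))


def make_phantom(length_mm: float, area_profile_spec) -> TendonPhantom:
    """Build a phantom from a profile spec.

    ``area_profile_spec`` is one of
      * ``("constant", a)`` — uniform CSA ``a`` mm^2,
      * ``("linear", a0, a1)`` — CSA tapering from ``a0`` at s=0 to ``a1`` at s=1,
      * ``("quadratic", c0, c1, c2)`` — polynomial ``c0 + c1*s + c2*s^2``.

    The true volume is the closed-form integral of the profile times the
    length, in ml.
    """
    if length_mm <= 0:
        raise ValueError(f"phantom length must be positive, got {length_mm}")
    kind, *params = area_profile_spec
    if kind == "constant":
        (a,) = params
        coeffs = (float(a),)
    elif kind == "linear":
        a0, a1 = params
        coeffs = (float(a0), float(a1) - float(a0))
    elif kind == "quadratic":
        coeffs = tuple(float(c) for c in params)
        if len(coeffs) != 3:
            raise ValueError("quadratic profile needs exactly 3 coefficients")
    else:
        raise ValueError(f"unknown area profile kind: {kind!r}")
    s = np.linspace(0.0, 1.0, 501)
    areas = sum(c * s**k for k, c in enumerate(coeffs))
    if np.any(areas <= 0):
        raise ValueError("area profile must be positive over the whole tendon")
    integral = sum(c / (k + 1) for k, c in enumerate(coeffs))  # over s in [0,1]
    return TendonPhantom(float(length_mm), coeffs, integral * length_mm / 1000.0)


def simulate_sweep(
    phantom: TendonPhantom,
    frame_spacing_mm: float = 0.1,
    pose_noise_mm: float = 0.0,
    pose_noise_deg: float = 0.0,
    contour_points: int = 64,
    seed: int | None = 0,
) -> TrackedSweep:
    """Simulate a tracked freehand sweep along a straight-centerline phantom.

    Frames are placed every ``frame_spacing_mm`` along the centerline (z axis
    of the world frame).  Each frame carries a circular cross-section contour
    inscribed in the phantom boundary, sampled at ``contour_points`` vertices
    in pixel coordinates, plus the probe pose.  Pose noise is isotropic
    Gaussian translation jitter (``pose_noise_mm`` per axis) and small-angle
    rotation jitter (``pose_noise_deg`` per axis).  The first and last frames
    are flagged as the calcaneal-notch and soleus-MTJ landmarks.
    """
    if frame_spacing_mm <= 0:
        raise ValueError("frame spacing must be positive")
    if frame_spacing_mm > phantom.length_mm:
        raise ValueError("frame spacing exceeds phantom length")
    if contour_points < 8:
        raise ValueError("need at least 8 contour points")
    rng = np.random.default_rng(seed)
    n_frames = int(round(phantom.length_mm / frame_spacing_mm)) + 1
    stations = np.linspace(0.0, phantom.length_mm, n_frames)
    areas = phantom.area_profile(stations / phantom.length_mm)
    radii = np.sqrt(areas / math.pi)

    theta = np.linspace(0.0, 2.0 * math.pi, contour_points, endpoint=False)
    # calibration centres the image on the probe origin
    calibration = CalibrationTransform(
        _PX_SPACING_MM,
        _PX_SPACING_MM,
        np.eye(3),
        np.array(
            [-_IMG_CENTER_PX * _PX_SPACING_MM, -_IMG_CENTER_PX * _PX_SPACING_MM, 0.0]
        ),
    )

    frames = []
    for i, (z, r) in enumerate(zip(stations, radii)):
        rows = _IMG_CENTER_PX + r * np.sin(theta) / _PX_SPACING_MM
        cols = _IMG_CENTER_PX + r * np.cos(theta) / _PX_SPACING_MM
        contour = np.column_stack([rows, cols])
        translation = np.array([0.0, 0.0, z])
        rotation = np.eye(3)
        if pose_noise_mm > 0:
            translation = translation + rng.normal(0.0, pose_noise_mm, 3)
        if pose_noise_deg > 0:
            rotation = Rotation.from_euler(
                "xyz", rng.normal(0.0, pose_noise_deg, 3), degrees=True
            ).as_matrix()
        landmark = (
            "calcaneal_notch"
            if i == 0
            else "soleus_mtj"
            if i == n_frames - 1
            else None
        )
        frames.append(Frame(Pose(rotation, translation), contour, landmark))
    meta = {
        "phantom_length_mm": phantom.length_mm,
        "true_volume_ml": phantom.true_volume_ml,
        "frame_spacing_mm": frame_spacing_mm,
    }
    return TrackedSweep(frames, calibration, meta)


# ---------------------------------------------------------------------------
# subjects and signals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedSubject:
    """Ground-truth physiology of one simulated participant."""

    mvic_torque_Nm: float = 120.0
    moment_arm_mm: float = 43.3
    rest_length_mm: float = 50.0
    rest_mean_csa_mm2: float = 50.0
    true_stiffness_Nmm: float = 330.0
    cocontraction_true: tuple = (2.0, 0.5)  # (slope N*m per V, intercept N*m)

    def __post_init__(self):
        for name in (
            "mvic_torque_Nm",
            "moment_arm_mm",
            "rest_length_mm",
            "rest_mean_csa_mm2",
            "true_stiffness_Nmm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def force_at(self, fraction: float) -> float:
        """True tendon force (N) at a given fraction of MVIC torque."""
        return fraction * self.mvic_torque_Nm / (self.moment_arm_mm / 1000.0)

    def length_at(self, fraction: float) -> float:
        """Loaded free-tendon length (mm) implied by the linear stiffness."""
        return self.rest_length_mm + self.force_at(fraction) / self.true_stiffness_Nmm


def simulate_subject(
    seed: int | None = 0,
    stiffness_band_Nmm: tuple = (200.0, 600.0),
) -> SimulatedSubject:
    """Draw a physiologically plausible subject (seeded)."""
    rng = np.random.default_rng(seed)
    return SimulatedSubject(
        mvic_torque_Nm=rng.uniform(80.0, 160.0),
        moment_arm_mm=rng.normal(43.3, 3.93),
        rest_length_mm=rng.uniform(40.0, 70.0),
        rest_mean_csa_mm2=rng.uniform(40.0, 65.0),
        true_stiffness_Nmm=rng.uniform(*stiffness_band_Nmm),
        cocontraction_true=(rng.uniform(1.0, 4.0), rng.uniform(0.2, 1.5)),
    )


@dataclass(frozen=True)
class TrialSignals:
    """Paired dynamometer torque and raw surface EMG from one trial."""

    time_s: np.ndarray
    torque_Nm: np.ndarray  # as recorded by the dynamometer
    emg_V: np.ndarray  # raw (unfiltered) EMG
    fs_hz: float
    true_torque_Nm: np.ndarray = None  # type: ignore[assignment]
    true_envelope_V: np.ndarray = None  # type: ignore[assignment]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time_s, "torque_Nm": self.torque_Nm, "emg_V": self.emg_V}
        )


def _bandlimited_noise(n: int, fs: float, lo: float, hi: float, rng) -> np.ndarray:
    """Unit-RMS noise with support restricted to [lo, hi] Hz (FFT masking)."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum[(freqs < lo) | (freqs > hi)] = 0.0
    x = np.fft.irfft(spectrum, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _ramp_hold(n: int, fs: float, ramp_s: float, level: float) -> np.ndarray:
    t = np.arange(n) / fs
    if ramp_s <= 0:
        return np.full(n, level)
    return level * np.clip(t / ramp_s, 0.0, 1.0)


def simulate_emg_torque_trial(
    subject: SimulatedSubject,
    mode: str,
    target_fraction: float | None = None,
    duration_s: float = 8.0,
    fs_hz: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    ramp_s: float = 1.0,
    cocontraction_envelope_V: float = 0.05,
) -> TrialSignals:
    """Simulate one dynamometer trial with surface EMG.

    ``mode="DF_MVIC"``: ramped maximal dorsiflexion.  The tibialis-anterior
    EMG envelope ramps up and the recorded dorsiflexion torque follows the
    subject's true linear co-contraction relationship
    ``torque = P1 * envelope + P2`` plus Gaussian noise — the calibration
    data for the antagonist-torque regression.

    ``mode="PF_staged"``: sustained plantarflexion at ``target_fraction`` of
    MVIC (0.35, 0.55 or 0.75), ramp then hold.  The returned ``torque_Nm``
    is the *net* recorded torque, i.e. the true plantarflexion torque minus
    the antagonist dorsiflexion torque implied by the co-contraction EMG;
    ``true_torque_Nm`` carries the ground truth.

    The raw EMG is band-limited (20-450 Hz) noise amplitude-modulated so
    that its RMS envelope equals the programmed envelope.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if fs_hz <= 0:
        raise ValueError("sampling rate must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    p1, p2 = subject.cocontraction_true

    if mode == "DF_MVIC":
        envelope = _ramp_hold(n, fs_hz, max(ramp_s, 0.25) * 3, 1.0)
        true_torque = p1 * envelope + p2
        recorded = true_torque + rng.normal(0.0, noise_sd, n)
    elif mode == "PF_staged":
        if target_fraction not in STAGED_FRACTIONS:
            raise ValueError(
                f"target_fraction must be one of {STAGED_FRACTIONS}, "
                f"got {target_fraction}"
            )
        envelope = _ramp_hold(n, fs_hz, ramp_s, cocontraction_envelope_V)
        true_torque = _ramp_hold(n, fs_hz, ramp_s, target_fraction * subject.mvic_torque_Nm)
        antagonist = p1 * envelope + p2
        recorded = true_torque - antagonist + rng.normal(0.0, noise_sd, n)
    else:
        raise ValueError(f"unknown trial mode: {mode!r}")

    emg = _bandlimited_noise(n, fs_hz, 20.0, min(450.0, 0.45 * fs_hz), rng) * envelope
    return TrialSignals(t, recorded, emg, fs_hz, true_torque, envelope)


def simulate_staged_session(
    subject: SimulatedSubject,
    length_noise_mm: float = 0.0,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Measured lengths/forces for the staged protocol (two scans per state).

    Returns a tidy frame with one row per (state, repeat): the rest state and
    each staged MVIC fraction, with the free-tendon length perturbed by
    ``length_noise_mm`` and the true tendon force at that level.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for state, fraction in [("rest", 0.0)] + [
        (f"{int(f * 100)}%", f) for f in STAGED_FRACTIONS
    ]:
        true_len = subject.rest_length_mm if fraction == 0 else subject.length_at(fraction)
        for repeat in (1, 2):
            rows.append(
                {
                    "state": state,
                    "fraction": fraction,
                    "repeat": repeat,
                    "length_mm": true_len + rng.normal(0.0, length_noise_mm),
                    "force_N": 0.0 if fraction == 0 else subject.force_at(fraction),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# crossover trial
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InterventionEffect:
    """Mean and SD of the acute (post - pre) change for one intervention."""

    volume_change_ml: float
    volume_change_sd: float
    stiffness_change_Nmm: float
    stiffness_change_sd: float

    def __post_init__(self):
        if self.volume_change_sd < 0 or self.stiffness_change_sd < 0:
            raise ValueError("change-score SDs must be non-negative")


#: intervention effects calibrated to the reported cohort: largest
#: reductions after 8 s contractions at 75% MVIC, a small stiffness
#: *increase* with the short 2 s contractions, intermediate response at 35%.
DEFAULT_EFFECTS = {
    "8s75": InterventionEffect(-0.30, 0.13, -67.35, 40.0),
    "2s75": InterventionEffect(-0.05, 0.13, +37.78, 40.0),
    "8s35": InterventionEffect(-0.12, 0.13, -36.45, 40.0),
}


@dataclass(frozen=True)
class EffectSpec:
    """Generative spec for the crossover outcome table."""

    effects: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    baseline_volume_ml: float = 2.2
    baseline_volume_sd: float = 0.6
    baseline_stiffness_Nmm: float = 330.0
    baseline_stiffness_sd: float = 60.0
    within_subject_correlation: float = 0.9

    def __post_init__(self):
        if not -1.0 <= self.within_subject_correlation <= 1.0:
            raise ValueError("within-subject correlation must be in [-1, 1]")

    def null(self) -> "EffectSpec":
        """Same baselines, all intervention effects and change SDs zero."""
        return replace(
            self,
            effects={k: InterventionEffect(0, 0, 0, 0) for k in self.effects},
        )


def _correlated_baselines(rng, n, k, mean, sd, rho):
    """n x k baselines with common mean/SD and within-subject correlation rho."""
    rho = max(rho, 0.0)
    subj = rng.normal(0.0, math.sqrt(rho), n)[:, None]
    sess = rng.normal(0.0, math.sqrt(1.0 - rho), (n, k))
    return mean + sd * (subj + sess)


def simulate_crossover_dataset(
    n_subjects: int = 16,
    effect_spec: EffectSpec | None = None,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Simulate the crossover outcome table.

    Each subject performs every intervention (randomized period order,
    one-week washout implied); volume and stiffness are measured pre and
    post.  Baselines are identical across interventions in expectation;
    post = pre + an intervention-specific change drawn from the effect spec.

    Returns a tidy frame: subject, intervention, period, time (pre/post),
    volume_ml, stiffness_Nmm.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    spec = effect_spec or EffectSpec()
    rng = np.random.default_rng(seed)
    interventions = list(spec.effects)
    k = len(interventions)
    vol_pre = _correlated_baselines(
        rng, n_subjects, k, spec.baseline_volume_ml, spec.baseline_volume_sd,
        spec.within_subject_correlation,
    )
    stiff_pre = _correlated_baselines(
        rng, n_subjects, k, spec.baseline_stiffness_Nmm, spec.baseline_stiffness_sd,
        spec.within_subject_correlation,
    )
    rows = []
    for i in range(n_subjects):
        order = rng.permutation(k)
        for j, name in enumerate(interventions):
            eff = spec.effects[name]
            dv = rng.normal(eff.volume_change_ml, eff.volume_change_sd)
            ds = rng.normal(eff.stiffness_change_Nmm, eff.stiffness_change_sd)
            period = int(order[j]) + 1
            for time, v, s in (
                ("pre", vol_pre[i, j], stiff_pre[i, j]),
                ("post", vol_pre[i, j] + dv, stiff_pre[i, j] + ds),
            ):
                rows.append(
                    {
                        "subject": f"S{i + 1:02d}",
                        "intervention": name,
                        "period": period,
                        "time": time,
                        "volume_ml": v,
                        "stiffness_Nmm": s,
                    }
                )
    return pd.DataFrame(rows)
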