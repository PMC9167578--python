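"""EMG processing, antagonist co-contraction correction and tendon force.

Net plantarflexion torque recorded by a dynamometer underestimates the true
agonist torque whenever the tibialis anterior (TA) co-contracts.  The
correction assumes a linear relationship between the TA EMG envelope and
dorsiflexion torque, calibrated during maximal dorsiflexion trials:

    torque_DF = P1 * envelope + P2

The estimated antagonist torque is added back to the net plantarflexion
torque, and the corrected ("true") torque is divided by the Achilles tendon
moment arm to give tendon force.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

__all__ = [
    "Signal",
    "CocontractionModel",
    "MomentArm",
    "MvicResult",
    "bandpass",
    "rms_envelope",
    "fit_cocontraction",
    "true_pf_torque",
    "moment_arm",
    "tendon_force",
    "mvic",
]


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled 1-D signal."""

    samples: np.ndarray
    fs_hz: float = 1000.0
    units: str = ""

    def __post_init__(self):
        x = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(x)):
            raise ValueError("signal contains non-finite samples")
        object.__setattr__(self, "samples", x)

    def __len__(self):
        return len(self.samples)


def _as_array(sig) -> tuple[np.ndarray, float]:
    if isinstance(sig, Signal):
        return sig.samples, sig.fs_hz
    return np.asarray(sig, dtype=float), 1000.0


def bandpass(sig, lo_hz: float = 20.0, hi_hz: float = 450.0, order: int = 4):
    """Zero-phase Butterworth band-pass, the standard surface-EMG cleanup.

    Applied forward-backward (``sosfiltfilt``) so the envelope stays aligned
    with the torque channel.  Raises if the upper edge reaches Nyquist.
    """
    x, fs = _as_array(sig)
    if not 0 < lo_hz < hi_hz:
        raise ValueError("need 0 < lo < hi")
    if hi_hz >= fs / 2:
        raise ValueError(f"high cutoff {hi_hz} Hz >= Nyquist ({fs / 2} Hz)")
    sos = sps.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    if isinstance(sig, Signal):
        return Signal(y, fs, sig.units)
    return y


def rms_envelope(sig, window: int = 200):
    """RMS envelope over a centred sliding window (default 200 samples).

    At the edges the window shrinks to the available samples, so the output
    has the same length as the input and is everywhere non-negative.
    """
    x, fs = _as_array(sig)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(x):
        raise ValueError(f"window ({window}) longer than signal ({len(x)})")
    sq = np.concatenate([[0.0], np.cumsum(x**2)])
    n = len(x)
    idx = np.arange(n)
    half_lo = window // 2
    half_hi = window - half_lo
    lo = np.clip(idx - half_lo, 0, n)
    hi = np.clip(idx + half_hi, 0, n)
    env = np.sqrt((sq[hi] - sq[lo]) / (hi - lo))
    if isinstance(sig, Signal):
        return Signal(env, fs, sig.units)
    return env


@dataclass(frozen=True)
class CocontractionModel:
    """Linear TA-EMG -> dorsiflexion-torque model (slope P1, intercept P2)."""

    p1_slope: float  # N*m per envelope unit
    p2_intercept: float  # N*m
    r_squared: float
    residual_sd: float
    n_samples: int

    def predict(self, envelope):
        return self.p1_slope * np.asarray(envelope, dtype=float) + self.p2_intercept


def fit_cocontraction(df_trials) -> CocontractionModel:
    """Fit the co-contraction regression on pooled dorsiflexion trials.

    ``df_trials`` is a sequence of ``(envelope, torque)`` pairs (arrays of
    matched samples, typically up to three ramped maximal dorsiflexion
    trials).  Ordinary least squares on the pooled samples.
    """
    envs, torques = [], []
    for env, tor in df_trials:
        env = np.asarray(env, dtype=float).ravel()
        tor = np.asarray(tor, dtype=float).ravel()
        if len(env) != len(tor):
            raise ValueError("envelope and torque lengths differ within a trial")
        envs.append(env)
        torques.append(tor)
    if not envs:
        raise ValueError("no dorsiflexion trials provided")
    x = np.concatenate(envs)
    y = np.concatenate(torques)
    if np.ptp(x) == 0:
        raise ValueError("EMG envelope is constant; cannot fit a slope")
    res = spstats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    dof = max(len(x) - 2, 1)
    return CocontractionModel(
        float(res.slope),
        float(res.intercept),
        float(res.rvalue**2),
        float(np.sqrt(resid @ resid / dof)),
        len(x),
    )


def true_pf_torque(net_pf_torque, ta_envelope, model: CocontractionModel):
    """Co-contraction-corrected plantarflexion torque.

    The antagonist dorsiflexion torque predicted from the TA envelope is
    added elementwise to the net recorded torque.
    """
    net, fs = _as_array(net_pf_torque)
    env, _ = _as_array(ta_envelope)
    if len(net) != len(env):
        raise ValueError(
            f"torque ({len(net)}) and envelope ({len(env)}) lengths differ"
        )
    out = net + model.predict(env)
    if isinstance(net_pf_torque, Signal):
        return Signal(out, fs, net_pf_torque.units)
    return out


@dataclass(frozen=True)
class MomentArm:
    """Achilles tendon moment arm from the two-distance B-mode method.

    d1: probe tip to ankle centre of rotation (tape measure);
    d2: skin to the tendon midline / line of action (on the B-mode image).
    The moment arm is their difference.
    """

    d1_mm: float
    d2_mm: float

    def __post_init__(self):
        if not self.d1_mm > self.d2_mm > 0:
            raise ValueError(
                f"require d1 > d2 > 0, got d1={self.d1_mm}, d2={self.d2_mm}"
            )

    @property
    def value_mm(self) -> float:
        return self.d1_mm - self.d2_mm


def moment_arm(d1_mm: float, d2_mm: float) -> MomentArm:
    """Tendon moment arm (mm) as the difference d1 - d2."""
    return MomentArm(float(d1_mm), float(d2_mm))


def tendon_force(true_torque_Nm, arm) -> np.ndarray | float:
    """Tendon force (N): corrected torque divided by the moment arm (in m)."""
    arm_mm = arm.value_mm if isinstance(arm, MomentArm) else float(arm)
    if arm_mm <= 0:
        raise ValueError("moment arm must be positive")
    torque = np.asarray(true_torque_Nm, dtype=float)
    force = torque / (arm_mm / 1000.0)
    return float(force) if force.ndim == 0 else force


@dataclass(frozen=True)
class MvicResult:
    """Outcome of the maximal-contraction acceptance rule."""

    trial_peaks_Nm: tuple
    accepted: bool
    mvic_Nm: float | None
    reason: str = ""


def _trial_peak(torque, fs_hz: float = 1000.0, smooth_s: float = 0.5) -> float:
    """Peak of the moving-average-smoothed torque (plateau estimate)."""
    x, fs = _as_array(torque) if not np.isscalar(torque) else (np.array([torque]), fs_hz)
    w = max(int(round(smooth_s * fs)), 1)
    if w >= len(x):
        return float(np.mean(x))
    smooth = np.convolve(x, np.ones(w) / w, mode="valid")
    return float(smooth.max())


def mvic(trials, fs_hz: float = 1000.0) -> MvicResult:
    """Apply the MVIC acceptance rule to 1-5 ramped maximal trials.

    The peak (plateau-smoothed) torque is extracted per trial; the maximum
    is accepted as the MVIC only if the two highest peaks are within 10% of
    each other, prompting a re-trial otherwise.
    """
    peaks = tuple(_trial_peak(t, fs_hz) for t in trials)
    if len(peaks) < 2:
        return MvicResult(peaks, False, None, "need at least 2 trials")
    top = sorted(peaks, reverse=True)
    spread = (top[0] - top[1]) / top[0]
    if spread > 0.10:
        return MvicResult(
            peaks, False, None,
            f"two highest trials differ by {spread:.1%} (> 10%)",
        )
    return MvicResult(peaks, True, top[0])
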