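"""End-to-end orchestration: simulate -> reconstruct -> force -> mechanics -> stats.

The three isometric loading interventions are shipped as named presets that
differ only in contraction duration and intensity while matching volume
(10 repetitions x 4 sets) and rest (10 s between repetitions, 3 min between
sets), so the total time under tension is the comparison of interest:
8 s x 10 x 4 = 320 s for the long-duration presets versus 80 s for the
short one.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import emgtorque, mechanics, recon3d, stats, synthgen

__all__ = [
    "InterventionSpec",
    "INTERVENTIONS",
    "RunConfig",
    "RunResults",
    "total_load_duration",
    "randomize_sequences",
    "measure_subject",
    "run_all",
]

logger = logging.getLogger("tendonmech")


@dataclass(frozen=True)
class InterventionSpec:
    """One isometric loading protocol."""

    name: str
    contraction_duration_s: float
    intensity_fraction: float
    repetitions: int = 10
    sets: int = 4
    rest_between_reps_s: float = 10.0
    rest_between_sets_s: float = 180.0
    ramp_s: float = 0.5  # within-repetition ramp to target (configurable)

    @property
    def total_load_duration_s(self) -> float:
        return self.contraction_duration_s * self.repetitions * self.sets


#: the three trial arms: long/heavy, short/heavy, long/light
INTERVENTIONS = {
    "8s75": InterventionSpec("8s75", 8.0, 0.75),
    "2s75": InterventionSpec("2s75", 2.0, 0.75),
    "8s35": InterventionSpec("8s35", 8.0, 0.35),
}


def total_load_duration(spec: InterventionSpec) -> float:
    """Total time under tension (s): duration x repetitions x sets."""
    return spec.total_load_duration_s


def randomize_sequences(n_subjects: int, interventions=None, seed: int | None = 0):
    """Computer-based random allocation of intervention order per subject."""
    names = list(interventions or INTERVENTIONS)
    rng = np.random.default_rng(seed)
    return [list(rng.permutation(names)) for _ in range(n_subjects)]


# ---------------------------------------------------------------------------
# per-subject measurement chain
# ---------------------------------------------------------------------------

def _measure_length_and_geometry(
    subject, fraction, *, frame_spacing_mm, contour_points, pose_noise_mm, seed
):
    """Scan the tendon at one contraction state and reconstruct geometry."""
    length = (
        subject.rest_length_mm if fraction == 0.0 else subject.length_at(fraction)
    )
    # the phantom carries the subject's (constant) resting CSA profile
    phantom = synthgen.make_phantom(length, ("constant", subject.rest_mean_csa_mm2))
    sweep = synthgen.simulate_sweep(
        phantom,
        frame_spacing_mm=frame_spacing_mm,
        pose_noise_mm=pose_noise_mm,
        contour_points=contour_points,
        seed=seed,
    )
    return recon3d.reconstruct_geometry(sweep, step_mm=frame_spacing_mm)


def measure_subject(
    subject: synthgen.SimulatedSubject,
    seed: int = 0,
    frame_spacing_mm: float = 0.5,
    contour_points: int = 64,
    pose_noise_mm: float = 0.0,
    emg_noise_sd: float = 0.0,
    trial_duration_s: float = 8.0,
) -> dict:
    """Run the full measurement chain for one simulated participant.

    Two sweeps per state (rest + each staged level) are reconstructed and
    averaged; dorsiflexion trials calibrate the co-contraction regression;
    staged plantarflexion trials give the net torque that is corrected and
    converted to tendon force; stiffness and Young's modulus come from the
    force-elongation fit.  Returns the measured quantities together with
    the subject's ground truth.
    """
    rng = np.random.default_rng(seed)

    def subseed():
        return int(rng.integers(0, 2**31 - 1))

    # -- co-contraction calibration from 3 ramped dorsiflexion trials
    df_pairs = []
    for _ in range(3):
        trial = synthgen.simulate_emg_torque_trial(
            subject, "DF_MVIC", duration_s=trial_duration_s,
            noise_sd=emg_noise_sd, seed=subseed(),
        )
        raw = emgtorque.Signal(trial.emg_V, trial.fs_hz, "V")
        env = emgtorque.rms_envelope(emgtorque.bandpass(raw))
        df_pairs.append((env.samples, trial.torque_Nm))
    cc_model = emgtorque.fit_cocontraction(df_pairs)
    arm = emgtorque.moment_arm(subject.moment_arm_mm + 6.7, 6.7)

    # -- geometry: two scans per state, averaged
    def scan_state(fraction):
        geoms = [
            _measure_length_and_geometry(
                subject, fraction,
                frame_spacing_mm=frame_spacing_mm,
                contour_points=contour_points,
                pose_noise_mm=pose_noise_mm,
                seed=subseed(),
            )
            for _ in range(2)
        ]
        return geoms, float(np.mean([g.length_mm for g in geoms]))

    rest_geoms, rest_len = scan_state(0.0)
    mean_csa = float(np.mean([g.mean_csa_mm2 for g in rest_geoms]))
    volume = float(np.mean([g.volume_ml for g in rest_geoms]))

    level_lengths, level_forces = {}, {}
    for fraction in synthgen.STAGED_FRACTIONS:
        _, level_lengths[fraction] = scan_state(fraction)
        trial = synthgen.simulate_emg_torque_trial(
            subject, "PF_staged", target_fraction=fraction,
            duration_s=trial_duration_s, noise_sd=emg_noise_sd, seed=subseed(),
        )
        raw = emgtorque.Signal(trial.emg_V, trial.fs_hz, "V")
        env = emgtorque.rms_envelope(emgtorque.bandpass(raw)).samples
        true_torque = emgtorque.true_pf_torque(trial.torque_Nm, env, cc_model)
        # plateau: mean over the central 50% of the hold phase
        n = len(true_torque)
        plateau = true_torque[int(n * 0.4): int(n * 0.9)]
        level_forces[fraction] = float(
            emgtorque.tendon_force(np.mean(plateau), arm)
        )

    trial_set = mechanics.StagedTrialSet(
        rest_len, level_lengths, level_forces, mean_csa_mm2=mean_csa
    )
    result = mechanics.analyze_staged_set(trial_set)
    return {
        "rest_length_mm": rest_len,
        "mean_csa_mm2": mean_csa,
        "volume_ml": volume,
        "forces_N": level_forces,
        "elongations_mm": {
            f: level_lengths[f] - rest_len for f in level_lengths
        },
        "stiffness_Nmm": result.stiffness.stiffness_Nmm,
        "stiffness_r2": result.stiffness.r_squared,
        "modulus_MPa": result.modulus.modulus_MPa,
        "cocontraction_p1": cc_model.p1_slope,
        "cocontraction_p2": cc_model.p2_intercept,
        "true_stiffness_Nmm": subject.true_stiffness_Nmm,
        "true_volume_ml": subject.rest_mean_csa_mm2 * subject.rest_length_mm / 1000.0,
    }


# ---------------------------------------------------------------------------
# run configuration and orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Fully serializable configuration; a run is reproducible from it alone."""

    seed: int = 0
    n_subjects: int = 16
    n_measured_subjects: int = 4
    frame_spacing_mm: float = 0.5
    contour_points: int = 64
    pose_noise_mm: float = 0.0
    emg_noise_sd: float = 0.0
    effect_spec: synthgen.EffectSpec = field(default_factory=synthgen.EffectSpec)
    icc_form: str = "absolute"
    out_dir: str = "tendonmech_out"

    def to_yaml(self, path=None):
        d = dataclasses.asdict(self)
        d["effect_spec"]["effects"] = {
            k: dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
            for k, v in self.effect_spec.effects.items()
        }
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
            return None
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = yaml.safe_load(text)
        if "effect_spec" in d:
            es = d["effect_spec"]
            es["effects"] = {
                k: synthgen.InterventionEffect(**v) for k, v in es["effects"].items()
            }
            d["effect_spec"] = synthgen.EffectSpec(**es)
        return cls(**d)


@dataclass
class RunResults:
    """Bundle of everything one end-to-end run produced."""

    config: RunConfig
    subject_table: pd.DataFrame
    dataset: pd.DataFrame
    anova: dict  # outcome -> CrossoverAnovaResults
    change_summary: pd.DataFrame


def _change_summary(dataset: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD change score per intervention and outcome (Fig.-style)."""
    rows = []
    for outcome in ("volume_ml", "stiffness_Nmm"):
        model = stats.CrossoverAnova(dataset, outcome)
        delta = model.change_scores()
        for name in delta.columns:
            rows.append(
                {
                    "outcome": outcome,
                    "intervention": name,
                    "mean_change": delta[name].mean(),
                    "sd_change": delta[name].std(ddof=1),
                }
            )
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> RunResults:
    """Execute the whole pipeline and write all tables under the output dir.

    Stages: (1) per-subject measurement chain on simulated participants,
    (2) crossover outcome simulation, (3) ANOVA + contrasts + simple effects
    per outcome, (4) change-score summary.  Every output is a CSV (or the
    config echo as YAML); a log records seeds and analysis toggles.  A stage
    failure raises with the stage name; earlier outputs are kept.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("run_all starting; seed=%d; config:\n%s", config.seed, config.to_yaml())
    rng = np.random.default_rng(config.seed)
    try:
        # stage 1: measured subjects
        try:
            rows = []
            for i in range(config.n_measured_subjects):
                subject = synthgen.simulate_subject(int(rng.integers(0, 2**31 - 1)))
                meas = measure_subject(
                    subject,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    frame_spacing_mm=config.frame_spacing_mm,
                    contour_points=config.contour_points,
                    pose_noise_mm=config.pose_noise_mm,
                    emg_noise_sd=config.emg_noise_sd,
                )
                flat = {
                    k: v for k, v in meas.items() if not isinstance(v, dict)
                }
                for f, v in meas["forces_N"].items():
                    flat[f"force_{int(f * 100)}_N"] = v
                for f, v in meas["elongations_mm"].items():
                    flat[f"elongation_{int(f * 100)}_mm"] = v
                rows.append({"subject": f"S{i + 1:02d}", **flat})
            subject_table = pd.DataFrame(rows)
            subject_table.to_csv(out / "subjects.csv", index=False)
        except Exception as exc:
            raise RuntimeError(f"stage 'measure' failed: {exc}") from exc

        # stage 2: crossover dataset
        try:
            dataset = synthgen.simulate_crossover_dataset(
                config.n_subjects, config.effect_spec,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            dataset.to_csv(out / "crossover_dataset.csv", index=False)
        except Exception as exc:
            raise RuntimeError(f"stage 'simulate-crossover' failed: {exc}") from exc

        # stage 3: statistics
        anova = {}
        try:
            for outcome in ("volume_ml", "stiffness_Nmm"):
                res = stats.CrossoverAnova(dataset, outcome).fit()
                anova[outcome] = res
                res.anova_table.to_csv(out / f"anova_{outcome}.csv")
                res.interaction_contrasts().to_csv(out / f"contrasts_{outcome}.csv")
                res.simple_effects().to_csv(out / f"simple_effects_{outcome}.csv")
        except Exception as exc:
            raise RuntimeError(f"stage 'stats' failed: {exc}") from exc

        # stage 4: reporting
        try:
            change_summary = _change_summary(dataset)
            change_summary.to_csv(out / "change_summary.csv", index=False)
            config.to_yaml(out / "config_echo.yaml")
            (out / "versions.json").write_text(
                json.dumps({"numpy": np.__version__, "pandas": pd.__version__})
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'report' failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    return RunResults(config, subject_table, dataset, anova, change_summary)
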