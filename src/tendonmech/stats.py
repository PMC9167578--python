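"""Crossover-trial inference and measurement-reliability statistics.

The primary inferential model is a two-way repeated-measures ANOVA with
time (pre/post) and intervention as within-subject factors, exposed as the
:class:`CrossoverAnova` model whose :meth:`~CrossoverAnova.fit` returns a
:class:`CrossoverAnovaResults` object carrying the ANOVA table, pairwise
interaction contrasts on change scores, and per-intervention simple
effects.  Sphericity is assumed (no epsilon correction) and pairwise
p-values are unadjusted; both behaviours are configurable.

Reliability metrics follow the two-way intraclass-correlation framework:
ICC in both absolute-agreement and consistency forms with F-based 95%
confidence intervals, coefficient of variation, standard error of
measurement (SEM) and the minimal detectable change MDC = SEM * 1.96 * sqrt(2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "CrossoverAnova",
    "CrossoverAnovaResults",
    "AnovaEffect",
    "ReliabilityResult",
    "SampleSizeResult",
    "rm_anova_2x3",
    "interaction_contrasts",
    "simple_effects",
    "effect_size",
    "ks_normality",
    "icc_3_1",
    "cv_percent",
    "sem_from_icc",
    "mdc",
    "reliability",
    "crossover_sample_size",
    "relative_difference_percent",
    "simulate_null_interaction_pvalues",
]


# ---------------------------------------------------------------------------
# repeated-measures ANOVA core
# ---------------------------------------------------------------------------

def _rm_anova_core(y: np.ndarray) -> dict:
    """Sum-of-squares decomposition for a fully within-subjects two-way design.

    ``y`` has shape (..., n_subjects, n_time, n_intervention); leading axes
    are independent replicates (used by the Monte-Carlo utilities).  Each
    within-subject effect is tested against its own subject-interaction
    stratum, the classical univariate approach with sphericity assumed.
    """
    y = np.asarray(y, dtype=float)
    n, t, k = y.shape[-3:]
    m = y.mean(axis=(-3, -2, -1), keepdims=True)
    m_s = y.mean(axis=(-2, -1), keepdims=True)
    m_t = y.mean(axis=(-3, -1), keepdims=True)
    m_k = y.mean(axis=(-3, -2), keepdims=True)
    m_st = y.mean(axis=-1, keepdims=True)
    m_sk = y.mean(axis=-2, keepdims=True)
    m_tk = y.mean(axis=-3, keepdims=True)

    def ss(x):
        return (x**2).sum(axis=(-3, -2, -1))

    # summing a broadcast deviation array over all three design axes applies
    # the correct n*k (etc.) multiplicity to each squared term
    ss_time = ss(np.broadcast_to(m_t - m, y.shape))
    ss_int = ss(np.broadcast_to(m_k - m, y.shape))
    ss_subj = ss(np.broadcast_to(m_s - m, y.shape))
    ss_ts = ss(np.broadcast_to(m_st - m_s - m_t + m, y.shape))
    ss_ks = ss(np.broadcast_to(m_sk - m_s - m_k + m, y.shape))
    ss_tk = ss(np.broadcast_to(m_tk - m_t - m_k + m, y.shape))
    ss_total = ss(y - m)
    ss_tks = ss_total - ss_subj - ss_time - ss_int - ss_ts - ss_ks - ss_tk

    out = {}
    for name, ss_eff, df_eff, ss_err, df_err in [
        ("time", ss_time, t - 1, ss_ts, (n - 1) * (t - 1)),
        ("intervention", ss_int, k - 1, ss_ks, (n - 1) * (k - 1)),
        ("time:intervention", ss_tk, (t - 1) * (k - 1), ss_tks,
         (n - 1) * (t - 1) * (k - 1)),
    ]:
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ms_eff / ms_err
        p = spstats.f.sf(f, df_eff, df_err)
        out[name] = {
            "ss": ss_eff, "df_num": df_eff, "df_den": df_err,
            "ms": ms_eff, "ms_err": ms_err, "F": f, "p": p,
        }
    return out


@dataclass(frozen=True)
class AnovaEffect:
    """One line of the within-subjects ANOVA table."""

    name: str
    F: float
    df_num: int
    df_den: int
    p: float


class CrossoverAnova:
    """Two-way fully-within-subjects ANOVA model for a crossover trial.

    Parameters
    ----------
    data : tidy DataFrame with one row per subject x intervention x time cell
    outcome : column holding the outcome (e.g. ``"volume_ml"``)
    subject, time, intervention : design column names
    time_order : level order for the time factor (default pre, post)

    The design must be complete and balanced: every subject x intervention x
    time cell present exactly once.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str,
        subject: str = "subject",
        time: str = "time",
        intervention: str = "intervention",
        time_order=("pre", "post"),
    ):
        for col in (outcome, subject, time, intervention):
            if col not in data.columns:
                raise ValueError(f"column {col!r} not in data")
        self.data = data
        self.outcome = outcome
        self.cols = dict(subject=subject, time=time, intervention=intervention)
        self.subjects = sorted(data[subject].unique())
        times = list(time_order) if time_order else sorted(data[time].unique())
        self.times = [lv for lv in times if lv in set(data[time])]
        self.interventions = sorted(data[intervention].unique())
        self._y = self._to_cube()

    def _to_cube(self) -> np.ndarray:
        c = self.cols
        pivot = self.data.pivot_table(
            index=c["subject"],
            columns=[c["time"], c["intervention"]],
            values=self.outcome,
            aggfunc="count",
        )
        expected = pd.MultiIndex.from_product([self.times, self.interventions])
        missing = []
        for subj in self.subjects:
            for cell in expected:
                if (
                    subj not in pivot.index
                    or cell not in pivot.columns
                    or pivot.loc[subj, cell] != 1
                ):
                    missing.append((subj, *cell))
        if missing:
            raise ValueError(
                f"design not complete/balanced; problem cells "
                f"(subject, time, intervention): {missing[:10]}"
            )
        values = self.data.pivot_table(
            index=c["subject"], columns=[c["time"], c["intervention"]],
            values=self.outcome,
        )
        n, t, k = len(self.subjects), len(self.times), len(self.interventions)
        y = np.empty((n, t, k))
        for ti, tv in enumerate(self.times):
            for ki, kv in enumerate(self.interventions):
                y[:, ti, ki] = values.loc[self.subjects, (tv, kv)].to_numpy()
        return y

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def change_scores(self) -> pd.DataFrame:
        """Per-subject post - pre change, one column per intervention."""
        if len(self.times) != 2:
            raise ValueError("change scores need exactly 2 time levels")
        delta = self._y[:, 1, :] - self._y[:, 0, :]
        return pd.DataFrame(delta, index=self.subjects, columns=self.interventions)

    def fit(self) -> "CrossoverAnovaResults":
        core = _rm_anova_core(self._y)
        effects = {
            name: AnovaEffect(name, float(r["F"]), r["df_num"], r["df_den"],
                              float(r["p"]))
            for name, r in core.items()
        }
        return CrossoverAnovaResults(self, effects)


@dataclass
class CrossoverAnovaResults:
    """Fitted crossover ANOVA: table, contrasts, simple effects, summary."""

    model: CrossoverAnova
    effects: dict = field(repr=False)

    @property
    def interaction(self) -> AnovaEffect:
        return self.effects["time:intervention"]

    @property
    def anova_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"effect": e.name, "F": e.F, "df_num": e.df_num,
                 "df_den": e.df_den, "p": e.p}
                for e in self.effects.values()
            ]
        ).set_index("effect")

    def interaction_contrasts(self, alpha: float = 0.05) -> pd.DataFrame:
        """Pairwise intervention comparisons of per-subject change scores.

        Paired t-test per intervention pair, unadjusted p-values, and the
        standardized effect size (difference of mean change scores divided
        by the pooled change-score SD).
        """
        delta = self.model.change_scores()
        rows = []
        for a, b in combinations(delta.columns, 2):
            d = delta[a] - delta[b]
            n = len(d)
            t_res = spstats.ttest_rel(delta[a], delta[b])
            se = d.std(ddof=1) / math.sqrt(n)
            tcrit = spstats.t.ppf(1 - alpha / 2, n - 1)
            rows.append(
                {
                    "contrast": f"{a} - {b}",
                    "estimate": d.mean(),
                    "ci_low": d.mean() - tcrit * se,
                    "ci_high": d.mean() + tcrit * se,
                    "t": float(t_res.statistic),
                    "p": float(t_res.pvalue),
                    "effect_size": effect_size(delta[a], delta[b]),
                }
            )
        return pd.DataFrame(rows).set_index("contrast")

    def simple_effects(self, mdc_threshold: float | None = None) -> pd.DataFrame:
        """Pre-vs-post paired comparison within each intervention.

        Reports mean change, percent change relative to the pre mean, and
        the paired-t p-value.  When an MDC threshold is supplied, mean
        changes smaller than it are flagged as within measurement error.
        """
        y = self.model._y
        rows = []
        for ki, name in enumerate(self.model.interventions):
            pre, post = y[:, 0, ki], y[:, 1, ki]
            change = post - pre
            if np.allclose(change, 0):
                t_stat, p = 0.0, 1.0
            else:
                res = spstats.ttest_rel(post, pre)
                t_stat, p = float(res.statistic), float(res.pvalue)
            row = {
                "intervention": name,
                "pre_mean": pre.mean(),
                "post_mean": post.mean(),
                "mean_change": change.mean(),
                "pct_change": 100.0 * change.mean() / pre.mean(),
                "t": t_stat,
                "p": p,
            }
            if mdc_threshold is not None:
                row["within_measurement_error"] = bool(
                    abs(change.mean()) < mdc_threshold
                )
            rows.append(row)
        return pd.DataFrame(rows).set_index("intervention")

    def summary(self) -> str:
        lines = [
            f"Crossover repeated-measures ANOVA on {self.model.outcome!r}",
            f"  subjects: {self.model.n_subjects}, "
            f"time levels: {self.model.times}, "
            f"interventions: {self.model.interventions}",
            "",
            self.anova_table.to_string(float_format=lambda v: f"{v:.4g}"),
            "",
            "Interaction contrasts (change scores):",
            self.interaction_contrasts().to_string(float_format=lambda v: f"{v:.4g}"),
            "",
            "Simple effects (pre vs post):",
            self.simple_effects().to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


def rm_anova_2x3(dataset: pd.DataFrame, outcome: str, **kwargs) -> CrossoverAnovaResults:
    """Convenience wrapper: build and fit :class:`CrossoverAnova`."""
    return CrossoverAnova(dataset, outcome, **kwargs).fit()


def interaction_contrasts(dataset: pd.DataFrame, outcome: str, **kwargs) -> pd.DataFrame:
    return CrossoverAnova(dataset, outcome, **kwargs).fit().interaction_contrasts()


def simple_effects(
    dataset: pd.DataFrame, outcome: str, mdc_threshold=None, **kwargs
) -> pd.DataFrame:
    return (
        CrossoverAnova(dataset, outcome, **kwargs).fit().simple_effects(mdc_threshold)
    )


def effect_size(changes_a, changes_b) -> float:
    """Standardized between-intervention effect size.

    Difference of mean change scores divided by the pooled (n-1 weighted)
    SD of the change scores.
    """
    a = np.asarray(changes_a, dtype=float)
    b = np.asarray(changes_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 change scores per group")
    sa, sb = a.std(ddof=1), b.std(ddof=1)
    pooled = math.sqrt(
        ((len(a) - 1) * sa**2 + (len(b) - 1) * sb**2) / (len(a) + len(b) - 2)
    )
    if pooled == 0:
        raise ValueError("pooled change-score SD is zero")
    return float((a.mean() - b.mean()) / pooled)


def ks_normality(values) -> tuple[float, float]:
    """Kolmogorov-Smirnov normality test with estimated parameters.

    Because mean and SD are estimated from the sample, the Lilliefors
    correction of the p-value is used.  Returns (statistic, p).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance; normality test undefined")
    stat, p = lilliefors(x, dist="norm")
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReliabilityResult:
    """Reliability summary for a subjects x sessions measurement table."""

    icc: float  # reported form (absolute agreement by default)
    icc_ci95: tuple
    icc_consistency: float
    icc_absolute: float
    cv_percent: float
    sem: float
    mdc: float


def _two_way_mean_squares(x: np.ndarray):
    n, k = x.shape
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    msr = k * np.sum((row_m - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_m - grand) ** 2) / (k - 1)
    resid = x - row_m[:, None] - col_m[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_3_1(
    measurements,
    form: str = "absolute",
    alpha: float = 0.05,
) -> tuple[float, tuple, float, float]:
    """Single-rater two-way intraclass correlation with 95% CI.

    ``measurements`` is a subjects x sessions array with no missing cells.
    Both the consistency form (classically labelled ICC(3,1)) and the
    absolute-agreement form (which additionally penalizes session mean
    shifts) are computed; ``form`` selects which one is reported with its
    F-based confidence interval.  Returns
    (icc, (ci_low, ci_high), icc_consistency, icc_absolute).
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2:
        raise ValueError("measurements must be 2-D (subjects x sessions)")
    if np.isnan(x).any():
        bad = np.argwhere(np.isnan(x))
        raise ValueError(f"missing cells at (subject, session): {bad.tolist()[:10]}")
    n, k = x.shape
    if k < 2 or n < 5:
        raise ValueError("need >= 2 sessions and >= 5 subjects")
    msr, msc, mse = _two_way_mean_squares(x)

    icc_c = (msr - mse) / (msr + (k - 1) * mse)
    icc_a = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))

    if form == "consistency":
        icc = icc_c
        f_obs = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / spstats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * spstats.f.ppf(1 - alpha / 2, df2, df1)
        ci = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
    elif form == "absolute":
        icc = icc_a
        # Satterthwaite df for the absolute-agreement CI (McGraw & Wong)
        a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
        b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
        if np.isinf(a):
            ci = (1.0, 1.0)
        else:
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f1 = spstats.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = spstats.f.ppf(1 - alpha / 2, v, n - 1)
            lower = n * (msr - f1 * mse) / (
                f1 * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            upper = n * (f2 * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f2 * msr
            )
            ci = (float(lower), float(upper))
    else:
        raise ValueError("form must be 'absolute' or 'consistency'")
    return float(icc), ci, float(icc_c), float(icc_a)


def cv_percent(measurements) -> float:
    """Mean within-subject coefficient of variation, in percent."""
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("measurements must be subjects x (>=2) repeats")
    means = x.mean(axis=1)
    if np.any(means == 0):
        raise ValueError("zero subject mean; CV undefined")
    return float(np.mean(x.std(axis=1, ddof=1) / np.abs(means)) * 100.0)


def sem_from_icc(pooled_sd: float, icc: float) -> float:
    """Standard error of measurement: pooled SD * sqrt(1 - ICC)."""
    if pooled_sd < 0:
        raise ValueError("pooled SD must be non-negative")
    if not -1 <= icc <= 1:
        raise ValueError("ICC out of range")
    return float(pooled_sd * math.sqrt(max(1.0 - icc, 0.0)))


def mdc(sem: float) -> float:
    """Minimal detectable change at 95% confidence: SEM * 1.96 * sqrt(2)."""
    if sem < 0:
        raise ValueError("SEM must be non-negative")
    return float(sem * 1.96 * math.sqrt(2.0))


def reliability(measurements, form: str = "absolute") -> ReliabilityResult:
    """Full reliability summary (ICC, CV, SEM, MDC) for repeated measures."""
    x = np.asarray(measurements, dtype=float)
    icc, ci, icc_c, icc_a = icc_3_1(x, form=form)
    pooled_sd = float(np.sqrt(x.var(axis=0, ddof=1).mean()))
    sem = sem_from_icc(pooled_sd, icc)
    return ReliabilityResult(icc, ci, icc_c, icc_a, cv_percent(x), sem, mdc(sem))


# ---------------------------------------------------------------------------
# design utilities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleSizeResult:
    n: int
    formula: str


def crossover_sample_size(
    es: float,
    alpha: float = 0.05,
    power: float = 0.8,
    correlation: float = 0.2,
) -> SampleSizeResult:
    """Paired-design sample size by the normal approximation.

    n = (z_{1-alpha/2} + z_{1-beta})^2 * 2 * (1 - rho) / ES^2, rounded up,
    with a floor of 2 subjects.  The formula is reported with the result so
    the convention in use is explicit.
    """
    if es <= 0:
        raise ValueError("effect size must be positive")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    if not abs(correlation) < 1:
        raise ValueError("|correlation| must be < 1")
    z_a = spstats.norm.ppf(1 - alpha / 2)
    z_b = spstats.norm.ppf(power)
    n = (z_a + z_b) ** 2 * 2.0 * (1.0 - correlation) / es**2
    return SampleSizeResult(
        max(int(math.ceil(n)), 2),
        "n = (z_{1-a/2} + z_{1-b})^2 * 2 * (1 - rho) / ES^2",
    )


def relative_difference_percent(change_ref: float, change_other: float) -> float:
    """How much larger (percent) the reference change is than another change.

    Magnitudes are compared, so the direction of each change does not
    matter: 100 * (|ref| - |other|) / |ref|.
    """
    if change_ref == 0:
        raise ValueError("reference change is zero")
    return float(100.0 * (abs(change_ref) - abs(change_other)) / abs(change_ref))


def simulate_null_interaction_pvalues(
    n_reps: int,
    n_subjects: int = 16,
    n_time: int = 2,
    n_interventions: int = 3,
    subject_sd: float = 1.0,
    noise_sd: float = 1.0,
    seed: int | None = 0,
) -> np.ndarray:
    """Interaction p-values under a compound-symmetric null (no effects).

    Each replicate draws a subject random effect plus i.i.d. Gaussian noise
    and computes the time-by-intervention interaction test; useful for
    checking the type-I error of the ANOVA implementation.
    """
    rng = np.random.default_rng(seed)
    shape = (n_reps, n_subjects, n_time, n_interventions)
    y = rng.normal(0.0, noise_sd, shape) + rng.normal(
        0.0, subject_sd, (n_reps, n_subjects, 1, 1)
    )
    return _rm_anova_core(y)["time:intervention"]["p"]
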