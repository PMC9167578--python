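"""Crossover ANOVA, contrasts, effect sizes, reliability and design utilities."""

import numpy as np
import pandas as pd
import pytest

from tendonmech import stats, synthgen
from tendonmech.stats import (
    CrossoverAnova,
    crossover_sample_size,
    cv_percent,
    effect_size,
    icc_3_1,
    ks_normality,
    mdc,
    relative_difference_percent,
    reliability,
    sem_from_icc,
)


class TestCrossoverAnova:
    def test_interaction_df_2x3_n16(self, crossover_dataset):
        res = CrossoverAnova(crossover_dataset, "volume_ml").fit()
        assert (res.interaction.df_num, res.interaction.df_den) == (2, 30)

    def test_matches_statsmodels_anovarm_exactly(self, crossover_dataset):
        from statsmodels.stats.anova import AnovaRM

        mine = CrossoverAnova(crossover_dataset, "stiffness_Nmm").fit()
        ref = AnovaRM(
            crossover_dataset, "stiffness_Nmm", "subject",
            within=["time", "intervention"],
        ).fit().anova_table
        for effect in ("time", "intervention", "time:intervention"):
            assert mine.effects[effect].F == pytest.approx(
                ref.loc[effect, "F Value"], rel=1e-10
            )
            assert mine.effects[effect].p == pytest.approx(
                ref.loc[effect, "Pr > F"], rel=1e-8, abs=1e-12
            )

    def test_uniform_shift_gives_zero_interaction(self):
        ds = synthgen.simulate_crossover_dataset(
            10, synthgen.EffectSpec().null(), seed=3
        )
        ds.loc[ds.time == "post", "volume_ml"] += 0.5  # same shift everywhere
        res = CrossoverAnova(ds, "volume_ml").fit()
        assert res.interaction.F == pytest.approx(0.0, abs=1e-9)

    def test_missing_cell_reported(self, crossover_dataset):
        broken = crossover_dataset.drop(crossover_dataset.index[0])
        with pytest.raises(ValueError, match="S01"):
            CrossoverAnova(broken, "volume_ml")

    def test_type_i_error_near_alpha_small_mc(self):
        ps = stats.simulate_null_interaction_pvalues(400, seed=17)
        assert (ps < 0.05).mean() == pytest.approx(0.05, abs=0.03)


class TestContrastsAndSimpleEffects:
    def test_identical_changes_give_zero_estimate(self):
        ds = synthgen.simulate_crossover_dataset(
            10, synthgen.EffectSpec().null(), seed=5
        )
        ds.loc[ds.time == "post", "volume_ml"] += 0.2
        table = CrossoverAnova(ds, "volume_ml").fit().interaction_contrasts()
        np.testing.assert_allclose(table["estimate"], 0.0, atol=1e-12)

    def test_deterministic_difference(self):
        ds = synthgen.simulate_crossover_dataset(
            12, synthgen.EffectSpec().null(), seed=6
        )
        rng = np.random.default_rng(0)
        jitter = {
            s: rng.normal(0, 1e-6) for s in ds.subject.unique()
        }  # break exact ties so the paired t is defined
        for name, change in (("8s75", -0.3), ("8s35", -0.1)):
            m = (ds.time == "post") & (ds.intervention == name)
            ds.loc[m, "volume_ml"] += change
            ds.loc[m, "volume_ml"] += ds.loc[m, "subject"].map(jitter)
        table = CrossoverAnova(ds, "volume_ml").fit().interaction_contrasts()
        row = table.loc["8s35 - 8s75"]
        assert row["estimate"] == pytest.approx(0.2, abs=1e-5)
        assert row["p"] < 1e-10

    def test_contrast_antisymmetry(self, crossover_dataset):
        model = CrossoverAnova(crossover_dataset, "stiffness_Nmm")
        delta = model.fit().model.change_scores()
        a, b = delta["8s75"], delta["2s75"]
        assert (a - b).mean() == pytest.approx(-(b - a).mean())
        assert effect_size(a, b) == pytest.approx(-effect_size(b, a))

    def test_post_equals_pre_simple_effect(self):
        ds = synthgen.simulate_crossover_dataset(
            8, synthgen.EffectSpec().null(), seed=7
        )
        table = CrossoverAnova(ds, "volume_ml").fit().simple_effects()
        np.testing.assert_allclose(table["mean_change"], 0.0, atol=1e-12)
        np.testing.assert_allclose(table["p"], 1.0)

    def test_mdc_threshold_flag(self, crossover_dataset):
        table = (
            CrossoverAnova(crossover_dataset, "volume_ml")
            .fit()
            .simple_effects(mdc_threshold=0.1)
        )
        assert "within_measurement_error" in table.columns
        # the largest reduction (8s75 arm, ~0.3 ml) exceeds a 0.1 ml MDC
        assert not table.loc["8s75", "within_measurement_error"]

    def test_summary_renders(self, crossover_dataset):
        text = CrossoverAnova(crossover_dataset, "volume_ml").fit().summary()
        assert "time:intervention" in text and "Simple effects" in text


class TestEffectSize:
    def test_closed_form_two(self):
        a = np.array([-0.4, -0.3, -0.2])  # mean -0.3, sd 0.1
        b = np.array([-0.2, -0.1, 0.0])  # mean -0.1, sd 0.1
        assert abs(effect_size(a, b)) == pytest.approx(2.0, rel=1e-12)

    def test_identical_distributions_zero(self):
        a = np.array([0.1, 0.3, 0.5])
        assert effect_size(a, a) == 0.0

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        assert effect_size(a + 5.0, b + 5.0) == pytest.approx(effect_size(a, b))

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            effect_size(np.ones(3), np.ones(3))


class TestKsNormality:
    def test_gaussian_samples_mostly_pass(self):
        rng = np.random.default_rng(0)
        passes = sum(
            ks_normality(rng.normal(size=200))[1] > 0.05 for _ in range(40)
        )
        assert passes >= 36  # >= 90%

    def test_exponential_samples_mostly_fail(self):
        rng = np.random.default_rng(1)
        rejects = sum(
            ks_normality(rng.exponential(size=200))[1] < 0.05 for _ in range(40)
        )
        assert rejects >= 36

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            ks_normality(np.ones(10))


class TestIcc:
    def test_perfect_agreement(self):
        x = np.tile(np.arange(10.0)[:, None], (1, 3))
        icc, ci, icc_c, icc_a = icc_3_1(x)
        assert icc == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(200, 2))
        icc, *_ = icc_3_1(x)
        assert abs(icc) < 0.1

    def test_variance_components_recovered(self):
        rng = np.random.default_rng(8)
        n = 500
        x = rng.normal(0, 3, (n, 1)) + rng.normal(0, 1, (n, 2))
        icc, *_ = icc_3_1(x, form="consistency")
        assert icc == pytest.approx(0.9, abs=0.03)

    def test_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(9)
        x = rng.normal(0, 3, (20, 1)) + rng.normal(0, 1, (20, 3))
        icc, ci, icc_c, icc_a = icc_3_1(x, form="absolute")
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(20), 3),
                "raters": np.tile(np.arange(3), 20),
                "score": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, "targets", "raters", "score").set_index("Type")
        assert icc_a == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-9)
        assert icc_c == pytest.approx(ref.loc["ICC(C,1)", "ICC"], abs=1e-9)
        np.testing.assert_allclose(ci, ref.loc["ICC(A,1)", "CI95"], atol=5e-3)

    def test_missing_cells_rejected(self):
        x = np.ones((6, 2))
        x[2, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            icc_3_1(x)

    def test_too_small_design_rejected(self):
        with pytest.raises(ValueError):
            icc_3_1(np.ones((3, 2)))


class TestCvSemMdc:
    def test_identical_repeats_zero_cv(self):
        assert cv_percent(np.tile([[5.0, 5.0]], (6, 1))) == 0.0

    def test_two_point_cv(self):
        x = np.tile([[90.0, 110.0]], (5, 1))
        assert cv_percent(x) == pytest.approx(100 * np.sqrt(200.0) / 100.0, rel=1e-9)

    def test_cv_scale_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(50, 150, (8, 3))
        assert cv_percent(3.7 * x) == pytest.approx(cv_percent(x))

    def test_mdc_formula(self):
        assert mdc(1.0) == pytest.approx(1.96 * np.sqrt(2.0))
        assert mdc(0.0) == 0.0
        assert mdc(2.5) == pytest.approx(2.5 * mdc(1.0))

    def test_negative_sem_rejected(self):
        with pytest.raises(ValueError):
            mdc(-1.0)

    def test_sem_from_icc(self):
        assert sem_from_icc(10.0, 0.91) == pytest.approx(3.0)

    def test_reliability_bundle_internally_consistent(self):
        rng = np.random.default_rng(6)
        x = rng.normal(100, 10, (30, 1)) + rng.normal(0, 2, (30, 3))
        res = reliability(x)
        assert res.mdc == pytest.approx(res.sem * 1.96 * np.sqrt(2.0), rel=1e-12)
        assert -1 <= res.icc <= 1
        assert res.icc == res.icc_absolute


class TestDesignUtilities:
    def test_sample_size_example(self):
        assert crossover_sample_size(1.0, 0.05, 0.8, 0.5).n == 8

    def test_high_correlation_floors_at_two(self):
        assert crossover_sample_size(1.0, 0.05, 0.8, 0.999).n == 2

    def test_monotone_in_effect_size(self):
        ns = [crossover_sample_size(es).n for es in (0.3, 0.5, 0.8, 1.2)]
        assert ns == sorted(ns, reverse=True)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            crossover_sample_size(0.0)
        with pytest.raises(ValueError):
            crossover_sample_size(0.5, correlation=1.0)

    def test_relative_difference_of_printed_changes(self):
        assert round(relative_difference_percent(67.35, 36.45)) == 46
        assert round(relative_difference_percent(67.35, 37.78)) == 44
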