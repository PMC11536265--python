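"""Transform rule, OLS engine, interaction models, thresholds, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nutrigrs import assoc_stats
from nutrigrs.assoc_stats import (
    association_analysis, bonferroni_threshold, chi_square_2x2,
    descriptive_comparisons, fat_subtype_followup, fit_linear,
    interaction_analysis, min_detectable_effect, shapiro_wilk,
    stratified_effects, transform_for_analysis,
)
from nutrigrs.diet_exposures import dichotomize_exposure, exposure_table
from nutrigrs.errors import CollinearityError, DomainError
from nutrigrs.grs import grs_table
from nutrigrs.popgen_qc import dosage_matrix


@pytest.fixture(scope="module")
def analysis_inputs(sim_default, panel):
    dosages = dosage_matrix(sim_default.genotypes, panel)
    grs_df, _ = grs_table(dosages, cutoff=6)
    exposures = exposure_table(sim_default.recalls)
    return sim_default.cohort, grs_df, exposures


# ---------------------------------------------------------------------------
# Transform rule and normality
# ---------------------------------------------------------------------------

class TestTransformRule:
    @pytest.mark.parametrize("name", ["fat_pct", "carb_pct", "mufa_pct"])
    def test_exempt_variables_unchanged(self, name):
        values, flag = transform_for_analysis(name, np.array([31.5, 28.0]))
        assert not flag
        assert values == pytest.approx([31.5, 28.0])

    @pytest.mark.parametrize("name", ["tag", "hdl", "sfa_pct", "pufa_pct", "bmi"])
    def test_other_variables_logged(self, name):
        values, flag = transform_for_analysis(name, np.array([np.e, 50.0, 100.0]))
        assert flag
        assert values == pytest.approx([1.0, np.log(50.0), np.log(100.0)])

    def test_nonpositive_value_names_sample(self):
        series = pd.Series([1.0, -2.0], index=["S1", "S2"], name="tag")
        with pytest.raises(DomainError, match="S2"):
            transform_for_analysis("tag", series)


class TestShapiroWilk:
    def test_detects_normal_and_lognormal(self):
        """Over 100 seeded replicates at n=200 the test keeps normal samples
        (p > 0.05) and rejects lognormal samples (p < 0.05) at least 90 %
        of the time each."""
        rng = np.random.default_rng(20240914)
        keep_normal = sum(
            shapiro_wilk(rng.normal(size=200))[1] > 0.05 for _ in range(100)
        )
        reject_lognormal = sum(
            shapiro_wilk(rng.lognormal(size=200))[1] < 0.05 for _ in range(100)
        )
        assert keep_normal >= 90
        assert reject_lognormal >= 90

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DomainError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(DomainError):
            shapiro_wilk([3.0] * 10)


# ---------------------------------------------------------------------------
# OLS engine
# ---------------------------------------------------------------------------

class TestFitLinear:
    def test_perfect_fit_recovers_coefficients(self):
        x = pd.DataFrame({"x": np.arange(10, dtype=float)})
        y = pd.Series(2.0 + 3.0 * x["x"])
        fit = fit_linear(y, x)
        term = fit.term("x")
        assert term["beta"] == pytest.approx(3.0, abs=1e-10)
        assert term["ci_high"] - term["ci_low"] == pytest.approx(0.0, abs=1e-8)

    def test_orthogonal_covariate_leaves_estimate_unchanged(self):
        x = pd.Series([0.0, 1.0] * 10, name="x")
        z = pd.Series([0.0, 0.0, 1.0, 1.0] * 5, name="z")
        rng = np.random.default_rng(3)
        y = pd.Series(1.0 + 2.0 * x + 3.0 * z + rng.normal(0, 0.5, 20))
        adjusted = fit_linear(y, pd.concat([x, z], axis=1)).term("x")["beta"]
        unadjusted = fit_linear(y, x.to_frame()).term("x")["beta"]
        assert adjusted == pytest.approx(unadjusted, abs=1e-9)

    def test_collinear_design_names_columns(self):
        x = pd.Series(np.arange(10, dtype=float), name="x")
        x2 = (2 * x).rename("x_twice")
        y = pd.Series(np.arange(10, dtype=float) + 1)
        with pytest.raises(CollinearityError, match="x_twice"):
            fit_linear(y, pd.concat([x, x2], axis=1))

    def test_exp_beta_populated_only_when_transformed(self):
        x = pd.DataFrame({"x": np.arange(20, dtype=float)})
        rng = np.random.default_rng(4)
        y = pd.Series(rng.normal(5, 1, 20))
        assert "exp_beta" not in fit_linear(y, x, transformed=False).terms
        fit = fit_linear(y, x, transformed=True)
        term = fit.term("x")
        assert term["exp_beta"] == pytest.approx(np.exp(term["beta"]))

    def test_nesting_interaction_t_equals_partial_f(self, analysis_inputs):
        """The product-term t-test p equals the partial-F p for adding that
        single term, and the reduced model never has higher R^2."""
        cohort, grs_df, exposures = analysis_inputs
        res = interaction_analysis(cohort, grs_df, exposures, "fat_pct",
                                   outcomes=("tag",))["tag"]
        full = res.fit
        y, flag = np.log(cohort["tag"]), True
        base = pd.DataFrame({
            "grs_high": (grs_df["grs_group"] == "high").astype(float),
            "diet": exposures["fat_pct"],
            "age": cohort["age"],
            "sex_m": (cohort["sex"] == "M").astype(float),
            "bmi": cohort["bmi"],
        })
        reduced = fit_linear(pd.Series(y), base, transformed=flag)
        assert reduced.r_squared <= full.r_squared + 1e-12
        n = full.n_used
        sse_full = (1 - full.r_squared)
        sse_red = (1 - reduced.r_squared)
        f_stat = (sse_red - sse_full) / (sse_full / full.residual_df)
        p_f = stats.f.sf(f_stat, 1, full.residual_df)
        assert res.p_interaction == pytest.approx(p_f, abs=1e-9)


# ---------------------------------------------------------------------------
# Association and interaction models on a simulated cohort
# ---------------------------------------------------------------------------

class TestAssociationAnalysis:
    def test_emits_both_group_and_scaled_fits(self, analysis_inputs):
        cohort, grs_df, _ = analysis_inputs
        results = association_analysis(cohort, grs_df)
        assert set(results) == set(assoc_stats.DEFAULT_OUTCOMES)
        for res in results.values():
            assert "grs_high" in res.group_fit.term_names
            assert "grs_scaled" in res.scaled_fit.term_names
            assert res.group_fit.transformed  # all default outcomes are logged
            assert "exp_beta" in res.group_fit.terms

    def test_group_effect_estimate_is_unbiased(self, default_config):
        """Mean high-vs-low estimate over 300 replicates is within 0.01 of
        the generative log-scale effect (0.10 on TAG)."""
        from nutrigrs.synthetic_cohort import AnalysisSpec, replicate_experiment

        spec = AnalysisSpec(kind="association", outcome="tag")
        summary = replicate_experiment(default_config.with_overrides(seed=911),
                                       300, spec)
        assert summary.true_beta == pytest.approx(0.10)
        assert abs(summary.mean_beta - 0.10) < 0.01


class TestInteractionAnalysis:
    def test_strata_partition_sample(self, analysis_inputs):
        cohort, grs_df, exposures = analysis_inputs
        labels, _ = dichotomize_exposure(exposures["fat_pct"])
        strata = stratified_effects(cohort, grs_df, labels, "tag_hdl_ratio")
        assert sum(s.n for s in strata.values()) == len(cohort)
        for s in strata.values():
            assert s.stable
            assert "grs_high" in s.fit.term_names

    def test_tiny_stratum_flagged_unstable(self, analysis_inputs):
        cohort, grs_df, exposures = analysis_inputs
        ids = cohort.index[:3]
        labels = pd.Series("high", index=cohort.index)
        labels.loc[ids] = "low"
        strata = stratified_effects(cohort, grs_df, labels, "tag")
        assert not strata["low"].stable
        assert strata["low"].fit is None

    def test_followup_gated_on_parent_significance(self, analysis_inputs):
        cohort, grs_df, exposures = analysis_inputs
        parent = interaction_analysis(cohort, grs_df, exposures, "fat_pct",
                                      outcomes=("tag",))["tag"]
        parent.p_interaction = 0.5
        assert fat_subtype_followup(cohort, grs_df, exposures, "tag", parent) == {}
        parent.p_interaction = 0.001
        followup = fat_subtype_followup(cohort, grs_df, exposures, "tag", parent)
        assert set(followup) == {"sfa_pct", "mufa_pct", "pufa_pct"}

    def test_power_increases_with_effect_and_decreases_with_noise(self):
        """Interaction-test power is ordered: larger product-term effect or
        smaller residual noise gives strictly higher rejection rates
        (200 replicates per condition, fixed seeds)."""
        import dataclasses
        from nutrigrs.synthetic_cohort import (
            AnalysisSpec, SimulationConfig, _default_effects,
            replicate_experiment,
        )

        def rate(beta, sd_scale):
            effects = _default_effects()
            tag = effects["tag"]
            effects["tag"] = dataclasses.replace(
                tag, beta_interaction=beta, residual_sd=tag.residual_sd * sd_scale
            )
            cfg = SimulationConfig(seed=777, effects=effects)
            return replicate_experiment(cfg, 200, AnalysisSpec(outcome="tag")
                                        ).rejection_rate

        weak, strong, strong_noisy = rate(0.05, 1.0), rate(0.14, 1.0), rate(0.05, 2.0)
        assert strong > weak > strong_noisy


class TestSignalLocalisation:
    def test_sfa_interaction_localises_to_sfa(self):
        """When only SFA carries the product-term effect, its screen p-value
        is the smallest of the three fat subtypes in >= 90 % of 200
        replicates."""
        import dataclasses
        from nutrigrs.synthetic_cohort import (
            SimulationConfig, _default_effects, simulate_cohort,
        )

        effects = _default_effects()
        effects["tag"] = dataclasses.replace(effects["tag"], beta_interaction=1.0)
        cfg = SimulationConfig(seed=555, effects=effects, diet_exposure="sfa_pct")
        seeds = np.random.SeedSequence(555).generate_state(200, dtype=np.uint32) % 2**31
        wins = 0
        for seed in seeds:
            sim = simulate_cohort(cfg.with_overrides(seed=int(seed)))
            dosages = dosage_matrix(sim.genotypes, cfg.panel)
            grs_df, _ = grs_table(dosages, cutoff=6)
            exposures = exposure_table(sim.recalls)
            p = {
                sub: interaction_analysis(sim.cohort, grs_df, exposures, sub,
                                          outcomes=("tag",))["tag"].p_interaction
                for sub in ("sfa_pct", "mufa_pct", "pufa_pct")
            }
            wins += p["sfa_pct"] < p["mufa_pct"] and p["sfa_pct"] < p["pufa_pct"]
        assert wins >= 180


# ---------------------------------------------------------------------------
# Thresholds, descriptives, power calculator
# ---------------------------------------------------------------------------

class TestBonferroni:
    @pytest.mark.parametrize("n_tests,display", [(7, 0.007), (21, 0.002), (1, 0.05)])
    def test_thresholds(self, n_tests, display):
        thr = bonferroni_threshold(0.05, n_tests)
        assert thr.display == pytest.approx(display, abs=5e-4)
        assert thr.raw * n_tests == pytest.approx(0.05, abs=1e-15)

    def test_invalid_test_count_rejected(self):
        with pytest.raises(DomainError):
            bonferroni_threshold(0.05, 0)


class TestDescriptives:
    def test_identical_groups_give_null_t(self):
        data = pd.DataFrame({"v": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]},
                            index=list("abcdef"))
        group = pd.Series(["x"] * 3 + ["y"] * 3, index=data.index)
        table = descriptive_comparisons(data, group, variables=["v"])
        assert table.loc[0, "t"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc[0, "p"] == pytest.approx(1.0)

    def test_pooled_variance_t(self):
        # hand pooled-variance oracle: means 13 vs 23, each SS = 20,
        # s_p^2 = 40/6, se = sqrt(s_p^2 * 1/2), t = -10/se, df = 6
        a, b = [10.0, 12.0, 14.0, 16.0], [20.0, 22.0, 24.0, 26.0]
        data = pd.DataFrame({"v": a + b}, index=list("abcdefgh"))
        group = pd.Series(["x"] * 4 + ["y"] * 4, index=data.index)
        table = descriptive_comparisons(data, group, variables=["v"])
        s2p = 40.0 / 6.0
        t_hand = -10.0 / np.sqrt(s2p * 0.5)
        p_hand = 2 * stats.t.sf(abs(t_hand), df=6)
        assert table.loc[0, "t"] == pytest.approx(t_hand, abs=1e-9)
        assert table.loc[0, "p"] == pytest.approx(p_hand, abs=1e-12)

    def test_chi_square_independence(self):
        chi2, p = chi_square_2x2([[50, 50], [50, 50]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)


class TestMinDetectableEffect:
    def test_doubling_n_divides_by_sqrt2(self):
        b1 = min_detectable_effect(190, 0.3, 30.0)
        b2 = min_detectable_effect(380, 0.3, 30.0)
        assert b1 / b2 == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_maf_ratio_closed_form(self):
        """beta_min(maf 0.05) / beta_min(maf 0.5) = sqrt(0.5/0.095) for any
        n and residual SD."""
        ratio = (min_detectable_effect(190, 0.05, 30.0)
                 / min_detectable_effect(190, 0.5, 30.0))
        assert ratio == pytest.approx(np.sqrt(0.5 / 0.095), abs=1e-12)
        assert ratio == pytest.approx(2.294, abs=1e-3)

    def test_ratio_propagation(self):
        """Choosing the residual SD so the common-variant bound is 2.9 mg/dl
        at n=190 puts the rare-variant (maf 0.05) bound near 6.65 mg/dl."""
        z = stats.norm.ppf(0.975) + stats.norm.ppf(0.80)
        sd = 2.9 * np.sqrt(190 * 0.5) / z
        assert min_detectable_effect(190, 0.5, sd) == pytest.approx(2.9, abs=1e-9)
        assert min_detectable_effect(190, 0.05, sd) == pytest.approx(6.65, abs=0.01)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DomainError):
            min_detectable_effect(190, 0.0, 30.0)
        with pytest.raises(DomainError):
            min_detectable_effect(190, 0.3, 30.0, power=1.5)
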