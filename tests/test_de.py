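import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bloodtrace import (
    CountMatrix,
    SimConfig,
    apply_contrast,
    empirical_bayes_moderation,
    fit_gene_models,
    no_moderation,
    run_subcomparisons,
    simulate_diagnostic_cohort,
    voom_weights,
)
from bloodtrace.de import build_diagnostic_design, check_full_rank
from bloodtrace.preprocess import log2_rpm


def _null_counts(n_genes, n_samples, seed=0):
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.normal(3.0, 1.0, n_genes))
    phi = 0.05 + 2.0 / mu
    r = 1.0 / phi
    mean = mu[:, None] * np.ones(n_samples)
    counts = rng.negative_binomial(r[:, None] * np.ones(n_samples), (r / (r + mu))[:, None] * np.ones(n_samples))
    return CountMatrix(
        pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)], columns=[f"s{i}" for i in range(n_samples)])
    )


class TestVoomWeights:
    def test_identical_count_rows_get_identical_weights(self, two_group_design):
        rng = np.random.default_rng(0)
        base = rng.poisson(50, (20, 6))
        base[5] = base[3]
        cm = CountMatrix(pd.DataFrame(base, columns=two_group_design.index))
        vf = voom_weights(cm, two_group_design)
        np.testing.assert_allclose(vf.weights[5], vf.weights[3])

    def test_weights_match_independent_interpolation_oracle(self, two_group_design):
        cm = _null_counts(20, 6, seed=1)
        cm = CountMatrix(cm.counts.set_axis(two_group_design.index, axis=1))
        vf = voom_weights(cm, two_group_design)
        # oracle: refit each gene by plain lstsq on log2-RPM, map fitted
        # values to the log2-count scale, interpolate the trend, power -4
        y = log2_rpm(cm).values.to_numpy()
        X = two_group_design.to_numpy()
        lib = cm.library_sizes.to_numpy(dtype=float)
        for gi in range(20):
            beta, *_ = np.linalg.lstsq(X, y[gi], rcond=None)
            fitted_logcount = X @ beta + np.log2(lib + 1) - np.log2(1e6)
            pred = np.interp(fitted_logcount, vf.trend_x, vf.trend_y)
            np.testing.assert_allclose(vf.weights[gi], pred**-4.0, rtol=1e-10)

    def test_rank_deficient_design_rejected_with_column_names(self, two_group_design):
        cm = _null_counts(15, 6)
        bad = two_group_design.copy()
        bad["dup"] = bad["group"]
        with pytest.raises(ValueError, match="dup"):
            voom_weights(CountMatrix(cm.counts.set_axis(bad.index, axis=1)), bad)

    def test_too_few_genes_rejected(self, two_group_design):
        cm = _null_counts(5, 6)
        with pytest.raises(ValueError, match="10 genes"):
            voom_weights(CountMatrix(cm.counts.set_axis(two_group_design.index, axis=1)), two_group_design)


class TestFitGeneModels:
    def test_intercept_only_equals_weighted_mean(self):
        y = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["g"])
        w = np.array([[1.0, 1.0, 2.0, 4.0]])
        design = pd.DataFrame({"intercept": np.ones(4)})
        fits = fit_gene_models(y, w, design)
        expected = np.average(y.to_numpy()[0], weights=w[0])
        assert fits.coefficients[0, 0] == pytest.approx(expected)

    def test_two_group_coefficient_is_difference_of_means(self, two_group_design):
        vals = np.array([[1.0, 2.0, 3.0, 7.0, 8.0, 9.0]])
        y = pd.DataFrame(vals, columns=two_group_design.index)
        fits = fit_gene_models(y, None, two_group_design)
        assert fits.coefficients[0, 1] == pytest.approx(8.0 - 2.0)
        # residual variance: pooled within-group
        assert fits.s2[0] == pytest.approx(np.array([1, 2, 3]).var(ddof=1) * 2 * 2 / 4)

    def test_zero_residual_gene_has_zero_s2(self, two_group_design):
        y = pd.DataFrame([[0.0, 0.0, 0.0, 5.0, 5.0, 5.0]], columns=two_group_design.index)
        fits = fit_gene_models(y, None, two_group_design)
        assert fits.s2[0] == pytest.approx(0.0, abs=1e-20)

    def test_overparameterized_rejected(self):
        y = pd.DataFrame(np.ones((3, 2)))
        design = pd.DataFrame(np.eye(2))
        with pytest.raises(ValueError):
            fit_gene_models(y, None, design)


class TestEmpiricalBayes:
    def test_identical_variances_hit_infinite_prior_branch(self):
        mod = empirical_bayes_moderation(np.full(100, 2.5), np.full(100, 10.0))
        assert np.isinf(mod.d0)
        np.testing.assert_allclose(mod.s2_post, 2.5, rtol=1e-6)

    def test_posterior_is_convex_combination(self):
        rng = np.random.default_rng(5)
        s2 = rng.chisquare(6, 500) / 6
        mod = empirical_bayes_moderation(s2, 6.0)
        lo = np.minimum(s2, mod.s0_sq) - 1e-12
        hi = np.maximum(s2, mod.s0_sq) + 1e-12
        assert ((mod.s2_post >= lo) & (mod.s2_post <= hi)).all()

    def test_parameter_recovery_quick(self):
        # scaled-inverse-chi-square truth (d0 = 4, s0^2 = 2), observed via chi2(df)
        rng = np.random.default_rng(42)
        d0, s0sq, df, n = 4.0, 2.0, 10, 4000
        sigma2 = d0 * s0sq / rng.chisquare(d0, n)
        s2 = sigma2 * rng.chisquare(df, n) / df
        mod = empirical_bayes_moderation(s2, float(df))
        assert mod.d0 == pytest.approx(4.0, abs=0.8)
        assert mod.s0_sq == pytest.approx(2.0, abs=0.3)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            empirical_bayes_moderation([-1.0, 2.0], 5.0)
        with pytest.raises(ValueError):
            empirical_bayes_moderation([1.0, 2.0], 0.5)


class TestApplyContrast:
    def _fits(self, two_group_design, seed=0):
        rng = np.random.default_rng(seed)
        y = pd.DataFrame(rng.normal(5, 1, (30, 6)), columns=two_group_design.index)
        return fit_gene_models(y, None, two_group_design)

    def test_unit_contrast_picks_coefficient(self, two_group_design):
        fits = self._fits(two_group_design)
        mod = no_moderation(fits)
        res = apply_contrast(fits, mod, [0, 1])
        np.testing.assert_allclose(res["logFC"], fits.coefficients[:, 1])

    def test_negated_contrast_flips_sign_keeps_p(self, two_group_design):
        fits = self._fits(two_group_design)
        mod = no_moderation(fits)
        a = apply_contrast(fits, mod, [0, 1])
        b = apply_contrast(fits, mod, [0, -1])
        np.testing.assert_allclose(a["logFC"], -b["logFC"])
        np.testing.assert_allclose(a["P.Value"], b["P.Value"])

    def test_zero_contrast_rejected(self, two_group_design):
        fits = self._fits(two_group_design)
        with pytest.raises(ValueError):
            apply_contrast(fits, no_moderation(fits), [0, 0])

    def test_unmoderated_pipeline_equals_ols_t_test(self, two_group_design):
        # oracle equivalence: with unit weights and d0 = 0 the moderated t
        # reduces to the classical pooled two-sample t-test, gene by gene
        fits = self._fits(two_group_design, seed=3)
        res = apply_contrast(fits, no_moderation(fits), [0, 1])
        y = None
        rng = np.random.default_rng(3)
        y = rng.normal(5, 1, (30, 6))
        t_or, p_or = stats.ttest_ind(y[:, 3:], y[:, :3], axis=1, equal_var=True)
        np.testing.assert_allclose(res["t"], t_or, rtol=1e-10)
        np.testing.assert_allclose(res["P.Value"], p_or, rtol=1e-10)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(9)
        n = 12
        design = pd.DataFrame({"intercept": np.ones(n), "group": np.r_[np.ones(6), np.zeros(6)]})
        y = pd.DataFrame(rng.normal(0, 1, (5000, n)))
        fits = fit_gene_models(y, None, design)
        mod = empirical_bayes_moderation(fits.s2, fits.df_residual)
        res = apply_contrast(fits, mod, [0, 1])
        ks = stats.kstest(res["P.Value"], "uniform")
        assert ks.pvalue > 0.01


class TestSubcomparisons:
    def test_missing_sclc_skips_that_contrast_only(self, small_cohort):
        counts, ann, _, _ = small_cohort
        ann2 = ann.copy()
        ann2.loc[ann2["histology"] == "SCLC", "histology"] = "AD"
        with pytest.warns(UserWarning, match="SCLC_vs_NSCLC"):
            res = run_subcomparisons(counts, ann2)
        assert "SCLC_vs_NSCLC" not in res
        assert "case_vs_falsepos" in res and "late_vs_falsepos" in res

    def test_planted_genes_rank_above_null(self, small_cohort):
        counts, ann, truth, _ = small_cohort
        res = run_subcomparisons(counts, ann)["case_vs_falsepos"]
        ranks = res["P.Value"].rank()
        planted_rank = ranks[res["gene_id"].isin(truth.de_gene_ids)].median()
        null_rank = ranks[~res["gene_id"].isin(truth.de_gene_ids)].median()
        assert planted_rank < null_rank / 4

    def test_relabeling_swaps_logfc_sign(self, small_cohort):
        counts, ann, _, _ = small_cohort
        res_a = run_subcomparisons(counts, ann)["case_vs_falsepos"]
        flipped = ann.copy()
        flipped["case_status"] = np.where(flipped["case_status"] == "case", "control", "case")
        # stage/histology must follow the new "cases"
        flipped["stage"] = pd.NA
        flipped["histology"] = pd.NA
        res_b = run_subcomparisons(counts, flipped)["case_vs_falsepos"]
        corr = np.corrcoef(res_a["logFC"], res_b["logFC"])[0, 1]
        assert corr < -0.95

    def test_design_is_full_rank(self, small_cohort):
        _, ann, _, _ = small_cohort
        design = build_diagnostic_design(ann)
        check_full_rank(design)  # does not raise
        assert {"intercept", "case", "age_scaled", "sex_M"} <= set(design.columns)
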