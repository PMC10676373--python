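import numpy as np
import pandas as pd
import pytest

from bloodtrace import (
    SimConfig,
    log2_rpm,
    make_reference,
    simulate_cell_mixtures,
    simulate_diagnostic_cohort,
    simulate_prospective_cohorts,
    simulate_survival,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("frac_de", 1.5),
            ("n_genes", 0),
            ("window_years", 0.0),
            ("censor_rate", -0.1),
            ("survival_log_hr", float("inf")),
        ],
    )
    def test_invalid_config_rejected_naming_field(self, field, value):
        with pytest.raises(ValueError, match=field):
            SimConfig(**{field: value})


class TestDiagnosticCohort:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(n_genes=100, n_samples_per_group=10, seed=7)
        a = simulate_diagnostic_cohort(cfg)
        b = simulate_diagnostic_cohort(cfg)
        pd.testing.assert_frame_equal(a[0].counts, b[0].counts)
        pd.testing.assert_frame_equal(a[1], b[1])
        assert a[2].de_gene_ids == b[2].de_gene_ids

    def test_frac_de_zero_means_no_planted_genes(self):
        cfg = SimConfig(n_genes=50, n_samples_per_group=5, frac_de=0.0, seed=1)
        _, _, truth = simulate_diagnostic_cohort(cfg)
        assert truth.de_gene_ids == set()

    def test_planted_logfc_recovered_from_group_means(self):
        # oracle: recompute per-group mean log2RPM from the simulated counts
        cfg = SimConfig(n_genes=800, n_samples_per_group=100, frac_de=0.05, logfc_planted=1.0, seed=3)
        counts, ann, truth = simulate_diagnostic_cohort(cfg)
        expr = log2_rpm(counts).values
        is_case = (ann["case_status"] == "case").to_numpy()
        diffs = []
        for g, lfc in truth.true_logfc.items():
            # restrict to well-expressed genes where the +0.5 count offset
            # does not compress the log scale
            if counts.counts.loc[g].mean() < 30:
                continue
            d = expr.loc[g].to_numpy()[is_case].mean() - expr.loc[g].to_numpy()[~is_case].mean()
            diffs.append(d - lfc)
        assert len(diffs) > 5
        assert abs(np.mean(diffs)) < 0.1

    def test_nb_moments_match_parameterization(self):
        # variance of simulated counts follows mu + phi(mu) mu^2
        from bloodtrace.simulate import _nb_counts

        rng = np.random.default_rng(0)
        for mu, phi in [(5.0, 0.45), (50.0, 0.09), (500.0, 0.054)]:
            draws = _nb_counts(rng, np.full(10_000, mu), np.full(10_000, phi))
            assert draws.mean() == pytest.approx(mu, rel=0.05)
            assert draws.var() == pytest.approx(mu + phi * mu**2, rel=0.15)


class TestProspectiveCohorts:
    def test_controls_have_no_time_to_diagnosis(self):
        cfg = SimConfig(n_genes=50, seed=2, n_prospective_intensity=(20, 20), n_prospective_count=(10, 10))
        _, _, ann, _ = simulate_prospective_cohorts(cfg)
        ctrl = ann[ann["case_status"] == "control"]
        assert ctrl["time_to_dx_years"].isna().all()
        cases = ann[ann["case_status"] == "case"]
        assert (cases["time_to_dx_years"] > 0).all()
        assert (cases["time_to_dx_years"] <= cfg.max_ttd_years).all()

    def test_zero_amplitude_leaves_window_flat(self):
        cfg = SimConfig(n_genes=60, trend_amplitude=0.0, seed=4,
                        n_prospective_intensity=(150, 20), n_prospective_count=(5, 5))
        inten, _, ann, truth = simulate_prospective_cohorts(cfg)
        g = sorted(truth.trend_gene_ids)[0]
        sub = ann[ann["study"] == "prosp_intensity"]
        cases = sub[sub["case_status"] == "case"]
        vals = inten.values.loc[g, cases["sample_id"]].to_numpy()
        ttd = cases["time_to_dx_years"].to_numpy()
        inside = vals[ttd <= 2.0].mean()
        outside = vals[ttd > 2.0].mean()
        assert abs(inside - outside) < 0.3  # Monte-Carlo noise only

    def test_planted_ramp_matches_expected_elevation(self):
        # oracle: mean elevation implied by the drawn times vs the matrix
        cfg = SimConfig(n_genes=60, trend_amplitude=1.0, trend_noise_sd=0.3, seed=5,
                        n_prospective_intensity=(400, 20), n_prospective_count=(5, 5))
        inten, _, ann, truth = simulate_prospective_cohorts(cfg)
        g = sorted(truth.trend_gene_ids)[0]
        sub = ann[ann["study"] == "prosp_intensity"]
        cases = sub[sub["case_status"] == "case"]
        vals = inten.values.loc[g, cases["sample_id"]].to_numpy()
        ttd = cases["time_to_dx_years"].to_numpy()
        observed = vals[ttd <= 2.0].mean() - vals[ttd > 2.0].mean()
        expected = np.clip(1.0 - ttd[ttd <= 2.0] / 2.0, 0, 1).mean() * cfg.trend_amplitude
        assert observed == pytest.approx(expected, abs=0.15)

    def test_two_modalities_reported(self):
        cfg = SimConfig(n_genes=30, seed=6, n_prospective_intensity=(5, 5), n_prospective_count=(5, 5))
        inten, cnt, _, _ = simulate_prospective_cohorts(cfg)
        assert inten.modality == "microarray"
        assert cnt.modality == "rnaseq"


class TestCellMixtures:
    def test_proportions_on_simplex(self):
        ref = make_reference(0)
        cfg = SimConfig(n_genes=10, n_samples_per_group=20, seed=1)
        _, _, _, truth = simulate_cell_mixtures(ref, cfg)
        np.testing.assert_allclose(truth.proportions.sum(axis=1), 1.0, atol=1e-12)
        assert (truth.proportions.to_numpy() >= 0).all()

    def test_case_shift_recovered_from_truth(self):
        ref = make_reference(0)
        cfg = SimConfig(n_genes=10, n_samples_per_group=300, case_neutrophil_shift=0.08, seed=2)
        _, _, ann, truth = simulate_cell_mixtures(ref, cfg)
        is_case = (ann["case_status"] == "case").to_numpy()
        diff = (
            truth.proportions.loc[is_case, "Neutrophil"].mean()
            - truth.proportions.loc[~is_case, "Neutrophil"].mean()
        )
        assert diff == pytest.approx(0.08, abs=0.01)

    def test_rank_deficient_reference_rejected(self):
        ref = make_reference(0)
        bad = ref.copy()
        bad["CD8T"] = bad["CD4T"]
        cfg = SimConfig(n_genes=10, seed=0)
        with pytest.raises(ValueError, match="rank"):
            simulate_cell_mixtures(bad, cfg)

    def test_methylation_modality_in_unit_interval(self):
        ref = make_reference(1)
        cfg = SimConfig(n_genes=10, n_samples_per_group=10, seed=3)
        _, meth, _, _ = simulate_cell_mixtures(ref, cfg)
        assert meth.to_numpy().min() >= 0.0
        assert meth.to_numpy().max() <= 1.0


class TestSurvival:
    def test_censor_rate_zero_observes_all_events(self, small_cohort):
        counts, ann, truth, cfg = small_cohort
        cfg0 = SimConfig(**{**cfg.__dict__, "censor_rate": 0.0})
        out = simulate_survival(ann, truth, cfg0)
        cases = out[out["case_status"] == "case"]
        assert (cases["event"] == 1).all()

    def test_null_hazard_gives_similar_groups(self, small_cohort):
        import copy

        counts, ann, truth, cfg = small_cohort
        cfg0 = SimConfig(**{**cfg.__dict__, "survival_log_hr": 0.0, "censor_rate": 0.0})
        truth = copy.deepcopy(truth)
        truth.log_hazard_coefs = {"high_expr": 0.0}
        out = simulate_survival(ann, truth, cfg0)
        cases = out[out["case_status"] == "case"]
        hi = truth.hazard_indicator.reindex(cases["sample_id"]).to_numpy() == 1
        t = cases["survival_time"].to_numpy(dtype=float)
        # same exponential rate in both arms
        assert t[hi].mean() == pytest.approx(t[~hi].mean(), rel=0.5)

    def test_no_cases_rejected(self, small_cohort):
        counts, ann, truth, cfg = small_cohort
        ctrl_only = ann[ann["case_status"] == "control"]
        with pytest.raises(ValueError, match="cases"):
            simulate_survival(ctrl_only, truth, cfg)
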