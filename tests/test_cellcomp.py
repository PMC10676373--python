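import numpy as np
import pandas as pd
import pytest

from bloodtrace import (
    ProportionEstimates,
    ReferenceMatrix,
    SimConfig,
    celltype_association,
    cross_platform_calibrate,
    deconvolve_samples,
    make_reference,
    rpc_deconvolve,
    simulate_cell_mixtures,
)


@pytest.fixture()
def reference():
    return ReferenceMatrix(make_reference(0))


class TestRpcDeconvolve:
    def test_pure_column_recovered_exactly(self, reference):
        for k, ct in enumerate(reference.cell_types):
            est = rpc_deconvolve(reference.values[ct], reference)
            assert est[ct] == pytest.approx(1.0, abs=1e-8)
            assert est.drop(ct).abs().max() < 1e-8

    def test_fifty_fifty_mixture_exact(self, reference):
        cts = list(reference.cell_types[:2])
        bulk = 0.5 * reference.values[cts[0]] + 0.5 * reference.values[cts[1]]
        est = rpc_deconvolve(bulk, reference)
        assert est[cts[0]] == pytest.approx(0.5, abs=1e-6)
        assert est[cts[1]] == pytest.approx(0.5, abs=1e-6)

    def test_exact_on_arbitrary_simplex_truth(self, reference):
        rng = np.random.default_rng(1)
        p = rng.dirichlet(np.ones(len(reference.cell_types)))
        bulk = reference.values.to_numpy() @ p
        est = rpc_deconvolve(pd.Series(bulk, index=reference.values.index), reference)
        np.testing.assert_allclose(est.to_numpy(), p, atol=1e-6)

    def test_clean_data_matches_ols(self, reference):
        # with no outliers the Huber IRLS fixed point is the OLS solution
        rng = np.random.default_rng(2)
        p = rng.dirichlet(np.ones(len(reference.cell_types)) * 5)
        bulk = reference.values.to_numpy() @ p  # outlier-free: all Huber weights are 1
        X = np.column_stack([np.ones(len(bulk)), reference.values.to_numpy()])
        ols = np.linalg.lstsq(X, bulk, rcond=None)[0][1:]
        ols = np.clip(ols, 0, None)
        ols = ols / ols.sum()
        est = rpc_deconvolve(pd.Series(bulk, index=reference.values.index), reference)
        np.testing.assert_allclose(est.to_numpy(), ols, atol=1e-8)

    def test_rank_deficient_reference_rejected(self):
        ref = make_reference(0)
        ref["CD8T"] = ref["CD4T"] * 2
        with pytest.raises(ValueError, match="rank"):
            ReferenceMatrix(ref)

    def test_marker_mismatch_rejected(self, reference):
        bulk = pd.Series([1.0, 2.0], index=["nope_1", "nope_2"])
        with pytest.raises(ValueError, match="markers"):
            rpc_deconvolve(bulk, reference)


class TestCrossPlatformCalibrate:
    def _props(self, arr, cts, prefix="s"):
        return pd.DataFrame(arr, columns=cts, index=[f"{prefix}{i}" for i in range(len(arr))])

    def test_identity_mapping_when_platforms_agree(self, reference):
        rng = np.random.default_rng(0)
        cts = list(reference.cell_types)
        a = self._props(rng.dirichlet(np.ones(len(cts)) * 10, 20), cts)
        est_b = ProportionEstimates(a.copy(), "expression")
        cal, cmap = cross_platform_calibrate(est_b, a, a.copy())
        for ct in cts:
            assert cmap.spearman_r[ct] == pytest.approx(1.0)
            assert cmap.slopes[ct] == pytest.approx(1.0, abs=1e-8)
        pd.testing.assert_frame_equal(cal.fractions, a, atol=1e-10, check_exact=False)

    def test_affine_distortion_recovered_on_held_out_samples(self, reference):
        rng = np.random.default_rng(1)
        cts = list(reference.cell_types)
        truth = self._props(rng.dirichlet(np.ones(len(cts)) * 10, 40), cts)
        distorted = 0.5 * truth + 0.1
        overlap = truth.index[:25]
        held_out = truth.index[25:]
        est_b = ProportionEstimates(distorted.loc[held_out], "expression")
        cal, cmap = cross_platform_calibrate(est_b, truth.loc[overlap], distorted.loc[overlap])
        assert cal.calibrated
        np.testing.assert_allclose(
            cal.fractions.to_numpy(), truth.loc[held_out].to_numpy(), atol=1e-6
        )

    def test_too_few_overlap_refused(self, reference):
        rng = np.random.default_rng(2)
        cts = list(reference.cell_types)
        a = self._props(rng.dirichlet(np.ones(len(cts)), 5), cts)
        est_b = ProportionEstimates(a.copy(), "expression")
        with pytest.warns(UserWarning, match="refused"):
            cal, cmap = cross_platform_calibrate(est_b, a, a.copy(), min_overlap=10)
        assert not cal.calibrated

    def test_anticorrelated_platforms_warn_but_map(self, reference):
        rng = np.random.default_rng(3)
        cts = list(reference.cell_types)
        a = self._props(rng.dirichlet(np.ones(len(cts)) * 10, 15), cts)
        b = a.max().max() - a  # reversed ranks
        est_b = ProportionEstimates(b.copy(), "expression")
        with pytest.warns(UserWarning, match="anti-correlated"):
            cal, cmap = cross_platform_calibrate(est_b, a, b)
        assert all(r < 0 for r in cmap.spearman_r.values())

    def test_calibrated_rows_stay_on_simplex(self, reference):
        rng = np.random.default_rng(4)
        cts = list(reference.cell_types)
        a = self._props(rng.dirichlet(np.ones(len(cts)) * 5, 30), cts)
        b = self._props(rng.dirichlet(np.ones(len(cts)) * 5, 30), cts)
        est_b = ProportionEstimates(b.copy(), "expression")
        cal, _ = cross_platform_calibrate(est_b, a, b)
        assert (cal.fractions.to_numpy() >= 0).all()
        np.testing.assert_allclose(cal.fractions.sum(axis=1), 1.0, atol=1e-9)


class TestCelltypeAssociation:
    def test_planted_neutrophil_shift_detected(self):
        ref = make_reference(0)
        cfg = SimConfig(n_genes=10, n_samples_per_group=90, case_neutrophil_shift=0.1, seed=5)
        bulk, _, ann, truth = simulate_cell_mixtures(ref, cfg)
        props = ProportionEstimates(truth.proportions, "methylation")
        table = celltype_association(props, ann).set_index("cell_type")
        assert table.loc["Neutrophil", "OR"] > 1.0
        assert table.loc["Neutrophil", "p"] < 0.05

    def test_permuted_labels_lose_association(self):
        ref = make_reference(0)
        cfg = SimConfig(n_genes=10, n_samples_per_group=90, case_neutrophil_shift=0.1, seed=6)
        bulk, _, ann, truth = simulate_cell_mixtures(ref, cfg)
        rng = np.random.default_rng(0)
        ann_p = ann.copy()
        ann_p["case_status"] = rng.permutation(ann_p["case_status"].to_numpy())
        props = ProportionEstimates(truth.proportions, "methylation")
        orig = celltype_association(props, ann).set_index("cell_type")
        perm = celltype_association(props, ann_p).set_index("cell_type")
        assert perm.loc["Neutrophil", "p"] > orig.loc["Neutrophil", "p"]

    def test_estimates_from_deconvolution_track_truth(self):
        ref = make_reference(0)
        cfg = SimConfig(n_genes=10, n_samples_per_group=25, mixture_noise_sd=0.2, seed=7)
        bulk, _, ann, truth = simulate_cell_mixtures(ref, cfg)
        est = deconvolve_samples(bulk, ReferenceMatrix(ref))
        err = (est.fractions - truth.proportions).abs().to_numpy().max()
        assert err < 0.05

    def test_constant_proportion_column_skipped(self):
        ref = make_reference(0)
        cfg = SimConfig(n_genes=10, n_samples_per_group=20, seed=8)
        _, _, ann, truth = simulate_cell_mixtures(ref, cfg)
        frac = truth.proportions.copy()
        frac["NK"] = 0.05
        props = ProportionEstimates(frac, "methylation")
        with pytest.warns(UserWarning, match="constant"):
            table = celltype_association(props, ann)
        assert "NK" not in set(table["cell_type"])
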