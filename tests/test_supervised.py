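import numpy as np
import pandas as pd
import pytest

from mixdecon.core import ExpressionMatrix, MixDeconError, validate_proportions
from mixdecon.simulate import MixtureDesign, SignatureDesign, make_dataset
from mixdecon.supervised import (
    MrnaScalingFactors,
    SvrConfig,
    alts_deconvolve,
    fit_mrna_scaling,
    nnls_deconvolve,
    ols_deconvolve,
    rlm_deconvolve,
    svr_deconvolve,
)

from conftest import expression_from, proportions_from


def simplex_grid_oracle(S, b, step=1e-4):
    """Exhaustive search over the 2-type probability simplex."""
    p1 = np.arange(0.0, 1.0 + step / 2, step)
    P = np.vstack([p1, 1 - p1])
    resid = np.linalg.norm(S @ P - b[:, None], axis=0)
    return P[:, np.argmin(resid)]


def contaminated(ds, frac=0.05, factor=50.0, seed=11):
    rng = np.random.default_rng(seed)
    idx = rng.choice(ds.B.shape[0], size=int(frac * ds.B.shape[0]), replace=False)
    data = ds.B.data.copy()
    data.iloc[idx] *= factor
    return ExpressionMatrix(data), set(data.index[idx])


class TestNnls:
    def test_exact_two_by_two_solve(self, toy_signature):
        B = expression_from([[1.4], [2.2]], ["g1", "g2"], ["s1"])
        res = nnls_deconvolve(B, toy_signature)
        np.testing.assert_allclose(res.P_est.values[:, 0], [0.4, 0.6], atol=1e-12)

    def test_raw_solution_renormalized(self, toy_signature):
        # S^-1 b = ((3*1.5 - 2.2)/5, (-1.5 + 2*2.2)/5) = (0.46, 0.58); sum 1.04
        B = expression_from([[1.5], [2.2]], ["g1", "g2"], ["s1"])
        res = nnls_deconvolve(B, toy_signature)
        np.testing.assert_allclose(res.P_est.values[:, 0],
                                   [0.46 / 1.04, 0.58 / 1.04], atol=1e-10)

    def test_pure_sample_is_one_hot(self, toy_signature):
        B = expression_from(toy_signature.data[["t2"]].to_numpy(), ["g1", "g2"], ["s1"])
        res = nnls_deconvolve(B, toy_signature)
        np.testing.assert_allclose(res.P_est.values[:, 0], [0.0, 1.0], atol=1e-10)

    def test_matches_simplex_grid_search(self):
        rng = np.random.default_rng(21)
        S = rng.gamma(2.0, 5.0, size=(40, 2))
        p = rng.dirichlet([1, 1])
        b = S @ p
        genes = [f"g{i}" for i in range(40)]
        res = nnls_deconvolve(
            expression_from(b[:, None], genes, ["s1"]),
            _sig(S, genes, ["t1", "t2"]),
        )
        oracle = simplex_grid_oracle(S, b)
        assert np.max(np.abs(res.P_est.values[:, 0] - oracle)) < 2e-4


def _sig(values, genes, types):
    from mixdecon.core import SignatureMatrix

    return SignatureMatrix(pd.DataFrame(values, index=genes, columns=types))


class TestSvr:
    def test_noiseless_recovery_close_to_nnls(self, clean_dataset):
        ds = clean_dataset
        svr = svr_deconvolve(ds.B, ds.S_true)
        nnls = nnls_deconvolve(ds.B, ds.S_true)
        assert np.max(np.abs(svr.P_est.values - ds.P_true.values)) < 0.02
        assert np.max(np.abs(svr.P_est.values - nnls.P_est.values)) < 0.02

    def test_pure_sample_dominant_type(self, clean_dataset):
        ds = clean_dataset
        b = ds.S_true.data[["C"]].to_numpy()
        B = expression_from(b, ds.S_true.gene_ids, ["pure"])
        res = svr_deconvolve(B, ds.S_true)
        assert res.P_est.data.index[np.argmax(res.P_est.values[:, 0])] == "C"

    def test_constant_mixture_flagged_degenerate(self, toy_signature):
        B = expression_from([[5.0], [5.0]], ["g1", "g2"], ["s1"])
        res = svr_deconvolve(B, toy_signature)
        assert res.extras["degenerate_samples"] == ("s1",)
        np.testing.assert_allclose(res.P_est.values[:, 0], [0.5, 0.5])

    def test_chosen_nu_recorded_from_grid(self, clean_dataset):
        ds = clean_dataset
        cfg = SvrConfig(nu_grid=(0.25, 0.5))
        res = svr_deconvolve(ds.B, ds.S_true, cfg)
        assert set(res.extras["chosen_nu"].values()) <= {0.25, 0.5}

    def test_invalid_config_rejected(self):
        with pytest.raises(MixDeconError):
            SvrConfig(nu_grid=())
        with pytest.raises(MixDeconError):
            SvrConfig(nu_grid=(1.5,))


class TestMrnaScaling:
    def test_exact_ratio(self):
        est = proportions_from([[0.4, 0.8]], ["k"], ["s1", "s2"], mode="raw")
        true = proportions_from([[0.2, 0.4]], ["k"], ["s1", "s2"], mode="raw")
        factors = fit_mrna_scaling(est, true)
        assert factors.alpha["k"] == pytest.approx(0.5)

    def test_identity_when_estimates_match_truth(self):
        P = proportions_from([[0.3, 0.6], [0.7, 0.4]], ["a", "b"], ["s1", "s2"])
        factors = fit_mrna_scaling(P, P)
        assert all(a == pytest.approx(1.0) for a in factors.alpha.values())

    def test_ratio_clipped_to_bounds(self):
        est = proportions_from([[1.0, 1.0]], ["k"], ["s1", "s2"], mode="raw")
        true = proportions_from([[0.05, 0.05]], ["k"], ["s1", "s2"], mode="raw")
        factors = fit_mrna_scaling(est, true, bounds=(0.1, 10.0))
        assert factors.alpha["k"] == 0.1

    def test_zero_estimates_flagged_alpha_one(self):
        est = proportions_from([[0.0, 0.0]], ["k"], ["s1", "s2"], mode="raw")
        true = proportions_from([[0.5, 0.5]], ["k"], ["s1", "s2"], mode="raw")
        factors = fit_mrna_scaling(est, true)
        assert factors.alpha["k"] == 1.0 and factors.flagged_types == ("k",)


class TestRlm:
    def test_noiseless_recovery(self, clean_dataset):
        ds = clean_dataset
        res = rlm_deconvolve(ds.B, ds.S_true)
        assert np.max(np.abs(res.P_est.values - ds.P_true.values)) < 1e-6

    def test_unit_alphas_equal_unscaled_fit(self, clean_dataset):
        ds = clean_dataset
        plain = rlm_deconvolve(ds.B, ds.S_true)
        unit = rlm_deconvolve(
            ds.B, ds.S_true,
            alphas=MrnaScalingFactors({ct: 1.0 for ct in ds.S_true.cell_type_ids}),
        )
        np.testing.assert_array_equal(plain.P_est.values, unit.P_est.values)

    def test_single_inflated_gene_beats_ols(self):
        ds = make_dataset(
            SignatureDesign(n_genes=200, cell_types=("a", "b", "c"), markers_per_type=8, seed=5),
            MixtureDesign(n_samples=6, proportion_mode="dirichlet", noise_cv=0.0, seed=6),
        )
        data = ds.B.data.copy()
        data.iloc[3] *= 100  # one grossly inflated gene
        Bc = ExpressionMatrix(data)
        rlm_err = np.linalg.norm(rlm_deconvolve(Bc, ds.S_true).P_est.values - ds.P_true.values)
        ols_err = np.linalg.norm(ols_deconvolve(Bc, ds.S_true).P_est.values - ds.P_true.values)
        assert rlm_err < ols_err

    def test_alpha_scaling_changes_estimate(self, clean_dataset):
        ds = clean_dataset
        scaled = rlm_deconvolve(
            ds.B, ds.S_true,
            alphas=MrnaScalingFactors({ct: 2.0 if ct == "A" else 1.0
                                       for ct in ds.S_true.cell_type_ids}),
        )
        plain = rlm_deconvolve(ds.B, ds.S_true)
        assert not np.allclose(scaled.P_est.values, plain.P_est.values)


class TestAlts:
    def test_clean_data_matches_nnls_with_no_flags(self, clean_dataset):
        ds = clean_dataset
        res, flags = alts_deconvolve(ds.B, ds.S_true)
        base = nnls_deconvolve(ds.B, ds.S_true)
        np.testing.assert_allclose(res.P_est.values, base.P_est.values, atol=1e-12)
        assert all(len(v) == 0 for v in flags.flagged_gene_ids.values())

    def test_contaminated_genes_flagged_and_recovered(self, clean_dataset):
        ds = clean_dataset
        Bc, contam = contaminated(ds)
        res, flags = alts_deconvolve(Bc, ds.S_true)
        for sample, flagged in flags.flagged_gene_ids.items():
            assert contam <= set(flagged)
        assert np.max(np.abs(res.P_est.values - ds.P_true.values)) < 1e-3

    def test_infinite_multiplier_equals_nnls(self, clean_dataset):
        ds = clean_dataset
        Bc, _ = contaminated(ds)
        res, flags = alts_deconvolve(Bc, ds.S_true, threshold_multiplier=np.inf)
        base = nnls_deconvolve(Bc, ds.S_true)
        np.testing.assert_allclose(res.P_est.values, base.P_est.values, atol=1e-12)
        assert all(len(v) == 0 for v in flags.flagged_gene_ids.values())

    def test_runaway_trimming_aborts(self):
        # a threshold at the median of noisy residuals keeps finding "outliers"
        # until the majority is flagged; the degenerate-contamination guard
        # must abort instead of silently fitting a minority of genes
        ds = make_dataset(
            SignatureDesign(n_genes=500, cell_types=("A", "B", "C", "D", "E"),
                            markers_per_type=10, seed=3),
            MixtureDesign(n_samples=12, proportion_mode="dirichlet", noise_cv=0.3, seed=7),
        )
        with pytest.raises(MixDeconError, match="50%"):
            alts_deconvolve(ds.B, ds.S_true, threshold_multiplier=1.0, max_iter=50)

    def test_majority_contamination_follows_majority(self, clean_dataset):
        # median-based trimming breaks down past 50% contamination: the fit
        # follows the (self-consistent) contaminated majority rather than
        # flagging it, so the estimate degrades instead of aborting
        ds = clean_dataset
        Bc, contam = contaminated(ds, frac=0.7, factor=500.0)
        res, flags = alts_deconvolve(Bc, ds.S_true, max_iter=50)
        assert all(len(v) <= 0.5 * ds.B.shape[0] for v in flags.flagged_gene_ids.values())


@pytest.fixture(scope="module")
def all_results(clean_dataset):
    ds = clean_dataset
    res = {
        "nnls": nnls_deconvolve(ds.B, ds.S_true),
        "svr": svr_deconvolve(ds.B, ds.S_true),
        "rlm": rlm_deconvolve(ds.B, ds.S_true),
        "alts": alts_deconvolve(ds.B, ds.S_true)[0],
    }
    return ds, res


class TestSharedContracts:
    def test_outputs_on_simplex(self, all_results):
        _, res = all_results
        for r in res.values():
            assert validate_proportions(r.P_est, tol=1e-9).ok

    def test_pure_sample_fidelity(self, tumor_dataset):
        # one-hot truth columns must receive >= 0.95 on the true type
        ds = tumor_dataset
        methods = {
            "nnls": nnls_deconvolve(ds.B, ds.S_true),
            "svr": svr_deconvolve(ds.B, ds.S_true),
            "rlm": rlm_deconvolve(ds.B, ds.S_true),
            "alts": alts_deconvolve(ds.B, ds.S_true)[0],
        }
        for name, res in methods.items():
            for sample in ("S01", "S02"):
                assert res.P_est.data.loc["CC", sample] >= 0.95, name

    def test_residuals_recorded_per_sample(self, all_results):
        ds, res = all_results
        for r in res.values():
            assert set(r.per_sample_fit) == set(ds.B.sample_ids)
            assert all(v >= 0 for v in r.per_sample_fit.values())
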