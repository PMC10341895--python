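import numpy as np
import pytest

from mixdecon.core import ExpressionMatrix, MixDeconError, validate_proportions
from mixdecon.simulate import MixtureDesign, SignatureDesign, make_dataset
from mixdecon.unsupervised import (
    assign_components,
    ica_deconvolve,
    linseed_deconvolve,
    mutual_linearity,
)

from conftest import expression_from, proportions_from


def matched_correlations(result, P_true):
    asg = assign_components(result.P_est, reference_P=P_true)
    return asg, {asg.mapping[comp]: r for comp, r in asg.correlations.items()}


class TestIca:
    def test_recovers_exponential_sources(self):
        # two independent exponential sources mixed into four samples
        rng = np.random.default_rng(5)
        sources = rng.exponential(1.0, size=(5000, 2))
        mixing = rng.uniform(0.5, 2.0, size=(2, 4))
        B = expression_from(sources @ mixing,
                            [f"g{i}" for i in range(5000)], [f"s{j}" for j in range(4)])
        decomp, _ = ica_deconvolve(B, 2, seed=1)
        for k in range(2):
            best = max(
                abs(np.corrcoef(decomp.S_est.values[:, k], sources[:, j])[0, 1])
                for j in range(2)
            )
            assert best >= 0.95

    def test_deterministic_under_seed(self, clean_dataset):
        d1, r1 = ica_deconvolve(clean_dataset.B, 5, seed=4)
        d2, r2 = ica_deconvolve(clean_dataset.B, 5, seed=4)
        np.testing.assert_array_equal(d1.S_est.values, d2.S_est.values)
        np.testing.assert_array_equal(r1.P_est.values, r2.P_est.values)

    def test_gaussian_only_data_does_not_converge(self):
        rng = np.random.default_rng(0)
        B = expression_from(np.abs(rng.normal(100, 1, size=(2000, 8))),
                            [f"g{i}" for i in range(2000)], [f"s{j}" for j in range(8)])
        decomp, res = ica_deconvolve(B, 3, seed=0)
        assert decomp.converged is False
        assert res.extras["converged"] is False

    def test_component_count_must_be_below_samples(self, clean_dataset):
        with pytest.raises(MixDeconError):
            ica_deconvolve(clean_dataset.B, 12)

    def test_proportions_on_simplex(self, clean_dataset):
        _, res = ica_deconvolve(clean_dataset.B, 5, seed=0)
        assert validate_proportions(res.P_est, tol=1e-9).ok

    def test_skewness_oriented_positive(self, clean_dataset):
        decomp, _ = ica_deconvolve(clean_dataset.B, 5, seed=0)
        from scipy.stats import skew

        assert np.all(skew(decomp.S_est.values, axis=0) > 0)


class TestAssignComponents:
    def test_row_swap_recovered(self):
        P = proportions_from([[0.1, 0.5, 0.2], [0.9, 0.5, 0.8]], ["a", "b"],
                             ["s1", "s2", "s3"])
        swapped = proportions_from(P.values[::-1], ["c1", "c2"], P.sample_ids)
        asg = assign_components(swapped, reference_P=P)
        assert asg.mapping == {"c1": "b", "c2": "a"}

    def test_identity_assignment(self):
        P = proportions_from([[0.1, 0.5, 0.2], [0.9, 0.5, 0.8]], ["a", "b"],
                             ["s1", "s2", "s3"])
        asg = assign_components(P, reference_P=P)
        assert asg.mapping == {"a": "a", "b": "b"}
        assert all(r == pytest.approx(1.0) for r in asg.correlations.values())

    def test_noise_component_flagged_low_confidence(self):
        rng = np.random.default_rng(3)
        truth = rng.dirichlet([1, 1], size=10).T
        P_true = proportions_from(np.vstack([truth, np.full(10, 1e-9)]),
                                  ["a", "b", "junk"], [f"s{j}" for j in range(10)],
                                  mode="raw")
        est = np.vstack([truth, rng.uniform(0, 1, 10)])
        P_est = proportions_from(est, ["c1", "c2", "c3"], P_true.sample_ids, mode="raw")
        asg = assign_components(P_est, reference_P=P_true)
        assert asg.mapping["c3"] == "junk"
        assert "c3" in asg.low_confidence

    def test_marker_reference_fallback(self, clean_dataset):
        ds = clean_dataset
        asg = assign_components(ds.P_true, marker_truth=ds.marker_truth, bulk=ds.B)
        assert asg.mapping == {ct: ct for ct in ds.P_true.cell_type_ids}

    def test_size_mismatch_rejected(self):
        P2 = proportions_from([[0.4, 0.1], [0.6, 0.9]], ["a", "b"], ["s1", "s2"])
        P3 = proportions_from([[0.4, 0.1], [0.3, 0.2], [0.3, 0.7]],
                              ["a", "b", "c"], ["s1", "s2"])
        with pytest.raises(MixDeconError):
            assign_components(P2, reference_P=P3)


class TestMutualLinearity:
    def test_proportional_genes_score_one(self):
        B = expression_from([[1, 2, 3, 4], [2, 4, 6, 8], [4, 1, 5, 2]],
                            ["g1", "g2", "g3"], list("abcd"))
        graph = mutual_linearity(B, top_k_edges=1)
        assert graph.scores.loc["g1", "g2"] == pytest.approx(1.0)

    def test_orthogonal_genes_score_zero(self):
        # zero correlation by construction over 4 samples
        B = expression_from([[3, 3, 1, 1], [3, 1, 3, 1]], ["g1", "g2"], list("abcd"))
        graph = mutual_linearity(B, top_k_edges=1)
        assert graph.scores.loc["g1", "g2"] == pytest.approx(0.0, abs=1e-12)

    def test_planted_blocks_reach_max_collinearity(self, planted_marker_dataset):
        ds = planted_marker_dataset
        graph = mutual_linearity(ds.B, top_k_edges=4)
        for genes in ds.marker_truth.values():
            for g in genes:
                # 4 other markers of the same block at r^2 = 1
                assert graph.collinearity[g] == pytest.approx(4.0, abs=1e-9)

    def test_symmetric_scores_in_unit_interval(self, clean_dataset):
        graph = mutual_linearity(clean_dataset.B, top_n_genes=100)
        arr = graph.scores.to_numpy()
        np.testing.assert_allclose(arr, arr.T, atol=1e-12)
        assert arr.min() >= 0 and arr.max() <= 1

    def test_needs_three_samples(self):
        B = expression_from([[1, 2], [2, 4]], ["g1", "g2"], ["s1", "s2"])
        with pytest.raises(MixDeconError):
            mutual_linearity(B)


class TestLinseed:
    def test_planted_markers_recovered_exactly(self, planted_marker_dataset):
        ds = planted_marker_dataset
        _, res, markers = linseed_deconvolve(ds.B, 3)
        asg, _ = matched_correlations(res, ds.P_true)
        by_type = {asg.mapping[cid]: set(genes) for cid, genes in markers.items()}
        for ct, want in ds.marker_truth.items():
            assert by_type[ct] == set(want)  # precision = recall = 1

    def test_matched_rows_correlate_with_truth(self, planted_marker_dataset):
        ds = planted_marker_dataset
        _, res, _ = linseed_deconvolve(ds.B, 3)
        _, corrs = matched_correlations(res, ds.P_true)
        assert all(r >= 0.999 for r in corrs.values())

    def test_pure_cancer_samples_get_full_weight(self, tumor_dataset):
        ds = tumor_dataset
        _, res, _ = linseed_deconvolve(ds.B, 6)
        asg, _ = matched_correlations(res, ds.P_true)
        inv = {ct: comp for comp, ct in asg.mapping.items()}
        cc = res.P_est.data.loc[inv["CC"]]
        assert cc["S01"] >= 0.95 and cc["S02"] >= 0.95

    def test_scale_invariance(self, planted_marker_dataset):
        ds = planted_marker_dataset
        model1, res1, markers1 = linseed_deconvolve(ds.B, 3)
        scaled = ExpressionMatrix(ds.B.data * 7.5)
        model2, res2, markers2 = linseed_deconvolve(scaled, 3)
        assert markers1 == markers2
        np.testing.assert_allclose(model1.H_norm_est.values, model2.H_norm_est.values,
                                   atol=1e-9)

    def test_sample_permutation_equivariance(self, planted_marker_dataset):
        ds = planted_marker_dataset
        perm = ["S03", "S01", "S09", "S05", "S02", "S8" if False else "S08", "S04",
                "S07", "S06"]
        _, res1, _ = linseed_deconvolve(ds.B, 3)
        _, res2, _ = linseed_deconvolve(ExpressionMatrix(ds.B.data[perm]), 3)
        np.testing.assert_allclose(res1.P_est.data[perm].values, res2.P_est.values,
                                   atol=1e-8)

    def test_corner_search_matches_exhaustive_extremes(self):
        # c=2: corners found by successive projection must equal the exact
        # extreme points of the gene cloud along its principal axis
        ds = make_dataset(
            SignatureDesign(n_genes=40, cell_types=("a", "b"), markers_per_type=4, seed=2),
            MixtureDesign(n_samples=6, proportion_mode="dirichlet", noise_cv=0.05, seed=8),
        )
        model, _, _ = linseed_deconvolve(ds.B, 2, collinearity_quantile=0.0)
        Xn = model.X_norm.to_numpy()
        axis = Xn @ model.projection_basis
        centered = axis - axis.mean(axis=0)
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        coord = centered @ vt[0]
        extremes = {model.X_norm.index[int(np.argmin(coord))],
                    model.X_norm.index[int(np.argmax(coord))]}
        assert set(model.corner_gene_ids) == extremes

    def test_proportions_on_simplex(self, tumor_dataset):
        _, res, _ = linseed_deconvolve(tumor_dataset.B, 6)
        assert validate_proportions(res.P_est, tol=1e-9).ok

    def test_too_few_samples_rejected(self, planted_marker_dataset):
        B = ExpressionMatrix(planted_marker_dataset.B.data.iloc[:, :2])
        with pytest.raises(MixDeconError):
            linseed_deconvolve(B, 3)

    def test_more_components_than_cell_types_rejected(self):
        # clean two-type data spans only two extreme directions: asking for
        # six components must fail with a hint to lower c
        rng = np.random.default_rng(1)
        P = rng.dirichlet([1, 1], size=8).T
        S = np.ones((30, 2))
        S[:5, 0], S[5:10, 1] = 50.0, 50.0
        Bx = expression_from(S @ P, [f"g{i}" for i in range(30)],
                             [f"s{j}" for j in range(8)])
        with pytest.raises(MixDeconError, match="smaller c"):
            linseed_deconvolve(Bx, 6, collinearity_quantile=0.0)
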