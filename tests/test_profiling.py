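"""SUCRA-profile PCA and partitioning around medoids."""

import itertools

import numpy as np
import pandas as pd
import pytest

import myelorank as mr
from myelorank import ValidationError
from myelorank.profiling import PROFILE_ENDPOINTS, SucraProfile, mean_silhouette


def chart_from(matrix, treatments=None):
    matrix = np.asarray(matrix, dtype=float)
    if treatments is None:
        treatments = [f"T{i}" for i in range(matrix.shape[0])]
    return pd.DataFrame(matrix, index=treatments, columns=list(PROFILE_ENDPOINTS))


class TestAssembleProfile:
    def test_full_chart_shape(self):
        rng = np.random.default_rng(2)
        profile = mr.assemble_profile(chart_from(rng.uniform(0, 1, (23, 5))))
        assert profile.matrix.shape == (23, 5)
        assert profile.endpoints == list(PROFILE_ENDPOINTS)

    def test_single_treatment(self):
        profile = mr.assemble_profile(chart_from([[0.5] * 5]))
        assert profile.matrix.shape == (1, 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            mr.assemble_profile(chart_from([[0.5, 0.5, 1.2, 0.5, 0.5]] * 2))

    def test_missing_endpoint_rejected(self):
        chart = chart_from(np.full((3, 5), 0.5)).drop(columns=["CR"])
        with pytest.raises(ValidationError, match="CR"):
            mr.assemble_profile(chart)


class TestPCA:
    def test_rank_one_matrix_single_component(self):
        u = np.linspace(0, 1, 6)[:, None]
        v = np.array([[0.2, 0.4, 0.6, 0.8, 1.0]])
        res = mr.pca_scores(SucraProfile(chart_from(u * v)), scale=False)
        assert res.explained_variance[0] == pytest.approx(1.0, abs=1e-12)

    def test_reconstruction_from_all_components(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (10, 5))
        res = mr.pca_scores(SucraProfile(chart_from(X)))
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        assert np.allclose(res.scores @ res.loadings.T, Z, atol=1e-10)

    def test_matches_svd_oracle(self):
        """Scores and explained variance agree with scikit-learn's SVD PCA."""
        sk = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(4, 20))
            X = rng.uniform(0, 1, (n, 5))
            res = mr.pca_scores(SucraProfile(chart_from(X)), scale=False)
            ref = sk.PCA()
            ref_scores = ref.fit_transform(X)
            for j in range(min(5, n - 1)):
                s = np.sign(res.scores[:, j] @ ref_scores[:, j]) or 1.0
                assert np.allclose(res.scores[:, j], s * ref_scores[:, j], atol=1e-8)
            assert np.allclose(
                res.explained_variance[: len(ref.explained_variance_ratio_)],
                ref.explained_variance_ratio_,
                atol=1e-10,
            )

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, (8, 5))
        perm = rng.permutation(8)
        a = mr.pca_scores(SucraProfile(chart_from(X)))
        b = mr.pca_scores(SucraProfile(chart_from(X[perm])))
        assert np.allclose(a.explained_variance, b.explained_variance, atol=1e-10)
        assert np.allclose(np.abs(a.scores[perm]), np.abs(b.scores), atol=1e-8)

    def test_constant_column_with_scale_rejected(self):
        X = np.full((4, 5), 0.5)
        X[:, 0] = np.linspace(0.1, 0.9, 4)
        with pytest.raises(ValidationError, match="OS"):
            mr.pca_scores(SucraProfile(chart_from(X)), scale=True)


class TestPAM:
    def test_k_equals_n_zero_objective(self):
        pts = np.random.default_rng(6).normal(0, 1, (5, 2))
        res = mr.pam_cluster(pts, k=5)
        assert res.objective == 0.0
        assert len(res.medoids) == 5

    def test_recovers_separated_blobs(self):
        rng = np.random.default_rng(7)
        centers = np.array([[0.0, 0.0], [1.5, 0.0], [0.0, 1.5]])
        pts = np.vstack([c + rng.normal(0, 0.01, (10, 2)) for c in centers])
        res = mr.pam_cluster(pts, k=3)
        labels = np.array([res.assignments[t] for t in res.treatments])
        planted = np.repeat([0, 1, 2], 10)
        # partition identical up to label permutation
        assert len({tuple(labels[planted == g]) for g in range(3)}) == 3
        for g in range(3):
            assert len(set(labels[planted == g])) == 1

    def test_objective_matches_exhaustive_minimum(self):
        """BUILD+SWAP attains the global k-medoids optimum for all n <= 8."""
        rng = np.random.default_rng(8)
        for n in range(2, 9):
            pts = rng.normal(0, 1, (n, 2))
            diff = pts[:, None, :] - pts[None, :, :]
            dist = np.sqrt((diff**2).sum(-1))
            for k in range(1, n + 1):
                res = mr.pam_cluster(pts, k=k)
                best = min(
                    dist[:, list(sub)].min(axis=1).sum()
                    for sub in itertools.combinations(range(n), k)
                )
                assert res.objective == pytest.approx(best, abs=1e-9)

    def test_medoids_belong_to_their_cluster(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(0, 1, (12, 3))
        res = mr.pam_cluster(pts, k=3)
        for g, m in enumerate(res.medoids):
            assert res.assignments[m] == g

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            mr.pam_cluster(np.zeros((3, 2)), k=4)


class TestChooseK:
    def blobs(self, k, rng, spread=0.05, per=8):
        centers = rng.normal(0, 2, (k, 3))
        return np.vstack([c + rng.normal(0, spread, (per, 3)) for c in centers])

    @pytest.mark.parametrize("true_k", [2, 3])
    def test_selects_planted_group_count(self, true_k):
        rng = np.random.default_rng(100 + true_k)
        res = mr.choose_k(self.blobs(true_k, rng), k_range=range(2, 7))
        assert res.k == true_k

    def test_silhouette_matches_sklearn(self):
        skm = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(12)
        pts = rng.normal(0, 1, (20, 2))
        labels = rng.integers(0, 3, 20)
        if len(np.unique(labels)) < 2:
            labels[0] = (labels[0] + 1) % 3
        ours = mean_silhouette(pts, labels)
        assert ours == pytest.approx(skm.silhouette_score(pts, labels), abs=1e-10)

    def test_singleton_cluster_contributes_zero(self):
        pts = np.array([[0.0, 0.0], [0.1, 0.0], [5.0, 5.0]])
        labels = np.array([0, 0, 1])
        b0, b1 = np.hypot(5.0, 5.0), np.hypot(4.9, 5.0)
        manual = ((b0 - 0.1) / b0 + (b1 - 0.1) / b1 + 0.0) / 3
        assert mean_silhouette(pts, labels) == pytest.approx(manual)


class TestPipeline:
    def test_retains_components_for_80pct_variance(self):
        rng = np.random.default_rng(13)
        chart = chart_from(rng.uniform(0, 1, (12, 5)))
        chart["mean_sucra"] = chart.mean(axis=1)
        res = mr.profile_and_cluster(chart, k=3)
        assert res.k == 3
        assert set(res.assignments) == set(chart.index)
        cum = np.cumsum(res.explained_variance)
        n_pc = np.searchsorted(cum, 0.8 - 1e-12) + 1
        assert n_pc >= 1
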