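import numpy as np
import pytest
from scipy.spatial.distance import mahalanobis as scipy_mahalanobis
from sklearn.metrics import adjusted_rand_score, silhouette_score

from grntrend.embedding import (GeneEmbedder, cluster_genes, embed_2d,
                                gene_features, mahalanobis_rank)
from grntrend.errors import DegenerateGeometryError, ParameterError
from grntrend.trend import SlopeMatrix


def _slope(beta):
    p = beta.shape[0]
    return SlopeMatrix(beta, [f"g{i}" for i in range(p)], np.linspace(0, 1, 4))


class TestGeneFeatures:
    def test_modes_assembled_exactly(self, rng):
        B = rng.normal(size=(3, 3))
        np.fill_diagonal(B, 0)
        sm = _slope(B)
        assert np.array_equal(gene_features(sm, "row"), B)
        assert np.array_equal(gene_features(sm, "col"), B.T)
        concat = gene_features(sm, "concat")
        assert concat.shape == (3, 6)
        assert np.array_equal(concat[:, :3], B)
        assert np.array_equal(concat[:, 3:], B.T)

    def test_symmetric_beta_makes_modes_equidistant(self, rng):
        B = rng.normal(size=(5, 5))
        B = (B + B.T) / 2
        np.fill_diagonal(B, 0)
        from scipy.spatial.distance import pdist
        d_row = pdist(gene_features(_slope(B), "row"))
        d_col = pdist(gene_features(_slope(B), "col"))
        d_cat = pdist(gene_features(_slope(B), "concat"))
        assert np.allclose(d_row, d_col)
        assert np.allclose(d_cat, np.sqrt(2) * d_row)

    def test_unknown_mode(self):
        with pytest.raises(ParameterError):
            gene_features(np.zeros((4, 4)), "diag")


class TestEmbed2d:
    def test_separated_blobs_stay_separated(self, rng):
        p = 200
        labels = np.repeat([0, 1], p // 2)
        feats = rng.normal(size=(p, 20))
        feats[labels == 1] += 12.0
        coords = embed_2d(feats, seed=0, perplexity=20)
        assert silhouette_score(coords, labels) > 0.5

    def test_deterministic_given_seed(self, rng):
        feats = rng.normal(size=(30, 8))
        c1 = embed_2d(feats, seed=5, perplexity=5)
        c2 = embed_2d(feats, seed=5, perplexity=5)
        assert np.array_equal(c1, c2)

    def test_small_p_boundary_runs(self, rng):
        coords = embed_2d(rng.normal(size=(4, 3)), seed=0, perplexity=2)
        assert coords.shape == (4, 2)

    def test_perplexity_too_large(self, rng):
        with pytest.raises(ParameterError):
            embed_2d(rng.normal(size=(5, 3)), seed=0, perplexity=10)


class TestClusterGenes:
    def test_single_cluster(self, rng):
        labels = cluster_genes(rng.normal(size=(10, 2)), K=1, seed=0)
        assert set(labels) == {1}

    def test_separable_triplets(self):
        coords = np.array([[0, 0], [0, 0.1], [0.1, 0],
                           [10, 10], [10, 10.1], [10.1, 10],
                           [-10, 10], [-10, 10.1], [-10.1, 10]], dtype=float)
        labels = cluster_genes(coords, K=3, seed=0)
        assert len({tuple(labels[i:i + 3]) for i in range(0, 9, 3)}) == 3
        for i in range(0, 9, 3):
            assert len(set(labels[i:i + 3])) == 1

    def test_planted_gaussians_recovered(self, rng):
        K = 50
        centers = rng.uniform(-100, 100, size=(K, 2))
        truth = np.repeat(np.arange(K), 50)
        coords = centers[truth] + rng.normal(scale=0.5, size=(K * 50, 2))
        labels = cluster_genes(coords, K=K, seed=0)
        assert adjusted_rand_score(truth, labels) > 0.9

    def test_labels_sorted_by_size(self, rng):
        coords = np.vstack([rng.normal(size=(30, 2)),
                            rng.normal(loc=50, size=(10, 2))])
        labels = cluster_genes(coords, K=2, seed=0)
        assert (labels == 1).sum() == 30  # biggest cluster gets label 1

    def test_p_smaller_than_k(self, rng):
        with pytest.raises(ParameterError):
            cluster_genes(rng.normal(size=(5, 2)), K=10, seed=0)


class TestMahalanobisRank:
    def test_gene_at_center_ranked_last(self, rng):
        coords = rng.normal(size=(20, 2))
        # place point 7 at the mean of the others => it is the exact centroid
        coords[7] = (coords.sum(axis=0) - coords[7]) / 19
        mdist, order = mahalanobis_rank(coords)
        # the centered point has (near-)minimal distance
        assert mdist[7] == pytest.approx(mdist.min(), abs=1e-8)
        assert order[-1] == 7

    def test_matches_scipy(self, rng):
        coords = rng.normal(size=(40, 2)) @ np.array([[2.0, 0.7], [0.0, 1.0]])
        mdist, _ = mahalanobis_rank(coords)
        mu = coords.mean(axis=0)
        VI = np.linalg.inv(np.cov(coords, rowvar=False, ddof=1))
        ref = [scipy_mahalanobis(x, mu, VI) for x in coords]
        assert np.allclose(mdist, ref, atol=1e-10)

    def test_isotropic_equals_euclidean_ranking(self, rng):
        base = rng.normal(size=(50, 2))
        base = (base - base.mean(0)) / base.std(0)
        mdist, order = mahalanobis_rank(base)
        eucl = np.linalg.norm(base - base.mean(0), axis=1)
        # same ordering when the sample covariance is (near) isotropic
        rho = np.corrcoef(mdist, eucl)[0, 1]
        assert rho > 0.99

    def test_affine_invariance(self, rng):
        coords = rng.normal(size=(30, 2))
        mdist, _ = mahalanobis_rank(coords)
        A = np.array([[1.5, 0.3], [-0.2, 0.8]])
        mdist2, _ = mahalanobis_rank(coords @ A.T + np.array([5.0, -3.0]))
        assert np.abs(mdist - mdist2).max() < 1e-8

    def test_singular_covariance_rejected(self):
        coords = np.column_stack([np.arange(10.0), np.arange(10.0)])
        with pytest.raises(DegenerateGeometryError):
            mahalanobis_rank(coords)


class TestGeneEmbedder:
    def test_fit_attributes_and_determinism(self, rng):
        beta = rng.normal(size=(60, 60))
        np.fill_diagonal(beta, 0)
        est = GeneEmbedder(perplexity=10, n_clusters=5, random_state=3)
        est.fit(beta)
        assert est.coords_.shape == (60, 2)
        assert set(est.labels_) <= set(range(1, 6))
        assert np.all(np.diff(est.mdist_[est.rank_order_]) <= 1e-12)
        est2 = GeneEmbedder(perplexity=10, n_clusters=5, random_state=3).fit(beta)
        assert np.array_equal(est.coords_, est2.coords_)
        assert np.array_equal(est.labels_, est2.labels_)

    def test_zero_beta_does_not_crash_features(self):
        feats = gene_features(np.zeros((10, 10)), "concat")
        assert np.all(feats == 0)
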