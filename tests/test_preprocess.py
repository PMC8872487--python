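import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grntrend.errors import ParameterError, PipelineError
from grntrend.io import CountMatrix
from grntrend.preprocess import (PearsonResidualNormalizer, filter_genes,
                                 pearson_residuals, qc_filter_cells)


def _counts_with_totals(totals, mito_fracs):
    """Two ordinary genes plus one mitochondrial gene hitting given totals."""
    mito = np.round(np.array(totals) * np.array(mito_fracs)).astype(int)
    rest = np.array(totals) - mito
    values = np.vstack([rest // 2, rest - rest // 2, mito])
    return CountMatrix(values, ["gA", "gB", "mt-nd1"],
                       [f"c{i}" for i in range(len(totals))])


class TestQc:
    def test_umi_boundary_inclusive(self):
        counts = _counts_with_totals([999, 1000], [0, 0])
        kept = qc_filter_cells(counts)
        assert kept.cell_ids == ["c1"]

    def test_no_mito_genes_only_umi_rule(self):
        values = np.array([[1500, 400], [0, 700]])
        counts = CountMatrix(values, ["gA", "gB"], ["c1", "c2"])
        kept = qc_filter_cells(counts)
        assert kept.cell_ids == ["c1", "c2"]  # both have >=1000 UMIs

    def test_both_rules_applied(self):
        counts = _counts_with_totals([500, 1000, 2000, 3000, 100],
                                     [0, 0, 0.2, 0.05, 0])
        kept = qc_filter_cells(counts)
        assert kept.cell_ids == ["c1", "c3"]
        assert kept.gene_ids == counts.gene_ids  # gene set unchanged

    def test_zero_survivors_is_pipeline_error(self):
        counts = _counts_with_totals([10, 20], [0, 0])
        with pytest.raises(PipelineError, match="below"):
            qc_filter_cells(counts)


class TestFilterGenes:
    def test_ceil_boundary(self):
        values = np.zeros((2, 100), dtype=int)
        values[0, :5] = 1   # nonzero in exactly 5 of 100 cells
        values[1, :] = 1
        kept = filter_genes(CountMatrix(values, ["g5", "gall"],
                                        [f"c{i}" for i in range(100)]),
                            min_cell_frac=0.05)
        assert kept.gene_ids == ["g5", "gall"]

    def test_all_zero_gene_removed(self):
        values = np.array([[0, 0], [1, 1]])
        kept = filter_genes(CountMatrix(values, ["dead", "live"], ["c1", "c2"]),
                            min_cell_frac=0.5)
        assert kept.gene_ids == ["live"]

    def test_counted_by_hand(self):
        # gene i nonzero in exactly i cells, n=20, frac 0.25 -> keep i >= 5
        values = np.zeros((10, 20), dtype=int)
        for i in range(10):
            values[i, :i] = 2
        counts = CountMatrix(values, [f"g{i}" for i in range(10)],
                             [f"c{i}" for i in range(20)])
        kept = filter_genes(counts, min_cell_frac=0.25)
        assert kept.gene_ids == [f"g{i}" for i in range(5, 10)]

    def test_frac_range_enforced(self, tiny_counts):
        with pytest.raises(ParameterError):
            filter_genes(tiny_counts, min_cell_frac=1.0)

    def test_qc_then_filter_idempotent(self, small_truth):
        once = filter_genes(qc_filter_cells(small_truth.counts, min_umi=100),
                            min_cell_frac=0.05)
        twice = filter_genes(qc_filter_cells(once, min_umi=100),
                             min_cell_frac=0.05)
        assert np.array_equal(once.values, twice.values)
        assert once.gene_ids == twice.gene_ids


class TestPearsonResiduals:
    def test_constant_matrix_residuals_zero(self):
        counts = CountMatrix(np.full((3, 4), 7), [f"g{i}" for i in range(3)],
                             [f"c{i}" for i in range(4)])
        norm = pearson_residuals(counts)
        assert np.abs(norm.values).max() < 1e-12

    def test_zero_gene_row_is_zero(self):
        values = np.array([[0, 0], [2, 3]])
        norm = pearson_residuals(CountMatrix(values, ["z", "g"], ["c1", "c2"]))
        assert np.all(norm.values[0] == 0)

    def test_two_by_two_hand_oracle(self):
        # mu = outer(rowsum, colsum)/total; r = (x-mu)/sqrt(mu+mu^2/100)
        counts = CountMatrix(np.array([[1, 3], [2, 4]]), ["g1", "g2"], ["c1", "c2"])
        expected = np.array([[-0.1814885, 0.11788388],
                             [0.1477474, -0.09560299]])
        norm = pearson_residuals(counts, theta=100)
        assert np.allclose(norm.values, expected, atol=1e-7)

    def test_clip_bound_exact(self, small_truth):
        norm = pearson_residuals(small_truth.counts, clip="sqrt-n")
        assert np.abs(norm.values).max() <= np.sqrt(small_truth.counts.n_cells)

    def test_theta_must_be_positive(self, tiny_counts):
        with pytest.raises(ParameterError):
            pearson_residuals(tiny_counts, theta=0)

    def test_sklearn_get_set_params(self):
        est = PearsonResidualNormalizer(theta=50)
        assert est.get_params()["theta"] == 50
        est.set_params(clip="none")
        assert est.clip == "none"

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.poisson(3.0, size=(6, 9))
        X[0, 0] += 1  # guarantee nonzero total
        counts = CountMatrix(X, [f"g{i}" for i in range(6)],
                             [f"c{i}" for i in range(9)])
        resid = pearson_residuals(counts).values
        pg = rng.permutation(6)
        pc = rng.permutation(9)
        permuted = CountMatrix(X[np.ix_(pg, pc)],
                               [f"g{i}" for i in pg], [f"c{i}" for i in pc])
        resid_perm = pearson_residuals(permuted).values
        assert np.allclose(resid_perm, resid[np.ix_(pg, pc)], atol=1e-12)
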