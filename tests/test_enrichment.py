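import math

import numpy as np
import pytest
from scipy import stats

from grntrend.enrichment import bh_fdr, gsea_preranked, ora_fisher
from grntrend.errors import DataError, ParameterError
from grntrend.io import GeneSetCollection


def _hypergeom_tail_bruteforce(M, K, n, k_obs):
    """Exact P(overlap >= k_obs) by summation over all outcomes."""
    total = math.comb(M, n)
    return sum(math.comb(K, x) * math.comb(M - K, n - x)
               for x in range(k_obs, min(K, n) + 1)) / total


class TestOra:
    def test_zero_overlap_certain(self):
        uni = [f"g{i}" for i in range(100)]
        res = ora_fisher(uni[:5], uni[90:], uni)
        assert res.overlap_count == 0
        assert res.p_value == 1.0

    def test_full_overlap_degenerate(self):
        uni = [f"g{i}" for i in range(10)]
        res = ora_fisher(uni, uni, uni)
        assert res.overlap_count == 10
        assert res.p_value == 1.0

    def test_tail_sum_oracle(self):
        uni = [f"g{i}" for i in range(100)]
        cluster = uni[:20]
        gene_set = uni[15:25]       # overlap = 5
        res = ora_fisher(cluster, gene_set, uni)
        assert res.overlap_count == 5
        assert res.p_value == pytest.approx(0.025464546427043124, rel=1e-12)

    def test_exhaustive_small_universes(self):
        # every configuration on universes up to 30 matches brute force
        for M, K, n in [(8, 3, 4), (12, 6, 5), (20, 7, 9), (30, 11, 13)]:
            uni = [f"g{i}" for i in range(M)]
            gene_set = uni[:K]
            for k_obs in range(0, min(K, n) + 1):
                if n - k_obs > M - K:
                    continue
                cluster = uni[:k_obs] + uni[K:K + n - k_obs]
                res = ora_fisher(cluster, gene_set, uni)
                assert res.overlap_count == k_obs
                expected = _hypergeom_tail_bruteforce(M, K, n, k_obs)
                assert res.p_value == pytest.approx(expected, rel=1e-10)

    def test_cluster_outside_universe_rejected(self):
        with pytest.raises(DataError):
            ora_fisher(["x"], ["a"], ["a", "b"])

    def test_empty_inputs_rejected(self):
        with pytest.raises(ParameterError):
            ora_fisher([], ["a"], ["a"])

    def test_case_insensitive_matching(self):
        uni = ["Sox2", "POU5F1", "nanog", "gata4"]
        res = ora_fisher(["Sox2", "nanog"], ["SOX2", "NANOG"], uni,
                         case_insensitive=True)
        assert res.overlap_count == 2


def _brute_force_es(genes, scores, members, weight):
    """Independent running-sum enumeration."""
    hits = [g in members for g in genes]
    nh = sum(hits)
    wsum = sum(abs(s) ** weight for s, h in zip(scores, hits) if h)
    run, best = 0.0, 0.0
    for s, h in zip(scores, hits):
        if h:
            run += (abs(s) ** weight / wsum) if wsum > 0 else 1.0 / nh
        else:
            run -= 1.0 / (len(genes) - nh)
        if abs(run) > abs(best):
            best = run
    return best


class TestGsea:
    genes = [f"g{i}" for i in range(10)]

    def _run(self, sets, scores, **kw):
        kw.setdefault("min_size", 1)
        kw.setdefault("n_perm", 50)
        kw.setdefault("seed", 0)
        return gsea_preranked(self.genes, scores, GeneSetCollection(sets), **kw)

    def test_top_set_equal_scores_weight0_is_ks_statistic(self):
        scores = np.ones(10)
        res = self._run({"top": self.genes[:2]}, scores, weight=0)
        expected = _brute_force_es(self.genes, scores, set(self.genes[:2]), 0)
        assert res[0].es == pytest.approx(expected, abs=1e-12)
        assert res[0].es == pytest.approx(1.0)  # set occupies the very top

    @pytest.mark.parametrize("weight", [0.0, 1.0, 2.0])
    def test_brute_force_equivalence_random_sets(self, weight, rng):
        scores = np.sort(rng.uniform(0.1, 5.0, size=10))[::-1]
        for trial in range(20):
            members = set(rng.choice(self.genes, size=rng.integers(1, 9),
                                     replace=False))
            res = self._run({"s": sorted(members)}, scores, weight=weight)
            expected = _brute_force_es(self.genes, scores, members, weight)
            assert res[0].es == pytest.approx(expected, abs=1e-12)

    def test_bottom_set_negative_es(self):
        scores = np.linspace(5, 1, 10)
        res = self._run({"bottom": self.genes[-3:]}, scores)
        assert res[0].es < 0
        assert set(res[0].leading_edge) <= set(self.genes[-3:])

    def test_reversal_negates_es_at_weight0(self, rng):
        scores = np.linspace(5, 1, 10)
        members = ["g1", "g2", "g6"]
        es_fwd = self._run({"s": members}, scores, weight=0)[0].es
        rev = gsea_preranked(self.genes[::-1], scores,
                             GeneSetCollection({"s": members}),
                             weight=0, min_size=1, n_perm=50, seed=0)
        assert rev[0].es == pytest.approx(-es_fwd, abs=1e-12)

    def test_es_bounded(self, rng):
        for _ in range(20):
            scores = np.sort(rng.normal(size=10))[::-1]
            members = list(rng.choice(self.genes, size=4, replace=False))
            res = self._run({"s": members}, scores, weight=1)
            assert -1.0 <= res[0].es <= 1.0

    def test_deterministic_given_seed(self, rng):
        scores = np.sort(rng.normal(size=10))[::-1]
        sets = {"a": self.genes[:3], "b": self.genes[4:9]}
        r1 = self._run(sets, scores, n_perm=200, seed=9)
        r2 = self._run(sets, scores, n_perm=200, seed=9)
        assert [r.p_value for r in r1] == [r.p_value for r in r2]
        assert [r.nes for r in r1] == [r.nes for r in r2]

    def test_size_window_skips_sets(self):
        scores = np.linspace(5, 1, 10)
        res = self._run({"tiny": self.genes[:1], "ok": self.genes[:6]},
                        scores, min_size=5)
        assert [r.set_name for r in res] == ["ok"]

    def test_full_coverage_skipped_with_warning(self):
        scores = np.linspace(5, 1, 10)
        with pytest.warns(UserWarning, match="covers"):
            res = self._run({"all": self.genes}, scores)
        assert res == []

    def test_leading_edge_members_of_set(self, rng):
        scores = np.sort(rng.uniform(1, 9, 10))[::-1]
        members = ["g0", "g3", "g8"]
        res = self._run({"s": members}, scores)
        assert set(res[0].leading_edge) <= set(members)

    def test_null_pvalues_uniform(self, rng):
        n_genes = 300
        genes = [f"g{i}" for i in range(n_genes)]
        scores = np.sort(rng.normal(size=n_genes))[::-1]
        sets = {f"S{k}": [genes[i] for i in rng.choice(n_genes, 15, replace=False)]
                for k in range(100)}
        res = gsea_preranked(genes, scores, GeneSetCollection(sets),
                             n_perm=300, seed=3)
        p = [r.p_value for r in res]
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_step_up_by_hand(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.all(bh_fdr([1.0, 1.0, 1.0]) == 1.0)

    def test_monotone_and_capped(self, rng):
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert q.max() <= 1.0
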