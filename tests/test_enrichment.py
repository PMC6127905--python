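import math
from fractions import Fraction

import numpy as np
import pytest

from plaquesig.enrichment import (
    annotate,
    hypergeom_tail,
    overlap_test,
    venn_counts,
)
from plaquesig.io import GeneSet, GeneSetCollection, ValidationError


def exact_tail(N: int, K: int, n: int, k: int) -> float:
    """Independent oracle: exact rational upper-tail sum."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for j in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, j) * math.comb(N - K, n - j), denom)
    return float(total)


class TestHypergeomTail:
    def test_enumeration_example(self):
        # all C(10,4)=210 draws; only 5 of them take all 4 from the 5 successes...
        # C(5,4)*C(5,0)=5 -> 5/210
        assert hypergeom_tail(10, 5, 4, 4) == pytest.approx(5 / 210, rel=1e-12)

    def test_zero_overlap_is_full_tail(self):
        assert hypergeom_tail(100, 30, 20, 0) == 1.0

    def test_published_overlap_is_below_2e56(self):
        assert hypergeom_tail(12130, 342, 67, 46) <= 2e-56

    def test_matches_rational_enumeration_small_grid(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        got = hypergeom_tail(N, K, n, k)
                        want = exact_tail(N, K, n, k)
                        assert got == pytest.approx(want, rel=1e-10, abs=1e-300), (N, K, n, k)

    def test_strictly_decreasing_in_k(self):
        values = [hypergeom_tail(200, 50, 40, k) for k in range(0, 30)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_symmetric_in_set_roles(self, rng):
        for _ in range(50):
            N = int(rng.integers(10, 500))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert hypergeom_tail(N, K, n, k) == pytest.approx(
                hypergeom_tail(N, n, K, k), rel=1e-9)

    @pytest.mark.parametrize("args", [(10, 11, 5, 2), (10, 5, 5, 6), (10, 5, 4, -1)])
    def test_inconsistent_counts_rejected(self, args):
        with pytest.raises(ValidationError):
            hypergeom_tail(*args)


class TestOverlapTest:
    def _background(self, n=200):
        return GeneSet("bg", {f"g{i:03d}" for i in range(n)})

    def test_disjoint_sets(self):
        bg = self._background()
        a = GeneSet("a", {f"g{i:03d}" for i in range(30)})
        b = GeneSet("b", {f"g{i:03d}" for i in range(30, 50)})
        result = overlap_test(a, b, bg)
        assert result.k == 0 and result.p_hyper == 1.0

    def test_nested_sets_maximal_overlap(self):
        bg = self._background()
        a = GeneSet("a", {f"g{i:03d}" for i in range(50)})
        b = GeneSet("b", {f"g{i:03d}" for i in range(10)})
        result = overlap_test(a, b, bg)
        assert result.k == len(b) == 10

    def test_background_restriction_applied(self):
        bg = GeneSet("bg", {"g1", "g2", "g3", "g4"})
        a = GeneSet("a", {"g1", "g2", "offbg1"})
        b = GeneSet("b", {"g2", "offbg2"})
        result = overlap_test(a, b, bg)
        assert (result.N, result.K, result.n, result.k) == (4, 2, 1, 1)

    def test_empty_after_restriction_names_set(self):
        bg = GeneSet("bg", {"g1"})
        with pytest.raises(ValidationError, match="phantom"):
            overlap_test(GeneSet("phantom", {"x"}), GeneSet("b", {"g1"}), bg)

    def test_tail_matches_permutation_null(self, rng):
        """Monte-Carlo permutation oracle: draw random same-size sets from
        the background and compare the empirical tail with the exact one."""
        N, K, n = 200, 30, 20
        bg_ids = [f"g{i:03d}" for i in range(N)]
        a_members = set(bg_ids[:K])
        k_obs = 6
        p_exact = hypergeom_tail(N, K, n, k_obs)
        draws = 100_000
        mask = np.zeros(N, dtype=bool)
        mask[:K] = True
        hits = 0
        chunk = 20_000
        for start in range(0, draws, chunk):
            m = min(chunk, draws - start)
            u = rng.random((m, N))
            idx = np.argpartition(u, n, axis=1)[:, :n]
            overlap = mask[idx].sum(axis=1)
            hits += int((overlap >= k_obs).sum())
        p_hat = hits / draws
        se = math.sqrt(p_exact * (1 - p_exact) / draws)
        assert abs(p_hat - p_exact) <= 3 * se


class TestVennCounts:
    def test_identical_sets(self):
        bg = GeneSet("bg", {f"g{i}" for i in range(50)})
        a = GeneSet("a", {f"g{i}" for i in range(20)})
        assert venn_counts(a, a, bg) == (0, 0, 20, 50)

    def test_published_venn_partition(self):
        """342 cortex-up and 67 niche-up genes sharing 46 members on a
        12,130-gene background partition as 296 / 21 / 46."""
        bg = GeneSet("bg", {f"g{i:05d}" for i in range(12130)})
        a = GeneSet("cortex_up", {f"g{i:05d}" for i in range(342)})
        b = GeneSet("niche_up", {f"g{i:05d}" for i in range(296, 296 + 67)})
        assert len(a.members & b.members) == 46
        assert venn_counts(a, b, bg) == (296, 21, 46, 12130)

    def test_matches_direct_set_algebra(self, rng):
        bg_ids = [f"g{i:03d}" for i in range(100)]
        bg = GeneSet("bg", set(bg_ids))
        a = GeneSet("a", set(rng.choice(bg_ids, size=30, replace=False)))
        b = GeneSet("b", set(rng.choice(bg_ids, size=40, replace=False)))
        a_only, b_only, inter, N = venn_counts(a, b, bg)
        assert a_only == len(a.members - b.members)
        assert b_only == len(b.members - a.members)
        assert inter == len(a.members & b.members)
        assert a_only + b_only + inter == len(a.members | b.members) <= N


class TestAnnotate:
    def _setup(self):
        bg = GeneSet("bg", {f"g{i:03d}" for i in range(100)})
        target = GeneSet("hit", {f"g{i:03d}" for i in range(20)})
        decoys = [GeneSet(f"decoy{j}", {f"g{i:03d}" for i in range(20 + 15 * j, 35 + 15 * j)})
                  for j in range(4)]
        collection = GeneSetCollection("paths", [target] + decoys)
        query = GeneSet("query", set(target.members))
        return query, collection, bg

    def test_single_set_bonferroni_identity(self):
        bg = GeneSet("bg", {f"g{i}" for i in range(50)})
        s = GeneSet("s", {f"g{i}" for i in range(10)})
        rows = annotate(GeneSet("q", {f"g{i}" for i in range(5)}),
                        GeneSetCollection("c", [s]), bg)
        assert rows[0].e_value == rows[0].p

    def test_e_value_capped_at_one(self):
        bg = GeneSet("bg", {f"g{i}" for i in range(100)})
        sets = [GeneSet(f"s{j}", {f"g{i}" for i in range(j * 10, j * 10 + 10)})
                for j in range(10)]
        rows = annotate(GeneSet("q", {"g0", "g1"}),
                        GeneSetCollection("c", sets), bg)
        assert all(r.e_value <= 1.0 for r in rows)
        assert any(r.e_value == 1.0 for r in rows)

    def test_self_annotation_e_value_enumerated(self):
        """Query equal to a 20-gene set on a 100-gene background with m=5:
        e = 5 * P(X >= 20) = 5 / C(100, 20)."""
        query, collection, bg = self._setup()
        rows = annotate(query, collection, bg)
        top = rows[0]
        assert top.set_name == "hit"
        expected = 5.0 / math.comb(100, 20)
        assert top.e_value == pytest.approx(expected, rel=1e-9)
        assert top.significant

    def test_rows_sorted_by_p_then_name(self):
        query, collection, bg = self._setup()
        rows = annotate(query, collection, bg)
        keys = [(r.p, r.set_name) for r in rows]
        assert keys == sorted(keys)

    def test_empty_query_after_restriction_rejected(self):
        bg = GeneSet("bg", {"g1"})
        collection = GeneSetCollection("c", [GeneSet("s", {"g1"})])
        with pytest.raises(ValidationError, match="query"):
            annotate(GeneSet("query", {"offbg"}), collection, bg)
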