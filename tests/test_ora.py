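"""Hypergeometric upper tail, BH step-up, and over-representation analysis."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from comorbinet.gene_sets import Category, CategoryType, GeneList, GeneSetCollection
from comorbinet.ora import (
    Background,
    bh_adjust,
    hypergeometric_pvalue,
    run_ora,
)

from conftest import bh_stepup_oracle, hypergeom_tail_exact


class TestHypergeometricPvalue:
    def test_zero_overlap_is_certain(self):
        assert hypergeometric_pvalue(0, 5, 10, 100) == 1.0

    def test_forced_full_overlap_is_certain(self):
        # query is the whole background, so overlap k = K is guaranteed
        assert hypergeometric_pvalue(7, 50, 7, 50) == pytest.approx(1.0)

    def test_matches_exact_rational_sum(self):
        p = hypergeometric_pvalue(3, 5, 10, 100)
        exact = float(hypergeom_tail_exact(3, 5, 10, 100))
        assert p == pytest.approx(exact, rel=1e-12)

    @pytest.mark.parametrize("N", [10, 25, 40])
    def test_exact_on_small_grid(self, N):
        for n in range(1, N + 1, 3):
            for K in range(1, N + 1, 3):
                for k in range(0, min(n, K) + 1):
                    got = hypergeometric_pvalue(k, n, K, N)
                    want = float(hypergeom_tail_exact(k, n, K, N))
                    assert got == pytest.approx(want, rel=1e-12, abs=1e-300)

    def test_monotone_in_k_and_K(self):
        n, N = 20, 120
        for K in range(5, 60, 5):
            ps = [hypergeometric_pvalue(k, n, K, N) for k in range(0, min(n, K) + 1)]
            assert all(a >= b for a, b in zip(ps, ps[1:]))
        for k in (1, 3, 5):
            ps = [hypergeometric_pvalue(k, n, K, N) for K in range(k, 80, 4)]
            assert all(a <= b + 1e-15 for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize(
        "k,n,K,N,msg",
        [(6, 5, 10, 100, "k="), (3, 101, 10, 100, "n="), (3, 5, 101, 100, "K="), (-1, 5, 10, 100, "k=")],
    )
    def test_bound_violations_name_the_argument(self, k, n, K, N, msg):
        with pytest.raises(ValueError, match=msg):
            hypergeometric_pvalue(k, n, K, N)


class TestBhAdjust:
    def test_single_p_is_fixed_point(self):
        assert bh_adjust([0.123]) == pytest.approx([0.123])

    def test_equal_ps_are_fixed_points(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_frozen_stepup_example(self):
        # hand step-up: every min_{j>=i} min(1, 4 p_(j)/j) equals 0.04
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
    @settings(max_examples=300, deadline=None)
    def test_matches_independent_stepup(self, ps):
        got = bh_adjust(ps)
        want = bh_stepup_oracle(ps)
        assert np.allclose(got, want, rtol=1e-12, atol=1e-15)
        assert np.all((got >= 0) & (got <= 1))

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60),
        st.floats(0.001, 0.2),
    )
    @settings(max_examples=200, deadline=None)
    def test_never_more_rejections_than_raw(self, ps, alpha):
        assert np.sum(bh_adjust(ps) <= alpha) <= np.sum(np.asarray(ps) <= alpha)


def _collection(cats: dict[str, frozenset], ctype=CategoryType.PATHWAY):
    return GeneSetCollection(
        "test", ctype, {cid: Category(cid, members) for cid, members in cats.items()}
    )


class TestRunOra:
    def setup_method(self):
        self.universe = [f"G{i:04d}" for i in range(1000)]
        self.background = Background(frozenset(self.universe))

    def test_disjoint_query_nothing_significant(self):
        coll = _collection({"c1": frozenset(self.universe[100:120]),
                            "c2": frozenset(self.universe[200:230])})
        query = GeneList("q", tuple(self.universe[:10]))
        res = run_ora(query, coll, self.background)
        assert all(r.k == 0 and r.p_value == 1.0 and not r.significant for r in res)

    def test_planted_category_ranks_first_and_is_significant(self):
        # 8 of 10 query genes inside a 20-gene category of a 1000-gene universe
        query = GeneList("q", tuple(self.universe[:10]))
        planted = frozenset(self.universe[:8]) | frozenset(self.universe[500:512])
        cats = {"planted": planted}
        cats.update(
            {f"bg{i}": frozenset(self.universe[50 * i : 50 * i + 20]) for i in range(2, 10)}
        )
        res = run_ora(query, _collection(cats), self.background, fdr_threshold=0.05)
        top = res[0]
        assert top.category_id == "planted" and top.significant
        exact = float(hypergeom_tail_exact(8, 10, 20, 1000))
        assert top.p_value == pytest.approx(exact, rel=1e-12)
        # BH with m tested categories applied to the smallest p
        assert top.fdr == pytest.approx(min(1.0, exact * len(res)), rel=1e-12)

    def test_identical_member_sets_get_identical_statistics(self):
        members = frozenset(self.universe[:15])
        query = GeneList("q", tuple(self.universe[5:25]))
        res = run_ora(query, _collection({"a": members, "b": members, "c": members}),
                      self.background)
        assert len({r.p_value for r in res}) == 1
        assert len({r.fdr for r in res}) == 1

    def test_query_outside_background_is_error(self):
        coll = _collection({"c1": frozenset(self.universe[:20])})
        query = GeneList("q", ("NOT_A_GENE",))
        with pytest.raises(ValueError, match="no query genes in background"):
            run_ora(query, coll, self.background)

    def test_size_filters_restrict_tested_categories(self):
        coll = _collection({
            "tiny": frozenset(self.universe[:2]),
            "ok": frozenset(self.universe[:10]),
            "huge": frozenset(self.universe[:600]),
        })
        query = GeneList("q", tuple(self.universe[:5]))
        res = run_ora(query, coll, self.background, min_category_size=3, max_category_size=500)
        assert [r.category_id for r in res] == ["ok"]

    def test_results_sorted_by_pvalue_then_id(self):
        query = GeneList("q", tuple(self.universe[:10]))
        coll = _collection({
            "b": frozenset(self.universe[:15]),
            "a": frozenset(self.universe[:15]),
            "z": frozenset(self.universe[500:520]),
        })
        res = run_ora(query, coll, self.background)
        assert [r.category_id for r in res] == ["a", "b", "z"]

    def test_null_queries_are_calibrated(self):
        """Uniform random queries should reject at most at the nominal rate."""
        rng = np.random.default_rng(11)
        universe = np.array(self.universe)
        coll = _collection({
            f"c{i}": frozenset(rng.choice(universe, 25, replace=False)) for i in range(20)
        })
        alpha, hits, total = 0.05, 0, 0
        for _ in range(300):
            query = GeneList("q", tuple(rng.choice(universe, 30, replace=False)))
            res = run_ora(query, coll, self.background)
            hits += sum(r.p_value <= alpha for r in res)
            total += len(res)
        rate = hits / total
        se = np.sqrt(alpha * (1 - alpha) / total)
        assert rate <= alpha + 3 * se
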