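import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toxfocus.enrichment import (
    EnrichmentConfig,
    bh_adjust,
    enrich,
    hypergeom_upper_tail,
    select_significant,
)
from toxfocus.go_sets import GeneSet


def exact_upper_tail(k, K, n, N):
    """Closed-form oracle in exact integer arithmetic."""
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return Fraction(num, comb(N, n))


def enumeration_upper_tail(k, K, n, N):
    """Brute force: enumerate every n-subset of an N-gene universe."""
    universe = range(N)
    query = set(range(K))
    hits = sum(
        1 for draw in itertools.combinations(universe, n) if len(query & set(draw)) >= k
    )
    return Fraction(hits, comb(N, n))


class TestHypergeomUpperTail:
    def test_zero_overlap_has_probability_one(self):
        assert hypergeom_upper_tail(0, 5, 5, 10) == 1.0
        assert hypergeom_upper_tail(0, 0, 3, 10) == 1.0

    def test_full_overlap_closed_form(self):
        # P(X=5) = C(5,5)C(5,0)/C(10,5) = 1/252
        assert hypergeom_upper_tail(5, 5, 5, 10) == pytest.approx(1 / 252, abs=1e-12)

    def test_query_fully_inside_pathway(self):
        # C(10,4)/C(20,4) = 210/4845
        assert hypergeom_upper_tail(4, 10, 4, 20) == pytest.approx(
            210 / 4845, abs=1e-12
        )

    @pytest.mark.parametrize("k,K,n,N", [(6, 5, 10, 20), (3, 5, 2, 20), (0, 5, 5, 4)])
    def test_inconsistent_counts_rejected(self, k, K, n, N):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(k, K, n, N)

    def test_matches_exact_closed_form_on_random_instances(self, rng):
        for _ in range(400):
            N = int(rng.integers(2, 31))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            expected = float(exact_upper_tail(k, K, n, N))
            assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(
                expected, abs=1e-12
            )

    def test_matches_subset_enumeration_at_tiny_n(self, rng):
        for _ in range(25):
            N = int(rng.integers(2, 11))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            assert exact_upper_tail(k, K, n, N) == enumeration_upper_tail(k, K, n, N)
            assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(
                float(enumeration_upper_tail(k, K, n, N)), abs=1e-12
            )


def bh_direct(pvalues):
    """Direct step-up definition: q_(i) = min_{j>=i} m·p_(j)/j, clipped at 1."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, m * pvalues[i] / rank)
        adjusted[i] = running_min
    return adjusted


class TestBHAdjust:
    def test_single_value_identity(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_hand_computed_examples(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_adjust([0.5, 0.01]) == pytest.approx([0.5, 0.02])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_direct_definition(self, pvalues):
        adjusted = bh_adjust(pvalues)
        expected = bh_direct(pvalues)
        assert adjusted == pytest.approx(expected, abs=1e-12)
        # q >= p elementwise, and adjusted values sort like the raw ones
        assert all(q >= p - 1e-15 for q, p in zip(adjusted, pvalues))
        order = sorted(range(len(pvalues)), key=lambda i: pvalues[i])
        assert all(
            adjusted[order[i]] <= adjusted[order[i + 1]] + 1e-15
            for i in range(len(order) - 1)
        )


def _universe_sets():
    universe = [f"g{i}" for i in range(20)]
    pathway = GeneSet("WP1", "pathway one", frozenset(universe[:10]))
    return universe, pathway


class TestEnrich:
    def test_single_pathway_matches_closed_form(self):
        universe, pathway = _universe_sets()
        (result,) = enrich(
            universe[:4],
            [pathway],
            measured=universe,
            config=EnrichmentConfig(universe_mode="measured"),
        )
        assert (result.k, result.n, result.K, result.N) == (4, 10, 4, 20)
        assert result.pvalue == pytest.approx(210 / 4845, abs=1e-12)
        assert result.hit_genes == frozenset(universe[:4])

    def test_small_sets_excluded_by_min_size(self):
        universe, pathway = _universe_sets()
        small = GeneSet("WP2", "too small", frozenset(universe[:5]))
        results = enrich(
            universe[:4], [pathway, small], measured=universe,
            config=EnrichmentConfig(universe_mode="measured"),
        )
        assert [r.set_id for r in results] == ["WP1"]

    def test_disjoint_query_scores_one(self):
        universe, pathway = _universe_sets()
        results = enrich(
            universe[10:14], [pathway], measured=universe,
            config=EnrichmentConfig(universe_mode="measured"),
        )
        assert results[0].k == 0 and results[0].pvalue == 1.0

    def test_universe_modes_change_background_size(self):
        universe, pathway = _universe_sets()
        other = GeneSet("WP3", "other", frozenset(universe[10:20]))
        r_coll = enrich(universe[:4], [pathway, other],
                        config=EnrichmentConfig(universe_mode="collection"))
        r_meas = enrich(universe[:4], [pathway, other], measured=universe[:15],
                        config=EnrichmentConfig(universe_mode="intersection"))
        assert r_coll[0].N == 20 and r_meas[0].N == 15

    def test_empty_query_within_universe_is_an_error(self):
        universe, pathway = _universe_sets()
        with pytest.raises(ValueError, match="query"):
            enrich(["absent"], [pathway], measured=universe,
                   config=EnrichmentConfig(universe_mode="measured"))

    def test_collection_order_does_not_matter(self, rng):
        universe = [f"g{i}" for i in range(40)]
        sets = [
            GeneSet(f"S{i}", "", frozenset(rng.choice(universe, 12, replace=False).tolist()))
            for i in range(6)
        ]
        query = rng.choice(universe, 8, replace=False).tolist()
        cfg = EnrichmentConfig(universe_mode="measured")
        forward = enrich(query, sets, measured=universe, config=cfg)
        backward = enrich(query, sets[::-1], measured=universe, config=cfg)
        assert forward == backward  # already sorted by (p, set_id)

    def test_qvalues_are_bh_over_retained_sets(self):
        universe = [f"g{i}" for i in range(30)]
        sets = [
            GeneSet("A", "", frozenset(universe[:10])),
            GeneSet("B", "", frozenset(universe[10:20])),
            GeneSet("C", "", frozenset(universe[20:30])),
        ]
        results = enrich(universe[:6], sets, measured=universe,
                         config=EnrichmentConfig(universe_mode="measured"))
        by_id = {r.set_id: r for r in results}
        expected_q = bh_adjust([by_id[s].pvalue for s in "ABC"])
        for s, q in zip("ABC", expected_q):
            assert by_id[s].qvalue == pytest.approx(q)


class TestSelectSignificant:
    def _results(self, pvalues, qvalues):
        universe, pathway = _universe_sets()
        base = enrich(universe[:4], [pathway], measured=universe,
                      config=EnrichmentConfig(universe_mode="measured"))[0]
        from dataclasses import replace

        return [replace(base, set_id=f"S{i}", pvalue=p, qvalue=q)
                for i, (p, q) in enumerate(zip(pvalues, qvalues))]

    def test_selection_is_strict_at_the_threshold(self):
        results = self._results([0.01, 0.05, 0.2], [0.03, 0.1, 0.3])
        kept = select_significant(results, EnrichmentConfig(p_select=0.05))
        assert [r.pvalue for r in kept] == [0.01]

    def test_threshold_one_keeps_everything(self):
        results = self._results([0.01, 0.05, 0.2], [0.03, 0.1, 0.3])
        assert len(select_significant(results, EnrichmentConfig(p_select=1.0))) == 3

    def test_selection_on_q_values(self):
        results = self._results([0.01, 0.03], [0.03, 0.2])
        kept = select_significant(
            results, EnrichmentConfig(p_select=0.05, select_on="bh_q")
        )
        assert [r.qvalue for r in kept] == [0.03]
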