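from fractions import Fraction

import pytest

from conftest import random_gene_sets
from toxfocus.go_sets import GeneSet
from toxfocus.tox_classify import (
    as_cutoff,
    classify_pathways,
    classify_pathways_ora,
    compare_classifiers,
    cutoff_sweep,
    overlap_fraction,
)


def make_set(set_id, genes):
    return GeneSet(set_id, set_id, frozenset(genes))


class TestOverlapFraction:
    def test_half_overlap(self):
        score = overlap_fraction(make_set("P", "abcd"), make_set("G", "ab"))
        assert (score.intersection, score.pathway_size) == (2, 4)
        assert score.fraction == Fraction(1, 2)

    def test_disjoint_sets_score_zero(self):
        assert overlap_fraction(make_set("P", "abc"), make_set("G", "xyz")).fraction == 0

    def test_pathway_inside_go_set_scores_one(self):
        assert overlap_fraction(make_set("P", "ab"), make_set("G", "abcd")).fraction == 1

    def test_empty_pathway_rejected(self):
        with pytest.raises(ValueError):
            overlap_fraction(make_set("P", ""), make_set("G", "ab"))


class TestAsCutoff:
    @pytest.mark.parametrize(
        "value, expected",
        [(0.5, Fraction(1, 2)), (0.6, Fraction(3, 5)), ("7/10", Fraction(7, 10)),
         (Fraction(4, 5), Fraction(4, 5)), (1, Fraction(1))],
    )
    def test_coercion_snaps_floats_to_exact_rationals(self, value, expected):
        assert as_cutoff(value) == expected

    @pytest.mark.parametrize("value", [0, -0.1, 1.5])
    def test_out_of_range_rejected(self, value):
        with pytest.raises(ValueError):
            as_cutoff(value)


class TestClassifyPathways:
    @pytest.mark.parametrize(
        "cutoff", [Fraction(1, 2), Fraction(3, 5), Fraction(7, 10), Fraction(4, 5)]
    )
    def test_fraction_exactly_at_cutoff_is_labeled(self, cutoff):
        # pathway of size = denominator with exactly numerator genes in the set
        size = cutoff.denominator * 2
        k = cutoff.numerator * 2
        genes = [f"g{i}" for i in range(size)]
        pathway = make_set("P", genes)
        go = make_set("GO:0000001", genes[:k])
        (label,) = classify_pathways([pathway], [go], cutoff)
        assert label.terms == frozenset({"GO:0000001"})

    def test_just_below_cutoff_not_labeled(self):
        genes = [f"g{i}" for i in range(20)]
        pathway = make_set("P", genes)
        go = make_set("GO:0000001", genes[:15])  # 0.75 < 0.8
        (label,) = classify_pathways([pathway], [go], Fraction(4, 5))
        assert label.terms == frozenset()

    def test_pathway_can_carry_multiple_terms(self):
        genes = [f"g{i}" for i in range(10)]
        pathway = make_set("P", genes)
        go1 = make_set("GO:0000001", genes[:5])
        go2 = make_set("GO:0000002", genes[5:])
        (label,) = classify_pathways([pathway], [go1, go2], "1/2")
        assert label.terms == frozenset({"GO:0000001", "GO:0000002"})

    def test_labels_shrink_as_cutoff_rises(self, rng):
        pathways = random_gene_sets(rng, 20, prefix="P")
        go_sets = random_gene_sets(rng, 3, prefix="GO:000000")
        low = {l.pathway_id: l.terms for l in classify_pathways(pathways, go_sets, "1/4")}
        high = {l.pathway_id: l.terms for l in classify_pathways(pathways, go_sets, "3/4")}
        assert all(high[p] <= low[p] for p in low)


class TestCutoffSweep:
    def test_planted_fraction_staircase(self):
        go_genes = [f"t{i}" for i in range(100)]
        go = make_set("GO:0000001", go_genes)
        in_counts = [11, 13, 15, 17]  # of 20 genes: fractions 0.55/0.65/0.75/0.85
        pathways = []
        for j, k in enumerate(in_counts):
            inside = [go_genes[20 * j + i] for i in range(k)]
            outside = [f"o{j}_{i}" for i in range(20 - k)]
            pathways.append(make_set(f"P{j}", inside + outside))
        table = cutoff_sweep(pathways, [go], [0.5, 0.6, 0.7, 0.8])
        assert table.loc["GO:0000001"].tolist() == [4, 3, 2, 1]

    def test_cutoff_one_counts_full_containment_only(self):
        go = make_set("GO:0000001", "abcdef")
        contained = make_set("P1", "abc")
        partial = make_set("P2", "abx")
        table = cutoff_sweep([contained, partial], [go], [1.0])
        assert table.loc["GO:0000001", "1"] == 1

    def test_counts_non_increasing_in_cutoff_on_random_collections(self, rng):
        for _ in range(20):
            pathways = random_gene_sets(rng, 15, prefix="P")
            go_sets = random_gene_sets(rng, 3, prefix="GO:000000")
            table = cutoff_sweep(pathways, go_sets, [0.5, 0.6, 0.7, 0.8])
            for term in table.index:
                counts = table.loc[term].tolist()
                assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestClassifyPathwaysORA:
    def test_pathway_inside_small_go_set_is_labeled(self):
        universe = [f"g{i}" for i in range(1000)]
        go = make_set("GO:0000001", universe[:50])
        pathway = make_set("P", universe[:20])
        (label,) = classify_pathways_ora([pathway], [go], universe=universe)
        assert label.terms == frozenset({"GO:0000001"})

    def test_go_set_equal_to_universe_never_labels(self):
        universe = [f"g{i}" for i in range(100)]
        go = make_set("GO:0000001", universe)
        pathway = make_set("P", universe[:20])
        (label,) = classify_pathways_ora([pathway], [go], universe=universe)
        assert label.terms == frozenset()

    def test_null_false_positive_rate_near_alpha(self, rng):
        # pathways sampled uniformly from the universe should be labeled
        # with probability ~ alpha
        universe = [f"g{i}" for i in range(2000)]
        go = make_set("GO:0000001", universe[:200])
        pathways = [
            make_set(f"P{i}", rng.choice(universe, 100, replace=False).tolist())
            for i in range(400)
        ]
        labels = classify_pathways_ora(pathways, [go], universe=universe)
        rate = sum(1 for l in labels if l.terms) / len(labels)
        assert 0.01 <= rate <= 0.10

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            classify_pathways_ora([make_set("P", "ab")], [make_set("G", "ab")], universe=[])


class TestCompareClassifiers:
    def test_ora_counts_at_least_match_half_cutoff_on_planted_fixture(self, toy):
        _, pathways, go_sets, _ = toy
        table = compare_classifiers(pathways, go_sets)
        for term in table.index:
            assert table.loc[term, "ora"] >= table.loc[term, "1/2"]

    def test_empty_collection_gives_all_zero_table(self):
        go = make_set("GO:0000001", "abc")
        table = compare_classifiers([], [go])
        assert (table.to_numpy() == 0).all()

    def test_deterministic_on_repeated_input(self, toy):
        _, pathways, go_sets, _ = toy
        first = compare_classifiers(pathways, go_sets)
        second = compare_classifiers(pathways, go_sets)
        assert first.equals(second)
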