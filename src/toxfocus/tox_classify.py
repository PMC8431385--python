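"""Classify pathways into toxicity categories by gene overlap with focus GO terms.

The classification statistic is the overlap fraction

    |pathway genes ∩ GO-term genes| / |pathway genes|

i.e. the share of the pathway that is directly linked to the term.  A pathway
is labeled with a term when its fraction is *at least* the cutoff (default
50%: at least half of the pathway belongs to the term).  Fractions are kept
as exact integer ratios and the cutoff comparison is done in rational
arithmetic, so a pathway sitting exactly on the cutoff (e.g. 10/20 at 1/2)
is labeled deterministically, with no floating-point edge effects.

A pathway may carry several terms (the focus processes overlap biologically),
or none — an empty label means "not toxicity-related".

Two classifiers are provided: the fraction/cutoff rule above (with a cutoff
sweep over 50/60/70/80% for sensitivity analysis), and an ORA-based
alternative that instead asks whether the pathway's genes are
overrepresented in each GO gene list (hypergeometric, raw p < alpha, no
multiple-testing correction and no size filters by default).  The ORA route
is far more permissive — it flags a pathway on any excess overlap, however
small a share of the pathway — which is why the fraction rule is the
default.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd

from .enrichment import hypergeom_upper_tail
from .go_sets import GeneSet

DEFAULT_CUTOFF = Fraction(1, 2)
DEFAULT_SWEEP = (Fraction(1, 2), Fraction(3, 5), Fraction(7, 10), Fraction(4, 5))


def as_cutoff(value: float | str | Fraction) -> Fraction:
    """Coerce a cutoff to an exact Fraction in (0, 1].

    Accepts a Fraction, a string like ``"3/5"`` or ``"0.6"``, or a float
    (snapped to the nearest small-denominator rational, so 0.6 becomes 3/5
    rather than its binary approximation).
    """
    if isinstance(value, Fraction):
        cutoff = value
    elif isinstance(value, str):
        cutoff = Fraction(value)
    elif isinstance(value, int):
        cutoff = Fraction(value)
    else:
        cutoff = Fraction(value).limit_denominator(10_000)
    if not 0 < cutoff <= 1:
        raise ValueError(f"cutoff must lie in (0, 1], got {value!r}")
    return cutoff


@dataclass(frozen=True)
class OverlapScore:
    """Exact overlap of one pathway with one GO-term gene set."""

    pathway_id: str
    term_id: str
    intersection: int
    pathway_size: int

    def __post_init__(self) -> None:
        if not 0 <= self.intersection <= self.pathway_size or self.pathway_size < 1:
            raise ValueError(
                f"inconsistent overlap counts for {self.pathway_id}/{self.term_id}: "
                f"{self.intersection}/{self.pathway_size}"
            )

    @property
    def fraction(self) -> Fraction:
        return Fraction(self.intersection, self.pathway_size)


@dataclass(frozen=True)
class ToxicityLabel:
    """The focus terms a pathway is classified into at a given cutoff."""

    pathway_id: str
    terms: frozenset[str]
    cutoff: Fraction

    @property
    def is_toxicity_related(self) -> bool:
        return bool(self.terms)


def overlap_fraction(pathway: GeneSet, go_set: GeneSet) -> OverlapScore:
    """Score one pathway against one GO gene set.

    The denominator is the pathway's full gene list as parsed (it is not
    intersected with any universe).  An empty pathway has no defined fraction
    and is a domain error.
    """
    if not pathway.genes:
        raise ValueError(f"pathway {pathway.set_id!r} has no genes")
    return OverlapScore(
        pathway_id=pathway.set_id,
        term_id=go_set.set_id,
        intersection=len(pathway.genes & go_set.genes),
        pathway_size=len(pathway.genes),
    )


def overlap_scores(
    collection: Sequence[GeneSet], go_sets: Sequence[GeneSet]
) -> list[OverlapScore]:
    """All pathway × term overlap scores, in input order."""
    return [overlap_fraction(p, g) for p in collection for g in go_sets]


def classify_pathways(
    collection: Sequence[GeneSet],
    go_sets: Sequence[GeneSet],
    cutoff: float | str | Fraction = DEFAULT_CUTOFF,
) -> list[ToxicityLabel]:
    """Label every pathway with the focus terms whose overlap fraction >= cutoff."""
    c = as_cutoff(cutoff)
    labels = []
    for pathway in collection:
        terms = frozenset(
            g.set_id for g in go_sets if overlap_fraction(pathway, g).fraction >= c
        )
        labels.append(ToxicityLabel(pathway_id=pathway.set_id, terms=terms, cutoff=c))
    return labels


def cutoff_sweep(
    collection: Sequence[GeneSet],
    go_sets: Sequence[GeneSet],
    cutoffs: Iterable[float | str | Fraction] = DEFAULT_SWEEP,
) -> pd.DataFrame:
    """Count labeled pathways per term at each cutoff.

    Returns a DataFrame indexed by term id with one column per cutoff
    (stringified fraction); counts are non-increasing left to right when the
    cutoffs increase.
    """
    cuts = [as_cutoff(c) for c in cutoffs]
    scores = {
        (p.set_id, g.set_id): overlap_fraction(p, g).fraction
        for p in collection
        for g in go_sets
    }
    data = {
        str(c): [
            sum(1 for p in collection if scores[(p.set_id, g.set_id)] >= c)
            for g in go_sets
        ]
        for c in cuts
    }
    return pd.DataFrame(data, index=[g.set_id for g in go_sets])


def classify_pathways_ora(
    collection: Sequence[GeneSet],
    go_sets: Sequence[GeneSet],
    universe: Iterable[str] | None = None,
    alpha: float = 0.05,
) -> list[ToxicityLabel]:
    """ORA-based alternative: label a pathway with a term when its genes are
    overrepresented in the term's gene list (hypergeometric upper tail,
    raw p < alpha; no multiple-testing correction).

    ``universe`` defaults to the union of all pathway and GO-set genes; both
    pathway and GO sets are intersected with it before testing.  The
    degenerate case GO set == universe gives p = 1 and is never labeled.
    """
    if universe is None:
        u: set[str] = set()
        for s in (*collection, *go_sets):
            u |= s.genes
    else:
        u = set(universe)
    if not u:
        raise ValueError("empty universe for ORA-based classification")
    N = len(u)
    labels = []
    for pathway in collection:
        pgenes = pathway.genes & u
        terms = set()
        for g in go_sets:
            ggenes = g.genes & u
            k = len(pgenes & ggenes)
            p = hypergeom_upper_tail(k, len(ggenes), len(pgenes), N)
            if p < alpha:
                terms.add(g.set_id)
        labels.append(
            ToxicityLabel(
                pathway_id=pathway.set_id, terms=frozenset(terms), cutoff=Fraction(0)
            )
        )
    return labels


def compare_classifiers(
    collection: Sequence[GeneSet],
    go_sets: Sequence[GeneSet],
    cutoffs: Iterable[float | str | Fraction] = DEFAULT_SWEEP,
    universe: Iterable[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term labeled-pathway counts from the cutoff sweep plus the ORA route.

    One row per focus term; one column per cutoff plus an ``ora`` column.
    """
    table = cutoff_sweep(collection, go_sets, cutoffs)
    if len(collection):
        ora = classify_pathways_ora(collection, go_sets, universe=universe, alpha=alpha)
        counts = {g.set_id: sum(1 for lab in ora if g.set_id in lab.terms) for g in go_sets}
    else:
        counts = {g.set_id: 0 for g in go_sets}
    table["ora"] = [counts[t] for t in table.index]
    return table


def labels_to_frame(
    labels: Sequence[ToxicityLabel],
    collection: Sequence[GeneSet],
    go_sets: Sequence[GeneSet],
) -> pd.DataFrame:
    """Long-format table: one row per pathway × term with counts, fraction, flag."""
    by_id = {lab.pathway_id: lab for lab in labels}
    rows = []
    for pathway in collection:
        lab = by_id[pathway.set_id]
        for g in go_sets:
            score = overlap_fraction(pathway, g)
            rows.append(
                {
                    "pathway_id": pathway.set_id,
                    "term_id": g.set_id,
                    "intersection": score.intersection,
                    "pathway_size": score.pathway_size,
                    "fraction": float(score.fraction),
                    "labeled": g.set_id in lab.terms,
                }
            )
    return pd.DataFrame(rows)
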