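"""Per-condition orchestration: DEG selection → ORA → toxicity filtering → summary.

Pathway toxicity labels depend only on the pathway collection, the GO gene
sets and the cutoff — not on any condition — so they are computed once and
joined to each condition's significant pathways.  A pathway that is
significantly overrepresented but carries no focus term contributes to the
"Significant" count only; pathways in the toxicity list are counted once per
focus term they carry, so per-term counts can sum to more than the number of
unique toxicity pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import pandas as pd

from .deg_filter import DEGCriteria, select_degs
from .enrichment import EnrichmentConfig, EnrichmentResult, enrich, select_significant
from .go_sets import GeneSet
from .io_formats import GeneStatTable
from .tox_classify import DEFAULT_CUTOFF, ToxicityLabel, classify_pathways

logger = logging.getLogger(__name__)


@dataclass
class ConditionResult:
    """Everything the workflow derives from one condition's gene statistics."""

    condition_id: str
    deg_count: int
    significant: list[EnrichmentResult]
    toxicity: list[tuple[EnrichmentResult, ToxicityLabel]]
    per_term_counts: dict[str, int]


def run_condition(
    stats: GeneStatTable,
    collection: Sequence[GeneSet],
    go_sets: Sequence[GeneSet],
    criteria: DEGCriteria | None = None,
    enr_config: EnrichmentConfig | None = None,
    cutoff: Fraction | float | str = DEFAULT_CUTOFF,
    labels: Sequence[ToxicityLabel] | None = None,
) -> ConditionResult:
    """Run the full per-condition analysis.

    ``labels`` may carry precomputed collection-level toxicity labels (they
    are condition-independent); otherwise they are computed here.  An empty
    DEG set is handled gracefully: no pathways are significant and all
    counts are zero.
    """
    criteria = criteria if criteria is not None else DEGCriteria()
    enr_config = enr_config if enr_config is not None else EnrichmentConfig()
    if labels is None:
        labels = classify_pathways(collection, go_sets, cutoff)
    labels_by_id = {lab.pathway_id: lab for lab in labels}

    try:
        degs = select_degs(stats, criteria)
        if degs:
            results = enrich(
                degs, collection, measured=stats.genes(), config=enr_config
            )
            significant = select_significant(results, enr_config)
        else:
            logger.warning(
                "condition %s: no differentially expressed genes", stats.condition_id
            )
            significant = []
    except ValueError as err:
        raise ValueError(f"condition {stats.condition_id}: {err}") from err

    toxicity = [
        (r, labels_by_id[r.set_id])
        for r in significant
        if labels_by_id[r.set_id].is_toxicity_related
    ]
    per_term_counts = {
        g.set_id: sum(1 for _, lab in toxicity if g.set_id in lab.terms)
        for g in go_sets
    }
    logger.info(
        "condition %s: %d DEGs, %d significant pathways, %d toxicity-related",
        stats.condition_id,
        len(degs),
        len(significant),
        len(toxicity),
    )
    return ConditionResult(
        condition_id=stats.condition_id,
        deg_count=len(degs),
        significant=significant,
        toxicity=toxicity,
        per_term_counts=per_term_counts,
    )


def summarize(
    results: Sequence[ConditionResult],
    collection: Sequence[GeneSet],
    go_sets: Sequence[GeneSet],
    cutoff: Fraction | float | str = DEFAULT_CUTOFF,
    labels: Sequence[ToxicityLabel] | None = None,
) -> pd.DataFrame:
    """Assemble the per-condition summary table.

    The first row ("Pathways") reports collection-level counts: total
    pathways, pathways labeled with at least one focus term, and per-term
    labeled counts.  Each following row gives one condition's number of
    significant pathways, of significant toxicity-related pathways, and the
    per-term breakdown.  Row order follows the input.
    """
    if not results:
        raise ValueError("summarize requires at least one condition result")
    if labels is None:
        labels = classify_pathways(collection, go_sets, cutoff)
    term_cols = [g.name for g in go_sets]
    header = [
        len(collection),
        sum(1 for lab in labels if lab.is_toxicity_related),
        *(
            sum(1 for lab in labels if g.set_id in lab.terms)
            for g in go_sets
        ),
    ]
    rows = [header]
    index = ["Pathways"]
    for res in results:
        rows.append(
            [
                len(res.significant),
                len(res.toxicity),
                *(res.per_term_counts.get(g.set_id, 0) for g in go_sets),
            ]
        )
        index.append(res.condition_id)
    return pd.DataFrame(
        rows, index=index, columns=["Significant", "Toxicity", *term_cols]
    )
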