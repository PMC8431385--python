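"""Differential-expression filtering and four-way volcano categorization.

A gene is called differentially expressed when it passes both a fold-change
and a p-value criterion: absolute fold change greater than 1.2 (log2 fold
change below -log2(1.2) or above +log2(1.2), i.e. beyond the printed +/-0.26)
and p-value below 0.05.  Both inequalities are strict: a gene exactly at a
threshold does not pass.

The working fold-change threshold is the unrounded log2(1.2) ~= 0.26303;
0.26 is the rounded display value.  For strict replication of analyses that
filtered on the literal rounded value, construct the criteria with
``criteria_from_fold_change(..., use_rounded=True)`` — behaviour differs only
for |log2fc| in (0.26, 0.26303].
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from enum import Enum

from .io_formats import GeneStatTable


class VolcanoCategory(str, Enum):
    """Which of the two DEG criteria a gene meets; partitions any table."""

    BOTH = "both"
    P_ONLY = "p_only"
    FC_ONLY = "fc_only"
    NONE = "none"


@dataclass(frozen=True)
class DEGCriteria:
    """Symmetric log2 fold-change magnitude and p-value thresholds.

    Parameters
    ----------
    log2fc_magnitude
        Positive working threshold on |log2 fold change| (default log2(1.2)).
    p_threshold
        Upper (exclusive) bound on the raw p-value (default 0.05).
    rounding
        Decimal places used when *reporting* the fold-change threshold
        (default 2, printing log2(1.2) as 0.26); never used in filtering.
    """

    log2fc_magnitude: float = math.log2(1.2)
    p_threshold: float = 0.05
    rounding: int = 2

    def __post_init__(self) -> None:
        if not self.log2fc_magnitude > 0:
            raise ValueError("log2fc_magnitude must be positive")
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must lie in (0, 1]")

    @property
    def printed_log2fc(self) -> float:
        """The display value of the threshold, rounded to ``rounding`` decimals."""
        return round(self.log2fc_magnitude, self.rounding)


def criteria_from_fold_change(
    fold_change: float,
    p_threshold: float = 0.05,
    rounding: int = 2,
    use_rounded: bool = False,
) -> DEGCriteria:
    """Build criteria from a linear fold-change cutoff (> 1).

    With ``use_rounded=True`` the working threshold is the rounded display
    value (0.26 for fold change 1.2) instead of the exact log2.
    """
    if not fold_change > 1:
        raise ValueError(f"fold_change must exceed 1, got {fold_change}")
    magnitude = math.log2(fold_change)
    if use_rounded:
        magnitude = round(magnitude, rounding)
    return DEGCriteria(
        log2fc_magnitude=magnitude, p_threshold=p_threshold, rounding=rounding
    )


def categorize(
    table: GeneStatTable, criteria: DEGCriteria | None = None
) -> dict[str, VolcanoCategory]:
    """Assign every gene to one of the four volcano-plot categories.

    The fold-change criterion is met iff log2fc < -magnitude or
    log2fc > +magnitude; the p criterion iff p < p_threshold (both strict).
    """
    crit = criteria if criteria is not None else DEGCriteria()
    fc_ok = table.frame["log2fc"].abs() > crit.log2fc_magnitude
    p_ok = table.frame["pvalue"] < crit.p_threshold
    out: dict[str, VolcanoCategory] = {}
    for gene, fc, p in zip(table.frame["gene_id"], fc_ok, p_ok):
        if fc and p:
            out[gene] = VolcanoCategory.BOTH
        elif p:
            out[gene] = VolcanoCategory.P_ONLY
        elif fc:
            out[gene] = VolcanoCategory.FC_ONLY
        else:
            out[gene] = VolcanoCategory.NONE
    return out


def select_degs(table: GeneStatTable, criteria: DEGCriteria | None = None) -> set[str]:
    """Genes meeting both criteria (the ``both`` volcano category)."""
    crit = criteria if criteria is not None else DEGCriteria()
    frame = table.frame
    mask = (frame["log2fc"].abs() > crit.log2fc_magnitude) & (
        frame["pvalue"] < crit.p_threshold
    )
    return set(frame.loc[mask, "gene_id"])


def category_counts(categories: dict[str, VolcanoCategory]) -> Counter:
    """Tally genes per volcano category."""
    return Counter(categories.values())
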