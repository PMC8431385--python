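"""Gene sets, GO gene-set construction with evidence filtering, and Venn overlaps.

A :class:`GeneSet` is the shared container for both pathway gene sets (from a
GMT collection) and GO-term gene sets (built from annotation records).  GO sets
are built from *direct* annotations only — no propagation up the GO hierarchy
is performed, so a gene annotated only to a child term does not appear in the
parent's set.

Only annotations backed by experimental or manually curated evidence are kept
by default.  The default whitelist covers the codes commonly accepted as
high-confidence: IBA, IC, IDA, IEP, IGI, IMP, IPI, TAS.  Electronic (IEA) and
sequence-similarity (ISS-family) annotations are excluded.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ConfigError

logger = logging.getLogger(__name__)

GO_ID_PATTERN = re.compile(r"^GO:\d{7}$")

#: Evidence codes for experimental or manually curated GO annotations.
DEFAULT_EVIDENCE_WHITELIST = frozenset(
    {"IBA", "IC", "IDA", "IEP", "IGI", "IMP", "IPI", "TAS"}
)

#: The four default focus terms: apoptosis, inflammation, DNA damage,
#: oxidative stress (biological-process terms).
DEFAULT_FOCUS_TERMS = (
    ("GO:0006915", "apoptotic process"),
    ("GO:0006954", "inflammatory response"),
    ("GO:0006974", "cellular response to DNA damage stimulus"),
    ("GO:0006979", "response to oxidative stress"),
)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (a pathway or a GO-term gene set).

    Gene identifiers are opaque, case-sensitive strings; no namespace mapping
    is performed.
    """

    set_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass(frozen=True)
class EvidenceWhitelist:
    """Set of accepted GO evidence codes; matching is exact-token, case-insensitive."""

    codes: frozenset[str] = DEFAULT_EVIDENCE_WHITELIST

    def __post_init__(self) -> None:
        codes = frozenset(c.upper() for c in self.codes)
        if not codes:
            raise ValueError("evidence whitelist must not be empty")
        object.__setattr__(self, "codes", codes)

    def accepts(self, evidence_code: str) -> bool:
        return evidence_code.upper() in self.codes


def build_go_set(
    annotations: Iterable,  # Iterable[AnnotationRecord]
    term_id: str,
    whitelist: EvidenceWhitelist | None = None,
    name: str | None = None,
) -> GeneSet:
    """Collect the genes directly annotated to ``term_id`` with whitelisted evidence.

    Parameters
    ----------
    annotations
        Records with ``gene_id``, ``term_id`` and ``evidence_code`` attributes
        (see :func:`toxfocus.io_formats.read_annotations`).
    term_id
        Well-formed GO identifier, e.g. ``"GO:0006915"``.
    whitelist
        Accepted evidence codes; defaults to the experimental/curated set.
    name
        Human-readable label stored on the returned set (defaults to the id).

    An empty result is not an error — downstream overlap math treats an empty
    GO set as zero overlap — but it is logged as a warning.
    """
    if not GO_ID_PATTERN.match(term_id):
        raise ValueError(f"malformed GO identifier: {term_id!r}")
    wl = whitelist if whitelist is not None else EvidenceWhitelist()
    genes = frozenset(
        rec.gene_id
        for rec in annotations
        if rec.term_id == term_id and wl.accepts(rec.evidence_code)
    )
    if not genes:
        logger.warning("GO term %s has no genes after evidence filtering", term_id)
    return GeneSet(set_id=term_id, name=name if name is not None else term_id, genes=genes)


def build_go_sets(
    annotations: Sequence,
    terms: Iterable[tuple[str, str]] = DEFAULT_FOCUS_TERMS,
    whitelist: EvidenceWhitelist | None = None,
) -> list[GeneSet]:
    """Build one evidence-filtered gene set per ``(term_id, label)`` pair."""
    annotations = list(annotations)
    return [
        build_go_set(annotations, term_id, whitelist=whitelist, name=label)
        for term_id, label in terms
    ]


def venn_counts(sets: Sequence[GeneSet]) -> dict[str, int]:
    """Count genes in each exclusive membership region of 2–5 gene sets.

    Returns a mapping from membership signature to gene count, where the
    signature is a string of ``"0"``/``"1"`` flags in input-set order (e.g.
    ``"10"`` = first set only, ``"11"`` = both).  Only non-empty regions are
    reported; the counts sum to the size of the union, and every gene is
    counted in exactly one region.
    """
    k = len(sets)
    if not 2 <= k <= 5:
        raise ValueError(f"venn_counts requires 2-5 sets, got {k}")
    counts: dict[str, int] = {}
    universe = set().union(*(s.genes for s in sets))
    for gene in universe:
        sig = "".join("1" if gene in s.genes else "0" for s in sets)
        counts[sig] = counts.get(sig, 0) + 1
    return counts


def venn_region_ids(k: int) -> list[str]:
    """All 2^k - 1 non-trivial membership signatures for k sets, sorted."""
    return [
        "".join(bits)
        for bits in itertools.product("01", repeat=k)
        if "1" in bits
    ]


def focus_terms_from_config(entries: Sequence[Mapping[str, str]]) -> list[tuple[str, str]]:
    """Parse ``[{term_id, label}, ...]`` config entries into (id, label) pairs."""
    terms: list[tuple[str, str]] = []
    for entry in entries:
        term_id = entry.get("term_id")
        if term_id is None or not GO_ID_PATTERN.match(term_id):
            raise ConfigError(f"focus term entry has a malformed term_id: {entry!r}")
        terms.append((term_id, entry.get("label", term_id)))
    return terms
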