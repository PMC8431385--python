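"""Readers and writers for the external formats the workflow touches.

Supported formats:

* gene-statistics tables — TSV with a header row naming at least a gene
  identifier, a log2 fold-change and a p-value column;
* GMT (Broad dialect) — one gene set per line: name, description/URL, genes;
* GO annotations — GAF 2.x or a simple 3-column ``gene<TAB>term<TAB>evidence``
  TSV;
* edge/node TSV pairs for pathway-gene bipartite networks.

All readers report how many rows they kept versus dropped, so
``kept + dropped`` always equals the number of non-comment input rows.
Gene identifiers are treated as opaque case-sensitive strings throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError
from .go_sets import GO_ID_PATTERN, GeneSet

if TYPE_CHECKING:  # pragma: no cover
    from .network import BipartiteNetwork


@dataclass
class ParseReport:
    """Bookkeeping for a single file parse: rows seen, kept, dropped, and why."""

    n_rows: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    messages: list[str] = field(default_factory=list)


class AnnotationRecord(NamedTuple):
    """One gene-to-GO-term assignment with its evidence code."""

    gene_id: str
    term_id: str
    evidence_code: str


@dataclass
class GeneStatTable:
    """Per-gene log2 fold change and p-value for one experimental condition.

    ``frame`` has columns ``gene_id`` (unique), ``log2fc`` (finite float) and
    ``pvalue`` (float in [0, 1]); invariants are enforced at construction.
    """

    condition_id: str
    frame: pd.DataFrame
    report: ParseReport = field(default_factory=ParseReport)

    def __post_init__(self) -> None:
        required = {"gene_id", "log2fc", "pvalue"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"gene-stat frame missing columns: {sorted(missing)}")
        dup = self.frame["gene_id"][self.frame["gene_id"].duplicated()]
        if len(dup):
            raise ValueError(
                f"duplicate gene_id in condition {self.condition_id!r}: "
                f"{sorted(dup.unique().tolist())}"
            )
        if not np.isfinite(self.frame["log2fc"].to_numpy()).all():
            raise ValueError("log2fc values must be finite")
        p = self.frame["pvalue"].to_numpy()
        if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
            raise ValueError("pvalues must lie in [0, 1]")
        self.frame = self.frame.reset_index(drop=True)

    def genes(self) -> set[str]:
        return set(self.frame["gene_id"])

    def __len__(self) -> int:
        return len(self.frame)


DEFAULT_STAT_COLUMNS = {"gene_id": "gene", "log2fc": "log2fc", "pvalue": "pvalue"}


def read_gene_stats(
    path: str | Path,
    condition_id: str,
    columns: dict[str, str] | None = None,
) -> GeneStatTable:
    """Read a per-gene statistics TSV into a :class:`GeneStatTable`.

    ``columns`` maps the canonical names (``gene_id``, ``log2fc``, ``pvalue``)
    to the header names used in the file.  Rows with a missing gene id or a
    non-numeric/out-of-range statistic are dropped and counted in the parse
    report rather than failing the whole file; a missing required column or a
    duplicated gene id is fatal.
    """
    colmap = dict(DEFAULT_STAT_COLUMNS)
    if columns:
        colmap.update(columns)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    for canonical, header in colmap.items():
        if header not in raw.columns:
            raise FormatError(
                f"{path}: required column {header!r} (for {canonical}) not found; "
                f"columns present: {list(raw.columns)}"
            )
    frame = pd.DataFrame(
        {
            "gene_id": raw[colmap["gene_id"]],
            "log2fc": pd.to_numeric(raw[colmap["log2fc"]], errors="coerce"),
            "pvalue": pd.to_numeric(raw[colmap["pvalue"]], errors="coerce"),
        }
    )
    n_rows = len(frame)
    ok = (
        frame["gene_id"].notna()
        & np.isfinite(frame["log2fc"].fillna(np.nan))
        & frame["pvalue"].between(0.0, 1.0, inclusive="both")
    )
    report = ParseReport(n_rows=n_rows, n_kept=int(ok.sum()), n_dropped=int((~ok).sum()))
    if report.n_dropped:
        report.messages.append(
            f"dropped {report.n_dropped} rows with missing/invalid statistics"
        )
    kept = frame[ok]
    dup = kept["gene_id"][kept["gene_id"].duplicated()]
    if len(dup):
        raise FormatError(
            f"{path}: duplicate gene identifiers: {sorted(dup.unique().tolist())}"
        )
    return GeneStatTable(condition_id=condition_id, frame=kept, report=report)


def write_gene_stats(table: GeneStatTable, path: str | Path) -> None:
    out = table.frame.rename(
        columns={"gene_id": "gene", "log2fc": "log2fc", "pvalue": "pvalue"}
    )
    out.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: per line, set name, description/URL, then gene ids.

    Duplicate genes within a line are deduplicated; empty gene fields are
    skipped; input order of the sets is preserved.  A line with fewer than
    three fields is a format error reported with its line number.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT line has {len(fields)} fields, "
                    "expected at least 3 (name, description, genes...)"
                )
            name, description = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            sets.append(GeneSet(set_id=name, name=description or name, genes=genes))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    """Write gene sets as GMT; genes are sorted for deterministic output."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.name, *sorted(s.genes)]) + "\n")


# GAF 2.x column positions (0-based): DB object symbol, GO id, evidence code.
_GAF_SYMBOL_COL = 2
_GAF_GOID_COL = 4
_GAF_EVIDENCE_COL = 6


def read_annotations(
    path: str | Path, dialect: str = "tsv"
) -> tuple[list[AnnotationRecord], ParseReport]:
    """Read gene→GO annotations from GAF 2.x or a 3-column TSV.

    Rows with a malformed GO identifier or too few columns are skipped and
    counted, not fatal.  Exact duplicate records (same gene, term, evidence)
    are deduplicated silently, as annotation files routinely repeat
    assignments; duplicates count as dropped so kept + dropped = data rows.
    """
    if dialect not in ("gaf", "tsv"):
        raise ValueError(f"unknown annotation dialect: {dialect!r}")
    records: list[AnnotationRecord] = []
    seen: set[AnnotationRecord] = set()
    report = ParseReport()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            report.n_rows += 1
            fields = line.split("\t")
            if dialect == "gaf":
                if len(fields) <= _GAF_EVIDENCE_COL:
                    report.n_dropped += 1
                    continue
                gene, term, evidence = (
                    fields[_GAF_SYMBOL_COL],
                    fields[_GAF_GOID_COL],
                    fields[_GAF_EVIDENCE_COL],
                )
            else:
                if len(fields) < 3:
                    report.n_dropped += 1
                    continue
                gene, term, evidence = fields[0], fields[1], fields[2]
            if not gene or not evidence or not GO_ID_PATTERN.match(term):
                report.n_dropped += 1
                continue
            rec = AnnotationRecord(gene, term, evidence)
            if rec in seen:
                report.n_dropped += 1
                continue
            seen.add(rec)
            records.append(rec)
    report.n_kept = len(records)
    if report.n_dropped:
        report.messages.append(
            f"skipped {report.n_dropped} malformed/short/duplicate annotation rows"
        )
    return records, report


def write_annotations(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    """Write annotation records in the simple 3-column TSV dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f"{rec.gene_id}\t{rec.term_id}\t{rec.evidence_code}\n")


def write_edge_node_files(
    network: "BipartiteNetwork", edge_path: str | Path, node_path: str | Path
) -> None:
    """Write a bipartite network as paired TSVs.

    The edge file has columns ``source`` (always the pathway) and ``target``
    (the gene).  The node file lists all unique nodes with ``id``, ``type``,
    ``label`` and, for pathway nodes, their comma-joined focus GO terms.
    """
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\n")
        for source, target in network.edges:
            fh.write(f"{source}\t{target}\n")
    with open(node_path, "w", encoding="utf-8") as fh:
        fh.write("id\ttype\tlabel\tgo_terms\n")
        for node in network.nodes:
            terms = ",".join(sorted(node.terms))
            fh.write(f"{node.id}\t{node.kind}\t{node.label}\t{terms}\n")


def read_edge_node_files(
    edge_path: str | Path, node_path: str | Path
) -> "BipartiteNetwork":
    """Read back the paired edge/node TSVs written by :func:`write_edge_node_files`."""
    from .network import BipartiteNetwork, Node

    nodes: list[Node] = []
    with open(node_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["id", "type", "label"]:
            raise FormatError(f"{node_path}: unexpected node-file header: {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{node_path}: line {lineno}: too few fields")
            terms = fields[3] if len(fields) > 3 else ""
            nodes.append(
                Node(
                    id=fields[0],
                    kind=fields[1],
                    label=fields[2],
                    terms=frozenset(t for t in terms.split(",") if t),
                )
            )
    edges: list[tuple[str, str]] = []
    with open(edge_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["source", "target"]:
            raise FormatError(f"{edge_path}: unexpected edge-file header: {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{edge_path}: line {lineno}: expected 2 fields")
            edges.append((fields[0], fields[1]))
    return BipartiteNetwork.from_parts(nodes, edges)
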