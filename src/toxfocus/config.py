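"""Run configuration: schema, validation with defaults, and the full-run driver.

A run config is a flat YAML/JSON document naming the input files, the
filtering thresholds and the output directory.  Validation injects defaults
(fold change 1.2, p < 0.05, gene-set sizes 10..300, overlap cutoff 1/2 with
sweep 0.5/0.6/0.7/0.8, the experimental/curated evidence whitelist), rejects
unknown keys by name, and the effective configuration is echoed into the
output directory together with input checksums and the package version, so
any run can be reproduced from its output directory alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import __version__
from .deg_filter import categorize, category_counts, criteria_from_fold_change
from .enrichment import EnrichmentConfig, results_to_frame
from .errors import ConfigError
from .go_sets import (
    DEFAULT_EVIDENCE_WHITELIST,
    DEFAULT_FOCUS_TERMS,
    EvidenceWhitelist,
    build_go_sets,
    focus_terms_from_config,
)
from .io_formats import read_annotations, read_gene_stats, write_gmt
from .network import build_network, export_network
from .pipeline import run_condition, summarize
from .tox_classify import (
    DEFAULT_SWEEP,
    as_cutoff,
    classify_pathways,
    compare_classifiers,
    labels_to_frame,
)

logger = logging.getLogger(__name__)

#: Allowed keys, their types, and defaults — the published config schema.
CONFIG_SCHEMA: dict[str, dict[str, Any]] = {
    "conditions": {"type": list, "default": []},
    "pathways_gmt": {"type": str, "default": None},
    "annotations": {"type": str, "default": None},
    "annotations_dialect": {"type": str, "default": "tsv", "choices": ("tsv", "gaf")},
    "focus_terms": {
        "type": list,
        "default": [{"term_id": t, "label": l} for t, l in DEFAULT_FOCUS_TERMS],
    },
    "evidence_whitelist": {"type": list, "default": sorted(DEFAULT_EVIDENCE_WHITELIST)},
    "fold_change": {"type": (int, float), "default": 1.2},
    "use_rounded_threshold": {"type": bool, "default": False},
    "p_threshold": {"type": (int, float), "default": 0.05},
    "min_set_size": {"type": int, "default": 10},
    "max_set_size": {"type": int, "default": 300},
    "p_select": {"type": (int, float), "default": 0.05},
    "select_on": {"type": str, "default": "raw_p", "choices": ("raw_p", "bh_q")},
    "universe_mode": {
        "type": str,
        "default": "intersection",
        "choices": ("collection", "measured", "intersection"),
    },
    "cutoff": {"type": (int, float, str), "default": "1/2"},
    "sweep": {"type": list, "default": ["1/2", "3/5", "7/10", "4/5"]},
    "gene_scope": {
        "type": str,
        "default": "hits",
        "choices": ("hits", "all_pathway_genes"),
    },
    "network_formats": {
        "type": list,
        "default": ["edge_node_tsv", "graphml", "sif"],
    },
    "stats_columns": {"type": dict, "default": {}},
    "out_dir": {"type": str, "default": "toxfocus_out"},
    "seed": {"type": int, "default": 0},
}


@dataclass(frozen=True)
class RunConfig:
    """Validated, fully-defaulted run configuration."""

    values: Mapping[str, Any] = field(default_factory=dict)

    def __getattr__(self, key: str) -> Any:
        try:
            return self.values[key]
        except KeyError:
            raise AttributeError(key) from None

    def to_dict(self) -> dict[str, Any]:
        return dict(self.values)


def validate_config(raw: Mapping[str, Any] | None) -> RunConfig:
    """Validate a raw config document against the schema and inject defaults.

    Unknown keys, wrong types, and infeasible values raise
    :class:`ConfigError` naming the offending key.  An empty document yields
    an all-defaults config (a fixed point: re-validating the echoed effective
    config returns an identical one).
    """
    raw = dict(raw or {})
    unknown = set(raw) - set(CONFIG_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    values: dict[str, Any] = {}
    for key, spec in CONFIG_SCHEMA.items():
        value = raw.get(key, spec["default"])
        if value is not None and not isinstance(value, spec["type"]):
            raise ConfigError(
                f"config key {key!r}: expected {spec['type']}, got {type(value).__name__}"
            )
        if "choices" in spec and value not in spec["choices"]:
            raise ConfigError(f"config key {key!r}: must be one of {spec['choices']}")
        values[key] = value
    # domain checks, each naming its key
    if not values["fold_change"] > 1:
        raise ConfigError("config key 'fold_change': must exceed 1")
    if not 0 < values["p_threshold"] <= 1:
        raise ConfigError("config key 'p_threshold': must lie in (0, 1]")
    if not 0 < values["p_select"] <= 1:
        raise ConfigError("config key 'p_select': must lie in (0, 1]")
    if not 1 <= values["min_set_size"] <= values["max_set_size"]:
        raise ConfigError("config key 'min_set_size': need 1 <= min <= max_set_size")
    try:
        as_cutoff(values["cutoff"])
        for c in values["sweep"]:
            as_cutoff(c)
    except (ValueError, ZeroDivisionError) as err:
        raise ConfigError(f"config key 'cutoff'/'sweep': {err}") from err
    for entry in values["conditions"]:
        if not isinstance(entry, Mapping) or "condition_id" not in entry or "stats" not in entry:
            raise ConfigError(
                "config key 'conditions': each entry needs 'condition_id' and 'stats'"
            )
    focus_terms_from_config(values["focus_terms"])
    if not values["evidence_whitelist"]:
        raise ConfigError("config key 'evidence_whitelist': must not be empty")
    return RunConfig(values=values)


def load_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        return validate_config(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_provenance(config: RunConfig, out: Path, inputs: Sequence[Path]) -> None:
    with open(out / "effective_config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    with open(out / "provenance.txt", "w", encoding="utf-8") as fh:
        fh.write(f"toxfocus version: {__version__}\n")
        for path in inputs:
            digest = _sha256(path) if path.exists() else "MISSING"
            fh.write(f"sha256 {digest}  {path.name}\n")


def run_all(config: RunConfig) -> int:
    """Execute the full workflow; returns 0 on success, 1 on any stage error.

    Stages: build GO sets from annotations → classify the collection →
    per-condition DEG/enrichment/toxicity filtering → summary table →
    pathway-gene networks.  All intermediate artifacts are written under the
    configured output directory for auditability.
    """
    try:
        _run_all_stages(config)
    except Exception:
        logger.exception("workflow failed")
        return 1
    return 0


def _run_all_stages(config: RunConfig) -> None:
    from .io_formats import read_gmt  # local import keeps module load cheap

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.pathways_gmt is None or config.annotations is None:
        raise ConfigError("config keys 'pathways_gmt' and 'annotations' are required")
    inputs = [Path(config.pathways_gmt), Path(config.annotations)]
    inputs.extend(Path(entry["stats"]) for entry in config.conditions)
    _write_provenance(config, out, inputs)

    logger.info("stage: go-sets")
    collection = read_gmt(config.pathways_gmt)
    records, report = read_annotations(config.annotations, config.annotations_dialect)
    if report.n_dropped:
        logger.info("annotations: %s", "; ".join(report.messages))
    whitelist = EvidenceWhitelist(frozenset(config.evidence_whitelist))
    terms = focus_terms_from_config(config.focus_terms)
    go_sets = build_go_sets(records, terms, whitelist)
    write_gmt(go_sets, out / "go_sets.gmt")

    logger.info("stage: classify")
    cutoff = as_cutoff(config.cutoff)
    labels = classify_pathways(collection, go_sets, cutoff)
    labels_to_frame(labels, collection, go_sets).to_csv(
        out / "labels.tsv", sep="\t", index=False
    )
    compare_classifiers(collection, go_sets, config.sweep).to_csv(
        out / "sweep.tsv", sep="\t", index_label="term_id"
    )

    criteria = criteria_from_fold_change(
        config.fold_change,
        p_threshold=config.p_threshold,
        use_rounded=config.use_rounded_threshold,
    )
    enr_config = EnrichmentConfig(
        min_set_size=config.min_set_size,
        max_set_size=config.max_set_size,
        p_select=config.p_select,
        select_on=config.select_on,
        universe_mode=config.universe_mode,
    )
    collection_by_id = {s.set_id: s for s in collection}
    condition_results = []
    for entry in config.conditions:
        cid = entry["condition_id"]
        logger.info("stage: condition %s", cid)
        try:
            stats = read_gene_stats(entry["stats"], cid, columns=config.stats_columns)
            result = run_condition(
                stats, collection, go_sets, criteria, enr_config, cutoff, labels=labels
            )
        except Exception as err:
            raise RuntimeError(f"condition {cid!r} failed: {err}") from err
        condition_results.append(result)

        cdir = out / "conditions" / cid
        cdir.mkdir(parents=True, exist_ok=True)
        cats = categorize(stats, criteria)
        with open(cdir / "degs.txt", "w", encoding="utf-8") as fh:
            for gene in sorted(g for g, c in cats.items() if c.value == "both"):
                fh.write(gene + "\n")
        with open(cdir / "categories.tsv", "w", encoding="utf-8") as fh:
            fh.write("gene_id\tcategory\n")
            for gene, cat in cats.items():
                fh.write(f"{gene}\t{cat.value}\n")
        logger.info("condition %s volcano counts: %s", cid, dict(category_counts(cats)))
        results_to_frame(result.significant).to_csv(
            cdir / "enrichment.tsv", sep="\t", index=False
        )
        results_to_frame([r for r, _ in result.toxicity]).assign(
            terms=[",".join(sorted(lab.terms)) for _, lab in result.toxicity]
        ).to_csv(cdir / "toxicity.tsv", sep="\t", index=False)

        network = build_network(
            result.toxicity, gene_scope=config.gene_scope, collection=collection_by_id
        )
        for fmt in config.network_formats:
            if fmt == "edge_node_tsv":
                export_network(
                    network,
                    fmt,
                    edge_path=cdir / "network_edges.tsv",
                    node_path=cdir / "network_nodes.tsv",
                )
            else:
                suffix = {"graphml": "graphml", "sif": "sif"}[fmt]
                export_network(network, fmt, path=cdir / f"network.{suffix}")

    if condition_results:
        logger.info("stage: summary")
        summary = summarize(condition_results, collection, go_sets, cutoff, labels=labels)
        summary.to_csv(out / "summary.tsv", sep="\t", index_label="Condition")
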