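"""Deterministic generators for synthetic workflow inputs.

The generators emulate the statistical structure the analysis assumes:

* a pathway collection whose overlap fraction with each focus GO gene set is
  *constructed exactly* (genes are composed from inside/outside the GO set in
  the planted integer ratio), so classification tests are deterministic;
* annotation files whose whitelisted-evidence records reconstruct the GO sets
  exactly, plus noise records under non-whitelisted codes (IEA, ISS, ...)
  that the evidence filter must remove;
* per-condition gene statistics with uniform null p-values, near-zero null
  log2 fold changes, and planted differentially expressed genes concentrated
  in chosen pathways.

Every generator is a pure function of its configuration and draws from its
own pseudo-random stream, seeded from ``(config.seed, generator id, index)``,
so adding one generator never perturbs another's output.

GO gene sets are generated pairwise disjoint; planted pathways take their
in-term genes from the term's block and their remaining genes from outside
every block, so all *unplanted* pathway-term overlaps are exactly zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .go_sets import DEFAULT_FOCUS_TERMS, GeneSet
from .io_formats import AnnotationRecord, GeneStatTable, write_annotations, write_gmt
from .tox_classify import as_cutoff

_STREAM_COLLECTION = 1
_STREAM_ANNOTATIONS = 2
_STREAM_STATS = 3

#: Evidence codes deliberately outside the default whitelist.
NOISE_EVIDENCE_CODES = ("IEA", "ISS", "NAS", "ND", "RCA")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic dataset.

    ``planted_overlap`` maps ``(pathway index, GO-term index)`` to the exact
    overlap fraction that pathway must have with that term's gene set;
    unplanted pairs have overlap zero.  ``planted_pathways`` lists, per
    condition, the pathway indices whose member genes are made
    differentially expressed.

    Defaults mirror a small two-color microarray study: ~2,000 measured
    genes, 60 curated pathways of 10-40 genes, four focus GO terms, a strong
    planted effect (|log2FC| = 1, p-values scaled below 1e-4) over a 1%
    background rate of incidental differential expression, and null log2
    fold changes with standard deviation 0.1.
    """

    seed: int = 0
    n_genes: int = 2000
    n_pathways: int = 60
    pathway_size_range: tuple[int, int] = (10, 40)
    n_go_terms: int = 4
    go_term_size: int = 200
    planted_overlap: Mapping[tuple[int, int], Fraction | float | str] = field(
        default_factory=dict
    )
    n_conditions: int = 1
    condition_ids: tuple[str, ...] | None = None
    planted_pathways: tuple[frozenset[int], ...] = ()
    de_log2fc: float = 1.0
    de_pvalue_scale: float = 1e-4
    background_de_rate: float = 0.01
    null_log2fc_sd: float = 0.1
    disjoint_pathways: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.pathway_size_range
        if not 1 <= lo <= hi:
            raise ConfigError("pathway_size_range must satisfy 1 <= min <= max")
        if self.n_go_terms * self.go_term_size > self.n_genes:
            raise ConfigError("GO-term blocks exceed the gene universe")
        if self.planted_pathways and len(self.planted_pathways) != self.n_conditions:
            raise ConfigError("planted_pathways must list one entry per condition")
        if not 0 <= self.background_de_rate <= 1:
            raise ConfigError("background_de_rate must lie in [0, 1]")
        normalized = {
            (int(i), int(t)): as_cutoff(f) for (i, t), f in self.planted_overlap.items()
        }
        for (i, t), f in normalized.items():
            if not 0 <= i < self.n_pathways or not 0 <= t < self.n_go_terms:
                raise ConfigError(f"planted_overlap index out of range: {(i, t)}")
        object.__setattr__(self, "planted_overlap", normalized)
        object.__setattr__(
            self, "planted_pathways", tuple(frozenset(s) for s in self.planted_pathways)
        )
        # every planted pathway must admit a size in range realising its
        # fractions exactly
        for i in {i for i, _ in normalized}:
            fracs = [f for (j, _), f in normalized.items() if j == i]
            if sum(fracs) > 1:
                raise ConfigError(f"pathway {i}: planted fractions sum beyond 1")
            if not self._feasible_sizes(fracs):
                raise ConfigError(
                    f"pathway {i}: no size in {self.pathway_size_range} realises "
                    f"fractions {[str(f) for f in fracs]} exactly"
                )

    def _feasible_sizes(self, fracs: Sequence[Fraction]) -> list[int]:
        lcm = 1
        for f in fracs:
            lcm = lcm * f.denominator // math.gcd(lcm, f.denominator)
        lo, hi = self.pathway_size_range
        return [s for s in range(lo, hi + 1) if s % lcm == 0]

    def condition_id(self, index: int) -> str:
        if self.condition_ids is not None:
            return self.condition_ids[index]
        return f"cond{index:02d}"


@dataclass(frozen=True)
class CollectionTruth:
    """Planted pathway-term overlap fractions (zero where unplanted)."""

    fractions: Mapping[tuple[str, str], Fraction]
    pathway_ids: tuple[str, ...]
    term_ids: tuple[str, ...]

    def labels_at(self, cutoff: Fraction | float | str) -> dict[str, frozenset[str]]:
        """True label sets at a cutoff: term included iff fraction >= cutoff."""
        c = as_cutoff(cutoff)
        return {
            p: frozenset(t for t in self.term_ids if self.fractions[(p, t)] >= c)
            for p in self.pathway_ids
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                [float(self.fractions[(p, t)]) for t in self.term_ids]
                for p in self.pathway_ids
            ],
            index=list(self.pathway_ids),
            columns=list(self.term_ids),
        )


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _term_meta(config: SimConfig) -> list[tuple[str, str]]:
    if config.n_go_terms <= len(DEFAULT_FOCUS_TERMS):
        return list(DEFAULT_FOCUS_TERMS[: config.n_go_terms])
    extra = [
        (f"GO:{9000000 + i:07d}", f"synthetic process {i}")
        for i in range(config.n_go_terms - len(DEFAULT_FOCUS_TERMS))
    ]
    return list(DEFAULT_FOCUS_TERMS) + extra


def gen_collection(
    config: SimConfig,
) -> tuple[list[GeneSet], list[GeneSet], CollectionTruth]:
    """Generate pathways, GO gene sets, and the planted truth matrix.

    Each pathway's overlap fraction with each GO set equals the planted
    target exactly; unplanted overlaps are exactly zero.
    """
    rng = np.random.default_rng([config.seed, _STREAM_COLLECTION])
    genes = np.array(_gene_ids(config.n_genes))
    terms = _term_meta(config)

    blocks: list[np.ndarray] = []
    for t in range(config.n_go_terms):
        start = t * config.go_term_size
        blocks.append(genes[start : start + config.go_term_size])
    filler = genes[config.n_go_terms * config.go_term_size :]
    go_sets = [
        GeneSet(set_id=term_id, name=label, genes=frozenset(block))
        for (term_id, label), block in zip(terms, blocks)
    ]

    pathway_ids = [f"P{i:03d}" for i in range(config.n_pathways)]
    pathways: list[GeneSet] = []
    fractions: dict[tuple[str, str], Fraction] = {}
    filler_pool = filler.copy()
    lo, hi = config.pathway_size_range
    for i, pid in enumerate(pathway_ids):
        planted = {
            t: f for (j, t), f in config.planted_overlap.items() if j == i
        }
        if planted:
            sizes = config._feasible_sizes(list(planted.values()))
            size = int(rng.choice(sizes))
        else:
            size = int(rng.integers(lo, hi + 1))
        member_lists = []
        n_in_terms = 0
        for t, f in sorted(planted.items()):
            count = int(f * size)  # exact by feasibility check
            member_lists.append(rng.choice(blocks[t], size=count, replace=False))
            n_in_terms += count
        n_filler = size - n_in_terms
        if n_filler:
            if config.disjoint_pathways:
                if n_filler > len(filler_pool):
                    raise ConfigError(
                        "disjoint_pathways: filler gene pool exhausted; "
                        "reduce pathway count/sizes or enlarge n_genes"
                    )
                picked = rng.choice(len(filler_pool), size=n_filler, replace=False)
                member_lists.append(filler_pool[picked])
                filler_pool = np.delete(filler_pool, picked)
            else:
                member_lists.append(rng.choice(filler, size=n_filler, replace=False))
        members = frozenset(np.concatenate(member_lists).tolist())
        pathways.append(GeneSet(set_id=pid, name=f"synthetic pathway {i}", genes=members))
        for t, (term_id, _) in enumerate(terms):
            fractions[(pid, term_id)] = Fraction(
                int(planted.get(t, Fraction(0)) * size), size
            )
    truth = CollectionTruth(
        fractions=fractions,
        pathway_ids=tuple(pathway_ids),
        term_ids=tuple(term_id for term_id, _ in terms),
    )
    return pathways, go_sets, truth


def gen_annotations(
    go_sets: Sequence[GeneSet],
    noise_per_gene: int = 1,
    seed: int = 0,
    whitelist_codes: Sequence[str] = ("IDA", "IMP", "IGI", "TAS", "IPI", "IEP", "IBA", "IC"),
) -> list[AnnotationRecord]:
    """Annotation records whose whitelisted subset reconstructs ``go_sets`` exactly.

    Every member gene gets one record under a whitelisted evidence code; in
    addition each gene receives ``noise_per_gene`` records under
    non-whitelisted codes (random term), which the evidence filter must drop.
    """
    rng = np.random.default_rng([seed, _STREAM_ANNOTATIONS])
    term_ids = [s.set_id for s in go_sets]
    records: list[AnnotationRecord] = []
    for s in go_sets:
        for gene in sorted(s.genes):
            code = whitelist_codes[int(rng.integers(len(whitelist_codes)))]
            records.append(AnnotationRecord(gene, s.set_id, code))
            for _ in range(noise_per_gene):
                noise_code = NOISE_EVIDENCE_CODES[
                    int(rng.integers(len(NOISE_EVIDENCE_CODES)))
                ]
                noise_term = term_ids[int(rng.integers(len(term_ids)))]
                records.append(AnnotationRecord(gene, noise_term, noise_code))
    return records


def gen_condition_stats(
    config: SimConfig, condition_index: int, pathways: Sequence[GeneSet]
) -> GeneStatTable:
    """Per-gene statistics for one condition.

    Null genes draw log2FC ~ Normal(0, null_log2fc_sd) and p ~ Uniform(0,1).
    Members of the condition's planted pathways, plus a
    ``background_de_rate`` fraction of the remaining genes, get
    log2FC = ±de_log2fc and p ~ Uniform(0,1) · de_pvalue_scale.
    """
    if not 0 <= condition_index < config.n_conditions:
        raise ValueError(f"condition index {condition_index} out of range")
    rng = np.random.default_rng([config.seed, _STREAM_STATS, condition_index])
    genes = _gene_ids(config.n_genes)
    planted_genes: set[str] = set()
    if config.planted_pathways:
        for i in config.planted_pathways[condition_index]:
            planted_genes |= pathways[i].genes

    n = config.n_genes
    log2fc = rng.normal(0.0, config.null_log2fc_sd, size=n)
    pvalue = rng.uniform(0.0, 1.0, size=n)
    is_de = np.array([g in planted_genes for g in genes])
    background = (~is_de) & (rng.uniform(size=n) < config.background_de_rate)
    de = is_de | background
    signs = rng.choice([-1.0, 1.0], size=n)
    log2fc[de] = signs[de] * config.de_log2fc
    pvalue[de] = rng.uniform(size=int(de.sum())) * config.de_pvalue_scale

    frame = pd.DataFrame({"gene_id": genes, "log2fc": log2fc, "pvalue": pvalue})
    return GeneStatTable(condition_id=config.condition_id(condition_index), frame=frame)


def toy_config(seed: int = 20210830) -> SimConfig:
    """The "toy-tox" dataset: 3 cell models × 2 doses, 60 pathways, 4 focus terms.

    Twelve pathways carry planted overlap fractions spanning the swept
    cutoffs (2/5, 1/2, 3/5, 7/10, 4/5), including one multi-label pathway
    and two below-cutoff distractors; each condition plants differential
    expression in an escalating, dose-dependent subset of the labeled
    pathways.
    """
    planted_overlap = {
        (0, 0): Fraction(1, 2),
        (1, 0): Fraction(3, 5),
        (2, 0): Fraction(7, 10),
        (3, 0): Fraction(4, 5),
        (4, 1): Fraction(1, 2),
        (5, 1): Fraction(2, 5),  # below the 50% cutoff: distractor
        (6, 2): Fraction(1, 2),
        (7, 2): Fraction(4, 5),
        (8, 3): Fraction(1, 2),
        (9, 0): Fraction(1, 2),
        (9, 1): Fraction(1, 2),  # multi-label pathway
        (10, 0): Fraction(2, 5),  # distractor
        (11, 3): Fraction(3, 5),
    }
    return SimConfig(
        seed=seed,
        n_genes=2000,
        n_pathways=60,
        pathway_size_range=(10, 40),
        n_go_terms=4,
        go_term_size=200,
        planted_overlap=planted_overlap,
        n_conditions=6,
        condition_ids=(
            "THP1_low",
            "THP1_high",
            "SAE_low",
            "SAE_high",
            "Caco2_low",
            "Caco2_high",
        ),
        planted_pathways=(
            frozenset({0}),
            frozenset({0, 1, 6, 9}),
            frozenset({4}),
            frozenset({4, 7, 8}),
            frozenset({2}),
            frozenset({2, 3, 11}),
        ),
    )


def write_dataset(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Materialise a synthetic dataset as files (GMT, TSV, truth JSON).

    Returns the paths written, keyed by artifact name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pathways, go_sets, truth = gen_collection(config)
    paths: dict[str, Path] = {}
    paths["pathways"] = out / "pathways.gmt"
    write_gmt(pathways, paths["pathways"])
    paths["go_sets"] = out / "go_sets.gmt"
    write_gmt(go_sets, paths["go_sets"])
    paths["annotations"] = out / "annotations.tsv"
    write_annotations(
        gen_annotations(go_sets, seed=config.seed), paths["annotations"]
    )
    for index in range(config.n_conditions):
        table = gen_condition_stats(config, index, pathways)
        path = out / f"stats_{table.condition_id}.tsv"
        table.frame.rename(columns={"gene_id": "gene"}).to_csv(
            path, sep="\t", index=False
        )
        paths[f"stats_{table.condition_id}"] = path
    paths["truth"] = out / "truth.json"
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "fractions": {
                    f"{p}|{t}": str(f) for (p, t), f in truth.fractions.items()
                },
                "pathway_ids": list(truth.pathway_ids),
                "term_ids": list(truth.term_ids),
                "planted_pathways": [sorted(s) for s in config.planted_pathways],
            },
            fh,
            indent=2,
        )
    return paths
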