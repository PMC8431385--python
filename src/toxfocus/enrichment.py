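"""In-house overrepresentation analysis (ORA).

Each gene set in a collection is tested for overrepresentation of a query
gene list with the exact hypergeometric upper-tail probability

    P(X >= k),  X ~ Hypergeometric(N, K, n)

where N is the background universe size, K the in-universe query size, n the
in-universe gene-set size and k the overlap.  Benjamini-Hochberg q-values
are computed across exactly the sets that were tested.

Universe handling follows common ORA-tool practice: by default the universe
is the intersection of the collection's genes with the measured genes (genes
neither annotated nor measured carry no information); without a measured
list this reduces to the union of collection genes.  Set-size filters
(default 10..300) are applied to in-universe sizes before testing; selection
of "significant" results uses the raw p-value by default (q-values are still
always reported).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .go_sets import GeneSet


@dataclass(frozen=True)
class EnrichmentConfig:
    """Knobs of the overrepresentation analysis.

    min_set_size / max_set_size
        Inclusive bounds on tested gene-set size (defaults 10 and 300).
    p_select
        Threshold used by :func:`select_significant` (default 0.05, strict).
    select_on
        ``"raw_p"`` (default) or ``"bh_q"``.
    universe_mode
        ``"collection"`` (union of collection genes), ``"measured"`` (the
        supplied measured set), or ``"intersection"`` (their intersection;
        default — equals ``collection`` when no measured set is given).
    size_filter_on
        ``"universe"`` (default): size bounds apply to in-universe set sizes;
        ``"raw"``: to sizes as parsed from the collection.
    """

    min_set_size: int = 10
    max_set_size: int = 300
    p_select: float = 0.05
    select_on: str = "raw_p"
    universe_mode: str = "intersection"
    size_filter_on: str = "universe"

    def __post_init__(self) -> None:
        if not 1 <= self.min_set_size <= self.max_set_size:
            raise ValueError("need 1 <= min_set_size <= max_set_size")
        if not 0 < self.p_select <= 1:
            raise ValueError("p_select must lie in (0, 1]")
        if self.select_on not in ("raw_p", "bh_q"):
            raise ValueError(f"unknown select_on: {self.select_on!r}")
        if self.universe_mode not in ("collection", "measured", "intersection"):
            raise ValueError(f"unknown universe_mode: {self.universe_mode!r}")
        if self.size_filter_on not in ("universe", "raw"):
            raise ValueError(f"unknown size_filter_on: {self.size_filter_on!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric test outcome for one gene set against one query list.

    All counts are taken within the background universe: ``k`` query genes in
    the set, set size ``n``, query size ``K``, universe size ``N``.
    """

    set_id: str
    name: str
    k: int
    n: int
    K: int
    N: int
    pvalue: float
    qvalue: float
    hit_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K) and self.n <= self.N and self.K <= self.N):
            raise ValueError(
                f"inconsistent counts for {self.set_id}: "
                f"k={self.k}, n={self.n}, K={self.K}, N={self.N}"
            )
        if len(self.hit_genes) != self.k:
            raise ValueError(f"{self.set_id}: |hit_genes| != k")


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n).

    Parameters use the sampling-without-replacement picture: a universe of
    ``N`` genes contains ``K`` query genes; a set of ``n`` genes drawn from
    the universe overlaps the query in ``X`` genes.  ``k = 0`` returns 1.
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    if min(k, K, n, N) < 0 or k > min(n, K) or n > N or K > N:
        raise ValueError(f"inconsistent hypergeometric counts: k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order, clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _build_universe(
    collection: Sequence[GeneSet],
    measured: set[str] | None,
    mode: str,
) -> set[str]:
    collection_genes: set[str] = set()
    for s in collection:
        collection_genes |= s.genes
    if mode == "collection":
        return collection_genes
    if mode == "measured":
        if measured is None:
            raise ValueError("universe_mode='measured' requires a measured gene set")
        return set(measured)
    # intersection; falls back to the collection when nothing was measured
    if measured is None:
        return collection_genes
    return collection_genes & set(measured)


def enrich(
    query: Iterable[str],
    collection: Sequence[GeneSet],
    measured: Iterable[str] | None = None,
    config: EnrichmentConfig | None = None,
) -> list[EnrichmentResult]:
    """Test every retained gene set for overrepresentation of ``query``.

    Results are sorted by ascending p-value with set id as the deterministic
    tie-break; q-values are BH-adjusted across exactly the retained sets.

    Raises ``ValueError`` (with diagnostic counts) if the universe or the
    in-universe query is empty.
    """
    cfg = config if config is not None else EnrichmentConfig()
    query = set(query)
    measured_set = set(measured) if measured is not None else None
    universe = _build_universe(collection, measured_set, cfg.universe_mode)
    if not universe:
        raise ValueError(
            f"empty universe (mode={cfg.universe_mode}, collection sets={len(collection)}, "
            f"measured={'none' if measured_set is None else len(measured_set)})"
        )
    query_u = query & universe
    if not query_u:
        raise ValueError(
            f"query empty within universe (query={len(query)}, universe={len(universe)})"
        )
    N, K = len(universe), len(query_u)

    rows: list[tuple[GeneSet, frozenset[str], frozenset[str]]] = []
    for s in collection:
        genes_u = frozenset(s.genes & universe)
        size = len(s.genes) if cfg.size_filter_on == "raw" else len(genes_u)
        if not cfg.min_set_size <= size <= cfg.max_set_size:
            continue
        rows.append((s, genes_u, frozenset(genes_u & query_u)))

    pvals = [hypergeom_upper_tail(len(hits), K, len(genes_u), N) for _, genes_u, hits in rows]
    qvals = bh_adjust(pvals)
    results = [
        EnrichmentResult(
            set_id=s.set_id,
            name=s.name,
            k=len(hits),
            n=len(genes_u),
            K=K,
            N=N,
            pvalue=p,
            qvalue=float(q),
            hit_genes=hits,
        )
        for (s, genes_u, hits), p, q in zip(rows, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.pvalue, r.set_id))
    return results


def select_significant(
    results: Sequence[EnrichmentResult], config: EnrichmentConfig | None = None
) -> list[EnrichmentResult]:
    """Subset with p (or BH q) strictly below the selection threshold; order kept."""
    cfg = config if config is not None else EnrichmentConfig()
    if cfg.select_on == "raw_p":
        return [r for r in results if r.pvalue < cfg.p_select]
    return [r for r in results if r.qvalue < cfg.p_select]


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate results; hit genes are comma-joined and sorted."""
    return pd.DataFrame(
        {
            "set_id": [r.set_id for r in results],
            "name": [r.name for r in results],
            "k": [r.k for r in results],
            "n": [r.n for r in results],
            "K": [r.K for r in results],
            "N": [r.N for r in results],
            "pvalue": [r.pvalue for r in results],
            "qvalue": [r.qvalue for r in results],
            "hit_genes": [",".join(sorted(r.hit_genes)) for r in results],
        }
    )
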