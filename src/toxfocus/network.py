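"""Pathway-gene bipartite networks for the altered toxicity-related pathways.

Each network has one node per toxicity-labeled, significantly overrepresented
pathway (carrying its focus GO terms as attributes) and one node per gene,
with an edge from a pathway to each of its genes.  A gene shared by several
pathways has degree >= 2, which is exactly the overlap/crosstalk structure
the networks are meant to expose.

By default the gene side holds each pathway's *hit* genes — the
differentially expressed genes that drove its enrichment — since the
networks depict altered pathways; ``gene_scope="all_pathway_genes"`` uses
full pathway membership instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from .enrichment import EnrichmentResult
from .go_sets import GeneSet
from .io_formats import write_edge_node_files
from .tox_classify import ToxicityLabel


@dataclass(frozen=True)
class Node:
    id: str
    kind: str  # "pathway" | "gene"
    label: str
    terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in ("pathway", "gene"):
            raise ValueError(f"unknown node kind: {self.kind!r}")
        if self.kind == "gene" and self.terms:
            raise ValueError(f"gene node {self.id!r} must not carry GO terms")


@dataclass(frozen=True)
class BipartiteNetwork:
    """Typed pathway/gene nodes plus pathway→gene edges, stored sorted.

    Invariants (checked at construction): every edge references existing
    nodes with the right kinds, edges are unique, and no pathway node is
    isolated.
    """

    nodes: tuple[Node, ...]
    edges: tuple[tuple[str, str], ...]

    @classmethod
    def from_parts(
        cls, nodes: Sequence[Node], edges: Sequence[tuple[str, str]]
    ) -> "BipartiteNetwork":
        nodes = tuple(sorted(set(nodes), key=lambda n: (n.kind, n.id)))
        edges = tuple(sorted(set(map(tuple, edges))))
        kinds = {n.id: n.kind for n in nodes}
        if len(kinds) != len(nodes):
            raise ValueError("duplicate node ids with conflicting attributes")
        for source, target in edges:
            if kinds.get(source) != "pathway" or kinds.get(target) != "gene":
                raise ValueError(f"edge ({source}, {target}) must run pathway -> gene")
        linked = {s for s, _ in edges}
        isolated = [n.id for n in nodes if n.kind == "pathway" and n.id not in linked]
        if isolated:
            raise ValueError(f"isolated pathway nodes: {isolated}")
        return cls(nodes=nodes, edges=edges)

    @property
    def pathway_nodes(self) -> tuple[Node, ...]:
        return tuple(n for n in self.nodes if n.kind == "pathway")

    @property
    def gene_nodes(self) -> tuple[Node, ...]:
        return tuple(n for n in self.nodes if n.kind == "gene")

    def degree(self, node_id: str) -> int:
        return sum(1 for s, t in self.edges if node_id in (s, t))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n.id, kind=n.kind, label=n.label, terms=",".join(sorted(n.terms)))
        g.add_edges_from(self.edges)
        return g


def build_network(
    toxicity: Sequence[tuple[EnrichmentResult, ToxicityLabel]],
    gene_scope: str = "hits",
    collection: Mapping[str, GeneSet] | None = None,
) -> BipartiteNetwork:
    """Assemble the bipartite network of altered toxicity-related pathways.

    Parameters
    ----------
    toxicity
        Significant, toxicity-labeled pathways with their enrichment results.
    gene_scope
        ``"hits"`` (default): connect each pathway to its enrichment hit
        genes; ``"all_pathway_genes"``: to its full membership (requires
        ``collection``, a mapping pathway id → :class:`GeneSet`).

    A pathway whose chosen gene set is empty is omitted (pathway nodes are
    never isolated); an empty input yields an empty network.
    """
    if gene_scope not in ("hits", "all_pathway_genes"):
        raise ValueError(f"unknown gene_scope: {gene_scope!r}")
    if gene_scope == "all_pathway_genes" and collection is None:
        raise ValueError("gene_scope='all_pathway_genes' requires the pathway collection")
    nodes: list[Node] = []
    edges: list[tuple[str, str]] = []
    genes_seen: set[str] = set()
    for result, label in toxicity:
        if gene_scope == "hits":
            genes = result.hit_genes
        else:
            genes = collection[result.set_id].genes  # type: ignore[index]
        if not genes:
            continue
        nodes.append(
            Node(id=result.set_id, kind="pathway", label=result.name, terms=label.terms)
        )
        for gene in genes:
            edges.append((result.set_id, gene))
            genes_seen.add(gene)
    nodes.extend(Node(id=g, kind="gene", label=g) for g in genes_seen)
    return BipartiteNetwork.from_parts(nodes, edges)


def export_network(
    network: BipartiteNetwork,
    format: str,
    path: str | Path | None = None,
    edge_path: str | Path | None = None,
    node_path: str | Path | None = None,
) -> None:
    """Write a network as paired edge/node TSVs, GraphML, or SIF.

    ``edge_node_tsv`` needs ``edge_path`` and ``node_path``; the other
    formats write to ``path``.  Output ordering is deterministic (nodes and
    edges sorted by id).  SIF uses the interaction token ``contains`` with
    one edge per line.
    """
    if format == "edge_node_tsv":
        if edge_path is None or node_path is None:
            raise ValueError("edge_node_tsv export needs edge_path and node_path")
        write_edge_node_files(network, edge_path, node_path)
    elif format == "graphml":
        if path is None:
            raise ValueError("graphml export needs path")
        nx.write_graphml(network.to_networkx(), path)
    elif format == "sif":
        if path is None:
            raise ValueError("sif export needs path")
        with open(path, "w", encoding="utf-8") as fh:
            for source, target in network.edges:
                fh.write(f"{source}\tcontains\t{target}\n")
    else:
        raise ValueError(f"unknown network export format: {format!r}")
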