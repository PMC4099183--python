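"""Interactome-map construction, simplification and export.

A gene is a node; a directed edge runs from a source (predictor) gene to
a target (predicted) gene, signed stimulatory or inhibitory by the sign
of its interaction score. Because a complete G x G matrix is unreadable
as a map, the published simplification keeps, for each target gene, only
the single strongest incoming association — reducing a 96-gene panel to
exactly 96 edges. Maps export to Cytoscape-readable SIF, GraphML and a
TSV edge list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import networkx as nx
from statsmodels.stats.multitest import multipletests

from .inference import InteractionScoreMatrix

__all__ = [
    "InteractionEdge",
    "NetworkMap",
    "strongest_edge_per_gene",
    "hubs",
    "truncated_p_values",
    "export_network",
    "read_edge_tsv",
]

STIMULATORY = "stimulatory"
INHIBITORY = "inhibitory"


@dataclass(frozen=True)
class InteractionEdge:
    """One directed, signed gene-gene association.

    ``sign`` is derived from the score: non-negative scores are
    stimulatory, negative scores inhibitory.
    """

    source: str
    target: str
    score: float
    sign: str = ""
    expression_r: float = float("nan")

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("self-edges are not allowed")
        expected = INHIBITORY if self.score < 0 else STIMULATORY
        if not self.sign:
            object.__setattr__(self, "sign", expected)
        elif self.sign != expected:
            raise ValueError(f"sign {self.sign!r} contradicts score {self.score!r}")


@dataclass
class NetworkMap:
    """A set of genes plus the directed edges linking them."""

    nodes: List[str]
    edges: List[InteractionEdge]
    node_annotations: Optional[Dict[str, str]] = None
    missing_targets: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for e in self.edges:
            if e.source not in node_set or e.target not in node_set:
                raise ValueError(f"edge {e.source}->{e.target} references unknown node")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        if self.node_annotations:
            nx.set_node_attributes(g, self.node_annotations, name="category")
        for e in self.edges:
            g.add_edge(
                e.source, e.target,
                score=float(e.score), sign=e.sign,
                expression_r=float(e.expression_r),
            )
        return g


def strongest_edge_per_gene(s: InteractionScoreMatrix) -> NetworkMap:
    """Keep only each target gene's strongest incoming association.

    For every gene, among the unmasked entries of its column the source
    with maximal absolute score wins (ties broken by lexicographic
    source key), yielding exactly G edges on a fully populated matrix.
    Targets whose incoming entries are all masked contribute no edge and
    are listed in ``missing_targets``.
    """
    genes = s.gene_ids
    if len(genes) < 2:
        raise ValueError("simplification requires at least 2 genes")
    edges: List[InteractionEdge] = []
    missing: List[str] = []
    for target in genes:
        col = s.scores[target].drop(labels=[target]).dropna()
        if col.empty:
            missing.append(target)
            continue
        col = col.sort_index()  # lexicographic tie-break
        source = col.abs().idxmax()
        score = float(col[source])
        expr = (
            float(s.expression_r.loc[source, target])
            if s.expression_r is not None else float("nan")
        )
        edges.append(InteractionEdge(source, target, score, expression_r=expr))
    return NetworkMap(nodes=list(genes), edges=edges, missing_targets=missing)


def hubs(n: NetworkMap, min_degree: int = 1) -> List[Tuple[str, int]]:
    """Genes ranked by total degree (in + out) in the map.

    Returns ``(gene, degree)`` pairs with degree at least ``min_degree``,
    ordered by degree descending then gene key.
    """
    deg: Dict[str, int] = {}
    for e in n.edges:
        deg[e.source] = deg.get(e.source, 0) + 1
        deg[e.target] = deg.get(e.target, 0) + 1
    ranked = [(g, d) for g, d in deg.items() if d >= min_degree]
    ranked.sort(key=lambda gd: (-gd[1], gd[0]))
    return ranked


def truncated_p_values(
    p: Sequence[float], rank: Sequence[int]
) -> np.ndarray:
    """Rank-weighted p-values with Benjamini-Hochberg adjustment.

    Each p-value is multiplied by its selection rank (capped at 1), and
    the products are then adjusted with the Benjamini-Hochberg step-up
    procedure. Useful for penalising genes selected late in a ranked
    screen.
    """
    p = np.asarray(p, dtype=float)
    rank = np.asarray(rank)
    if p.shape != rank.shape:
        raise ValueError("p and rank must have equal length")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (rank < 1).any():
        raise ValueError("ranks must be positive integers")
    products = np.minimum(p * rank, 1.0)
    adjusted = multipletests(products, method="fdr_bh")[1]
    return np.minimum(adjusted, 1.0)


_EDGE_COLUMNS = ["source", "target", "score", "sign", "expression_r"]


def export_network(n: NetworkMap, format: str, path) -> None:
    """Write a map as ``sif``, ``edge_tsv`` or ``graphml``.

    SIF lines read ``source stimulates target`` / ``source inhibits
    target``; the TSV and GraphML forms carry score, sign and expression
    correlation as edge attributes. All three load in Cytoscape.
    """
    path = Path(path)
    if format == "sif":
        verbs = {STIMULATORY: "stimulates", INHIBITORY: "inhibits"}
        lines = [f"{e.source}\t{verbs[e.sign]}\t{e.target}" for e in n.edges]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif format == "edge_tsv":
        with path.open("w") as fh:
            fh.write("\t".join(_EDGE_COLUMNS) + "\n")
            for e in n.edges:
                fh.write(
                    f"{e.source}\t{e.target}\t{e.score!r}\t{e.sign}\t{e.expression_r!r}\n"
                )
    elif format == "graphml":
        nx.write_graphml(n.to_digraph(), path)
    else:
        raise ValueError(f"unknown export format {format!r}")


def read_edge_tsv(path, nodes: Optional[Sequence[str]] = None) -> NetworkMap:
    """Read back an ``edge_tsv`` export into an identical NetworkMap."""
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    if list(df.columns) != _EDGE_COLUMNS:
        raise ValueError(f"{path}: not an edge TSV (columns {list(df.columns)})")
    edges = [
        InteractionEdge(
            row.source, row.target, float(row.score),
            sign=row.sign, expression_r=float(row.expression_r),
        )
        for row in df.itertuples()
    ]
    if nodes is None:
        seen: Dict[str, None] = {}
        for e in edges:
            seen.setdefault(e.source)
            seen.setdefault(e.target)
        nodes = list(seen)
    return NetworkMap(nodes=list(nodes), edges=edges)
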