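"""Gene-gene expression correlation networks over voxels, expandable.

Edges carry the Pearson correlation of two genes' expression profiles over
all voxels in the grid.  A network starts from a seed gene's top-m
correlates and grows by adding any member node's top correlates — the
interactive expand gesture, as a pure function.  Ranking is by signed r
descending by default (``absolute=True`` ranks by |r|).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Set, Tuple

import numpy as np

from .voxel import ExpressionGrid


class ConstantGeneError(ValueError):
    """Correlation is undefined for a gene constant across voxels."""


@dataclass(frozen=True)
class CorrelationEdge:
    gene_a: str
    gene_b: str
    r: float
    n_voxels: int

    def __post_init__(self):
        if self.gene_a >= self.gene_b:
            raise ValueError("edge endpoints must satisfy gene_a < gene_b")
        if not -1.0 <= self.r <= 1.0:
            raise ValueError(f"r={self.r} outside [-1, 1]")
        if self.n_voxels < 3:
            raise ValueError("correlation needs >= 3 voxels")


@dataclass
class GeneNetwork:
    nodes: Set[str] = field(default_factory=set)
    edges: Dict[Tuple[str, str], CorrelationEdge] = field(default_factory=dict)
    seed_genes: List[str] = field(default_factory=list)

    def copy(self) -> "GeneNetwork":
        return GeneNetwork(set(self.nodes), dict(self.edges), list(self.seed_genes))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for (a, b), e in sorted(self.edges.items(), key=lambda kv: kv[0]):
            g.add_edge(a, b, r=e.r, n_voxels=e.n_voxels)
        return g


def _edge(a: str, b: str, r: float, n: int) -> CorrelationEdge:
    lo, hi = (a, b) if a < b else (b, a)
    return CorrelationEdge(lo, hi, float(np.clip(r, -1.0, 1.0)), n)


def pairwise_correlation(
    grid: ExpressionGrid, gene_a: str, gene_b: str
) -> CorrelationEdge:
    """Pearson r of two genes' profiles over all voxels in the grid."""
    if gene_a == gene_b:
        raise ValueError("self-correlation is not an edge")
    x, y = grid.gene_row(gene_a), grid.gene_row(gene_b)
    n = x.size
    if n < 3:
        raise ValueError("correlation needs >= 3 voxels")
    for g, v in ((gene_a, x), (gene_b, y)):
        if np.ptp(v) == 0:
            raise ConstantGeneError(f"gene {g!r} is constant across voxels")
    r = np.corrcoef(x, y)[0, 1]
    return _edge(gene_a, gene_b, r, n)


def top_correlates(
    grid: ExpressionGrid, gene: str, m: int, absolute: bool = False
) -> List[CorrelationEdge]:
    """The m partners with the largest correlation to *gene*, descending,
    ties broken by partner id.  Constant genes are skipped silently; a
    constant query gene is an error."""
    if m < 1:
        raise ValueError("m must be >= 1")
    x = grid.gene_row(gene)
    if np.ptp(x) == 0:
        raise ConstantGeneError(f"gene {gene!r} is constant across voxels")
    n = x.size
    vals = grid.values
    xc = x - x.mean()
    vc = vals - vals.mean(axis=1, keepdims=True)
    denom = np.sqrt((vc**2).sum(axis=1)) * np.sqrt((xc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rs = (vc @ xc) / denom
    ranked = []
    for g, r in zip(grid.genes, rs):
        if g == gene or not np.isfinite(r):
            continue
        key = abs(r) if absolute else r
        ranked.append((-key, g, float(r)))
    ranked.sort()
    return [_edge(gene, g, r, n) for _, g, r in ranked[:m]]


def build_network(grid: ExpressionGrid, seed_gene: str, m: int) -> GeneNetwork:
    """Seed network: the seed gene plus its top-m correlates."""
    net = GeneNetwork(nodes={seed_gene}, seed_genes=[seed_gene])
    return expand(net, grid, seed_gene, m)


def expand(
    net: GeneNetwork, grid: ExpressionGrid, gene: str, m: int
) -> GeneNetwork:
    """Union the network with *gene*'s top-m correlates.  Pure and
    idempotent: repeating with identical arguments returns an equal network."""
    if gene not in net.nodes:
        raise ValueError(f"gene {gene!r} is not a node of the network")
    out = net.copy()
    for e in top_correlates(grid, gene, m):
        out.nodes.update((e.gene_a, e.gene_b))
        out.edges[(e.gene_a, e.gene_b)] = e
    return out
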