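"""Structure-specific expression scoring on a voxel grid.

A gene's enrichment in an anatomical structure is the ratio of its mean
expression over the structure's voxels to its mean over all voxels in the
grid ("whole brain"), including unassigned and zero-expression voxels.
Genes whose whole-brain mean does not exceed ``epsilon`` have an undefined
fold and are excluded from rankings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np


@dataclass
class ExpressionGrid:
    """Genes x voxels expression matrix with ordered id lists.

    ``coords`` carries integer (x, y, z) voxel coordinates; scoring never
    uses them, but fixtures and spatial methods downstream do.
    """

    genes: List[str]
    voxel_ids: List[str]
    values: np.ndarray
    coords: Optional[Dict[str, Tuple[int, int, int]]] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.voxel_ids)):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.genes)}, {len(self.voxel_ids)})"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids")
        if len(set(self.voxel_ids)) != len(self.voxel_ids):
            raise ValueError("duplicate voxel ids")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("expression values must be finite and non-negative")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._voxel_index = {v: j for j, v in enumerate(self.voxel_ids)}

    def gene_row(self, gene_id: str) -> np.ndarray:
        try:
            return self.values[self._gene_index[gene_id]]
        except KeyError:
            raise KeyError(f"unknown gene {gene_id!r}") from None

    def voxel_columns(self, voxel_ids: Sequence[str]) -> np.ndarray:
        return np.array([self._voxel_index[v] for v in voxel_ids])


@dataclass
class StructureMap:
    """Flat voxel -> structure labels (no hierarchy rollup)."""

    assignment: Dict[str, str]

    @property
    def structures(self) -> Set[str]:
        return set(self.assignment.values())

    def voxels_of(self, structure_id: str) -> List[str]:
        vs = [v for v, s in self.assignment.items() if s == structure_id]
        if not vs:
            raise KeyError(f"unknown structure {structure_id!r}")
        return vs

    def validate_against(self, grid: ExpressionGrid) -> None:
        missing = set(self.assignment) - set(grid.voxel_ids)
        if missing:
            raise ValueError(f"assigned voxels absent from grid: {sorted(missing)[:5]}")


@dataclass(frozen=True)
class StructureScore:
    gene_id: str
    structure_id: str
    structure_mean: float
    brain_mean: float
    fold: Optional[float]  # None when brain_mean <= epsilon (undefined)


def structure_fold(
    grid: ExpressionGrid,
    smap: StructureMap,
    gene_id: str,
    structure_id: str,
    epsilon: float = 0.0,
) -> StructureScore:
    """Ratio of the gene's mean over the structure's voxels to its mean over
    all voxels in the grid."""
    row = grid.gene_row(gene_id)
    cols = grid.voxel_columns(smap.voxels_of(structure_id))
    s_mean = float(row[cols].mean())
    b_mean = float(row.mean())
    fold = s_mean / b_mean if b_mean > epsilon else None
    return StructureScore(gene_id, structure_id, s_mean, b_mean, fold)


def top_genes(
    grid: ExpressionGrid,
    smap: StructureMap,
    structure_id: str,
    k: int = 20,
    epsilon: float = 0.0,
) -> List[StructureScore]:
    """The k genes most enriched in a structure, fold descending, ties by
    gene id; genes with undefined fold are excluded."""
    if k < 1:
        raise ValueError("k must be >= 1")
    cols = grid.voxel_columns(smap.voxels_of(structure_id))
    s_means = grid.values[:, cols].mean(axis=1)
    b_means = grid.values.mean(axis=1)
    scores = [
        StructureScore(g, structure_id, float(sm), float(bm), float(sm / bm))
        for g, sm, bm in zip(grid.genes, s_means, b_means)
        if bm > epsilon
    ]
    scores.sort(key=lambda s: (-s.fold, s.gene_id))
    return scores[:k]


def mean_top_fold(scores: Sequence[StructureScore]) -> float:
    """Arithmetic mean fold of a score list (e.g. a structure's top 20)."""
    if not scores:
        raise ValueError("empty score list")
    folds = [s.fold for s in scores]
    if any(f is None for f in folds):
        raise ValueError("undefined folds in score list")
    return float(np.mean(folds))
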