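"""Cell Type Relevance (CTR) scores and micro-cluster median ranks.

The CTR matrix is the plain product of the normalized cell-by-feature
matrix (restricted to the signature markers, in signature order) with the
signature weight matrix: a cell's score for a type is the weighted sum of
its signature-marker values, so higher scores mean stronger congruence
with the type's expected profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrices import CellFeatureMatrix, SignatureMatrix
from .microcluster import MicroClustering

__all__ = ["CTRMatrix", "RankedMedians", "compute_ctr", "rank_cluster_medians"]


@dataclass
class CTRMatrix:
    """Cell x cell-type relevance scores."""

    scores: np.ndarray
    cell_ids: list = field(default_factory=list)
    cell_type_names: list = field(default_factory=list)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.cell_ids), len(self.cell_type_names)):
            raise ValueError("score dimensions do not match id/name lists")

    def column(self, cell_type: str) -> np.ndarray:
        try:
            j = self.cell_type_names.index(cell_type)
        except ValueError:
            raise KeyError(f"unknown cell type {cell_type!r}") from None
        return self.scores[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores,
                            index=pd.Index(self.cell_ids, name="cell_id"),
                            columns=self.cell_type_names)


@dataclass
class RankedMedians:
    """Per micro-cluster median CTRs (z) and their ascending ranks (r).

    Ranks are a permutation of 1..k; ties are broken by micro-cluster
    index, which keeps the ordering deterministic.
    """

    z: np.ndarray
    r: np.ndarray
    cell_type: str

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.r = np.asarray(self.r, dtype=int)
        k = self.z.size
        if self.r.size != k or sorted(self.r.tolist()) != list(range(1, k + 1)):
            raise ValueError("r must be a permutation of 1..k")


def compute_ctr(mat: CellFeatureMatrix, sig: SignatureMatrix) -> CTRMatrix:
    """Score every cell against every cell-type signature (Gamma = A_sub @ S)."""
    if not mat.normalized:
        raise ValueError("cell-feature matrix must be normalized before scoring")
    cols = mat.marker_index(sig.marker_names)
    scores = mat.values[:, cols] @ sig.weights
    return CTRMatrix(scores=scores, cell_ids=list(mat.cell_ids),
                     cell_type_names=list(sig.cell_type_names))


def rank_cluster_medians(ctr: CTRMatrix, mc: MicroClustering,
                         cell_type: str) -> RankedMedians:
    """Median CTR of each micro-cluster and its rank (1 = lowest median)."""
    col = ctr.column(cell_type)
    if mc.assignment.size != col.size:
        raise ValueError("micro-clustering does not cover the CTR matrix cells")
    z = np.array([np.median(col[mc.assignment == j]) for j in range(1, mc.k + 1)])
    order = np.argsort(z, kind="stable")  # ties keep cluster-index order
    r = np.empty(mc.k, dtype=int)
    r[order] = np.arange(1, mc.k + 1)
    return RankedMedians(z=z, r=r, cell_type=cell_type)
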