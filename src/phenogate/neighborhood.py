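"""Cell-cell interaction graphs from Delaunay triangulation.

Cells with coordinates and a known label are triangulated; edges longer
than a per-tissue distance percentile (default 97th) are treated as
improbable contacts and dropped.  The interaction matrix counts surviving
edges per unordered cell-type pair ("Unknown" cells are excluded before
triangulation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

__all__ = ["InteractionResult", "build_interactions", "interactions_per_sample"]

UNKNOWN = "Unknown"


@dataclass
class InteractionResult:
    """Filtered Delaunay edge list plus the type-pair edge-count matrix."""

    edges: pd.DataFrame            # cell_i, cell_j, length, type_i, type_j
    matrix: pd.DataFrame           # symmetric type x type edge counts
    percentile_cutoff: float
    cutoff_length: float
    n_edges_pre_filter: int


def _delaunay_edges(coords: np.ndarray) -> np.ndarray:
    tri = Delaunay(coords)
    pairs = set()
    for simplex in tri.simplices:
        s = sorted(int(v) for v in simplex)
        pairs.update({(s[0], s[1]), (s[0], s[2]), (s[1], s[2])})
    return np.array(sorted(pairs), dtype=int)


def build_interactions(coords, labels, cell_ids=None,
                       percentile: float = 97.0) -> InteractionResult:
    """Triangulate labeled cells, drop over-long edges, count type pairs.

    Edges with length exactly at the percentile cutoff are kept.  A cell
    labeled "Unknown" never enters the triangulation.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) array")
    if labels.size != coords.shape[0]:
        raise ValueError("one label per coordinate row required")
    if cell_ids is None:
        cell_ids = np.arange(coords.shape[0]).astype(str)
    cell_ids = np.asarray(cell_ids, dtype=object)
    keep = labels != UNKNOWN
    coords, labels, cell_ids = coords[keep], labels[keep], cell_ids[keep]
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 labeled cells with coordinates")
    try:
        edges = _delaunay_edges(coords)
    except QhullError as exc:
        raise ValueError(f"degenerate geometry (collinear points?): {exc}") from None
    lengths = np.linalg.norm(coords[edges[:, 0]] - coords[edges[:, 1]], axis=1)
    cutoff = float(np.percentile(lengths, percentile))
    mask = lengths <= cutoff
    edges, lengths = edges[mask], lengths[mask]
    types = sorted(set(labels.tolist()))
    index = {t: i for i, t in enumerate(types)}
    mat = np.zeros((len(types), len(types)), dtype=int)
    for (a, b) in edges:
        i, j = index[labels[a]], index[labels[b]]
        mat[i, j] += 1
        if i != j:
            mat[j, i] += 1
    edge_df = pd.DataFrame({
        "cell_i": cell_ids[edges[:, 0]],
        "cell_j": cell_ids[edges[:, 1]],
        "length": lengths,
        "type_i": labels[edges[:, 0]],
        "type_j": labels[edges[:, 1]],
    })
    matrix = pd.DataFrame(mat, index=types, columns=types)
    return InteractionResult(edges=edge_df, matrix=matrix,
                             percentile_cutoff=percentile,
                             cutoff_length=cutoff,
                             n_edges_pre_filter=int(mask.size))


def interactions_per_sample(coords, labels, sample_ids, cell_ids=None,
                            percentile: float = 97.0
                            ) -> Dict[str, InteractionResult]:
    """Per-tissue interaction analysis: the distance percentile is computed
    within each sample's own edge-length distribution."""
    sample_ids = np.asarray(sample_ids, dtype=object)
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if cell_ids is None:
        cell_ids = np.arange(coords.shape[0]).astype(str)
    cell_ids = np.asarray(cell_ids, dtype=object)
    out = {}
    for s in pd.unique(sample_ids):
        m = sample_ids == s
        out[str(s)] = build_interactions(coords[m], labels[m],
                                         cell_ids=cell_ids[m],
                                         percentile=percentile)
    return out
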