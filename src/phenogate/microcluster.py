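"""Micro-clustering: fine-grained graph communities of cells.

Cells are partitioned into many small, highly homogeneous "micro-clusters"
whose mean size is driven into a target band (default 0.1%-0.5% of cells).
Micro-clusters approximate the within-population spread of marker values:
the per-cluster median relevance scores are what the downstream segmented
regression operates on.

Pipeline: PCA -> kNN -> shared-nearest-neighbor (Jaccard) graph -> Louvain
(or Leiden) community detection with a geometric/bisection search over the
resolution parameter until the mean cluster size enters the band.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import igraph as ig
import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = ["MicroClustering", "MicroClusterer", "build_knn_graph", "microcluster"]

#: minimum Jaccard shared-neighbor overlap kept as a graph edge
SNN_PRUNE = 1.0 / 15.0


@dataclass
class MicroClustering:
    """A partition of cells into k micro-clusters.

    ``assignment`` holds 1-based cluster indices.  ``in_band`` is False when
    the resolution search could not bring the mean cluster size n/k into
    ``target_band`` (the closest achieved partition is returned).
    """

    assignment: np.ndarray
    k: int
    resolution: float
    target_band: Tuple[float, float]
    seed: int
    in_band: bool = True

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=int)
        sizes = np.bincount(self.assignment)[1:]
        if self.assignment.min(initial=1) < 1 or len(sizes) != self.k or (sizes == 0).any():
            raise ValueError("assignment must use contiguous 1..k cluster indices")

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.k + 1)[1:]

    def cells_of(self, cluster: int) -> np.ndarray:
        """Row indices of the cells in one (1-based) micro-cluster."""
        return np.flatnonzero(self.assignment == cluster)


def _as_values(mat) -> np.ndarray:
    values = getattr(mat, "values", mat)
    return np.asarray(values, dtype=float)


def build_knn_graph(mat, n_neighbors: int = 20, n_pcs: int = 30,
                    seed: int = 0) -> ig.Graph:
    """Shared-nearest-neighbor graph over cells in PCA space.

    Edge weights are the Jaccard overlap of the two cells' neighbor sets
    (self included), pruned below 1/15.  Deterministic given the seed.
    """
    X = _as_values(mat)
    n, m = X.shape
    if n_neighbors < 1:
        raise ValueError("n_neighbors must be positive")
    if n < n_neighbors + 1:
        raise ValueError(f"need at least n_neighbors+1={n_neighbors + 1} cells, got {n}")
    if n_pcs > m:
        raise ValueError(f"n_pcs={n_pcs} exceeds number of features {m}")
    n_comp = min(n_pcs, n - 1, m)
    if n_comp < m:
        X = PCA(n_components=n_comp, svd_solver="full", random_state=seed).fit_transform(X)
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(X)
    _, idx = nn.kneighbors(X)  # column 0 is the cell itself
    rows = np.repeat(np.arange(n), n_neighbors + 1)
    knn = sparse.csr_matrix(
        (np.ones(rows.size), (rows, idx.ravel())), shape=(n, n)
    )
    shared = knn @ knn.T  # counts of shared neighbors (self included)
    shared = sparse.triu(shared, k=1).tocoo()
    size = n_neighbors + 1
    jacc = shared.data / (2 * size - shared.data)
    keep = jacc >= SNN_PRUNE
    edges = list(zip(shared.row[keep].tolist(), shared.col[keep].tolist()))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = jacc[keep].tolist()
    return g


def _detect(graph: ig.Graph, resolution: float, seed: int, backend: str) -> np.ndarray:
    if backend == "louvain":
        ig.set_random_number_generator(random.Random(seed))
        part = graph.community_multilevel(
            weights="weight" if graph.ecount() else None, resolution=resolution
        )
        membership = np.asarray(part.membership)
    elif backend == "leiden":
        import leidenalg

        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight" if graph.ecount() else None,
            resolution_parameter=resolution,
            seed=seed,
        )
        membership = np.asarray(part.membership)
    else:
        raise ValueError(f"unknown community-detection backend {backend!r}")
    # relabel to contiguous 1..k in order of first appearance (deterministic)
    _, first = np.unique(membership, return_index=True)
    order = membership[np.sort(first)]
    remap = {old: new + 1 for new, old in enumerate(order)}
    return np.array([remap[c] for c in membership], dtype=int)


class MicroClusterer(ClusterMixin, BaseEstimator):
    """Partition cells into micro-clusters sized within a target band.

    Parameters
    ----------
    band : (float, float)
        Target mean-cluster-size band as fractions of n (default
        0.001-0.005, i.e. on average 0.1%-0.5% of cells per cluster).
    n_neighbors, n_pcs : int
        kNN/SNN graph construction parameters.
    backend : {"louvain", "leiden"}
        Community-detection algorithm; Louvain is the default.
    max_search_iter : int
        Cap on resolution-search iterations (bracket + bisection).
    seed : int
        Governs PCA, graph tie-breaks and community detection.

    Attributes
    ----------
    labels_ : ndarray
        1-based micro-cluster index per cell.
    k_ : int
    resolution_ : float
    in_band_ : bool
    result_ : MicroClustering
    """

    def __init__(self, band=(0.001, 0.005), n_neighbors=20, n_pcs=30,
                 backend="louvain", max_search_iter=25, seed=0):
        self.band = band
        self.n_neighbors = n_neighbors
        self.n_pcs = n_pcs
        self.backend = backend
        self.max_search_iter = max_search_iter
        self.seed = seed

    def fit(self, X, y=None):
        values = _as_values(X)
        n = values.shape[0]
        if n == 0:
            raise ValueError("empty matrix")
        lo, hi = self.band
        if not (0 < lo < hi <= 1):
            raise ValueError("band must satisfy 0 < lo < hi <= 1")
        if n == 1:
            warnings.warn("single cell: one trivial micro-cluster", stacklevel=2)
            self.result_ = MicroClustering(
                np.array([1]), 1, 1.0, (lo, hi), self.seed, in_band=False
            )
            self._finish()
            return self
        n_neighbors = min(self.n_neighbors, n - 1)
        n_pcs = min(self.n_pcs, values.shape[1])
        graph = build_knn_graph(values, n_neighbors=n_neighbors,
                                n_pcs=n_pcs, seed=self.seed)
        self.result_ = self._search(graph, n, (lo, hi))
        self._finish()
        return self

    def _finish(self):
        res = self.result_
        self.labels_ = res.assignment
        self.k_ = res.k
        self.resolution_ = res.resolution
        self.in_band_ = res.in_band

    def _search(self, graph: ig.Graph, n: int, band) -> MicroClustering:
        lo, hi = band
        # mean size n/k in [lo*n, hi*n]  <=>  k in [1/hi, 1/lo]
        k_min, k_max = 1.0 / hi, 1.0 / lo

        def run(res: float):
            labels = _detect(graph, res, self.seed, self.backend)
            return labels, int(labels.max())

        def dist(k: int) -> float:
            # log-scale distance from the admissible k interval
            if k_min <= k <= k_max:
                return 0.0
            bound = k_min if k < k_min else k_max
            return abs(np.log(max(k, 1)) - np.log(bound))

        iters = 0
        res = 1.0
        labels, k = run(res)
        iters += 1
        best = (dist(k), res, labels, k)
        lo_res = hi_res = None  # bracket: lo_res gives too few clusters, hi_res too many
        cur_res, cur_k = res, k
        # geometric bracketing
        while iters < self.max_search_iter and dist(cur_k) > 0:
            if cur_k < k_min:
                lo_res = cur_res
                cur_res *= 2.0
            else:
                hi_res = cur_res
                cur_res /= 2.0
            labels, cur_k = run(cur_res)
            iters += 1
            cand = (dist(cur_k), cur_res, labels, cur_k)
            if cand[0] < best[0]:
                best = cand
            if cur_k < k_min:
                lo_res = cur_res
            else:
                hi_res = cur_res
            if lo_res is not None and hi_res is not None:
                break
        # bisection inside the bracket
        while (iters < self.max_search_iter and best[0] > 0
               and lo_res is not None and hi_res is not None):
            mid = float(np.sqrt(lo_res * hi_res))
            labels, k = run(mid)
            iters += 1
            cand = (dist(k), mid, labels, k)
            if cand[0] < best[0]:
                best = cand
            if k < k_min:
                lo_res = mid
            elif k > k_max:
                hi_res = mid
            else:
                break
        d, res, labels, k = best
        in_band = d == 0.0
        if not in_band:
            warnings.warn(
                f"mean micro-cluster size outside target band (k={k}, "
                f"admissible k in [{k_min:.1f}, {k_max:.1f}])", stacklevel=3
            )
        return MicroClustering(labels, k, res, band, self.seed, in_band=in_band)


def microcluster(mat, target_band=(0.001, 0.005), seed: int = 0,
                 n_neighbors: int = 20, n_pcs: int = 30,
                 backend: str = "louvain",
                 max_search_iter: int = 25) -> MicroClustering:
    """Functional wrapper around :class:`MicroClusterer`."""
    mc = MicroClusterer(band=target_band, n_neighbors=n_neighbors, n_pcs=n_pcs,
                        backend=backend, max_search_iter=max_search_iter,
                        seed=seed).fit(mat)
    return mc.result_
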