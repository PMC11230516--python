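"""Cell categorization, KNN deconvolution of mixed cells, and the
end-to-end annotator.

After per-type positivity gating, each cell is *clean* (positive for
exactly one type), *mixed* (positive for several) or *unknown* (positive
for none).  Mixed cells are resolved per distinct candidate set xi: using
only the union of the candidate types' signature markers, each mixed cell
takes the modal label of its k nearest clean anchor cells (Euclidean
distance, k = 10 by default, capped at the available anchor count).
Candidate sets with no clean anchors at all stay unresolved ("Unknown").
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .matrices import CellFeatureMatrix, SignatureMatrix, lognormalize, znormalize
from .microcluster import MicroClustering, microcluster
from .scoring import CTRMatrix, compute_ctr, rank_cluster_medians
from .thresholding import (
    ThresholdEntry,
    ThresholdSet,
    binarize,
    optimal_threshold,
    relevance_groups,
    select_fit,
)

__all__ = ["CellAssignment", "categorize", "deconvolve", "annotate",
           "SignatureAnnotator"]

logger = logging.getLogger("phenogate")

UNKNOWN = "Unknown"
CATEGORIES = ("clean", "mixed", "mixed_resolved", "unknown", "unresolved_mixed")


@dataclass
class CellAssignment:
    """Per-cell label, category and provenance."""

    cell_ids: list
    labels: np.ndarray                 # cell-type name or "Unknown"
    categories: np.ndarray             # entries from CATEGORIES
    candidate_sets: list               # tuple of positive types per cell
    ctr: Optional[CTRMatrix] = None
    cell_type_names: list = field(default_factory=list)

    def __post_init__(self):
        n = len(self.cell_ids)
        self.labels = np.asarray(self.labels, dtype=object)
        self.categories = np.asarray(self.categories, dtype=object)
        if self.labels.size != n or self.categories.size != n:
            raise ValueError("labels/categories must have one entry per cell")
        bad = set(self.categories) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories: {bad}")

    def counts(self) -> Dict[str, int]:
        cats, cnts = np.unique(self.categories, return_counts=True)
        return dict(zip(cats.tolist(), cnts.tolist()))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "cell_id": self.cell_ids,
            "label": self.labels,
            "category": self.categories,
            "candidate_set": [";".join(c) for c in self.candidate_sets],
        })
        if self.ctr is not None:
            for j, t in enumerate(self.ctr.cell_type_names):
                df[f"ctr_{t}"] = self.ctr.scores[:, j]
        return df


def categorize(B: np.ndarray, cell_type_names, cell_ids,
               ctr: Optional[CTRMatrix] = None) -> CellAssignment:
    """Classify cells by row sums of the binary positivity matrix."""
    B = np.asarray(B)
    if not np.isin(B, (0, 1)).all():
        raise ValueError("positivity matrix must be binary")
    names = list(cell_type_names)
    positives = B.sum(axis=1)
    labels = np.empty(B.shape[0], dtype=object)
    categories = np.empty(B.shape[0], dtype=object)
    candidate_sets = []
    for i in range(B.shape[0]):
        pos = tuple(names[j] for j in np.flatnonzero(B[i]))
        candidate_sets.append(pos)
        if positives[i] == 1:
            labels[i] = pos[0]
            categories[i] = "clean"
        elif positives[i] == 0:
            labels[i] = UNKNOWN
            categories[i] = "unknown"
        else:
            labels[i] = UNKNOWN
            categories[i] = "mixed"
    return CellAssignment(cell_ids=list(cell_ids), labels=labels,
                          categories=categories, candidate_sets=candidate_sets,
                          ctr=ctr, cell_type_names=names)


def _modal_label(anchor_labels: np.ndarray, dists: np.ndarray,
                 xi_order: Tuple[str, ...]) -> str:
    """Mode of the neighbor labels; ties broken by the smallest mean
    distance to the tied label's neighbors, then by candidate-set order."""
    labels, counts = np.unique(anchor_labels, return_counts=True)
    top = counts.max()
    tied = [str(l) for l in labels[counts == top]]
    if len(tied) == 1:
        return tied[0]
    mean_d = {l: float(dists[anchor_labels == l].mean()) for l in tied}
    best = min(mean_d.values())
    closest = [l for l in tied if mean_d[l] == best]
    if len(closest) == 1:
        return closest[0]
    for t in xi_order:
        if t in closest:
            return t
    return closest[0]


def deconvolve(assign: CellAssignment, mat: CellFeatureMatrix,
               sig: SignatureMatrix, k_neighbors: int = 10) -> CellAssignment:
    """Resolve mixed cells by KNN against clean anchors in the candidate
    types' marker subspace.  Clean labels are never altered."""
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be at least 1")
    if not mat.normalized:
        raise ValueError("matrix must be normalized")
    labels = assign.labels.copy()
    categories = assign.categories.copy()
    clean = categories == "clean"
    mixed_idx = np.flatnonzero(categories == "mixed")
    groups: Dict[Tuple[str, ...], list] = {}
    for i in mixed_idx:
        groups.setdefault(assign.candidate_sets[i], []).append(i)
    for xi, members in sorted(groups.items()):
        members = np.asarray(members)
        markers = sorted({m for t in xi for m in sig.markers_of(t)})
        cols = mat.marker_index(markers)
        anchors = np.flatnonzero(clean & np.isin(labels, list(xi)))
        if anchors.size == 0:
            labels[members] = UNKNOWN
            categories[members] = "unresolved_mixed"
            warnings.warn(
                f"no clean anchors for candidate set {xi}: left unresolved",
                stacklevel=2,
            )
            continue
        k_eff = min(k_neighbors, anchors.size)
        A_anchor = mat.values[np.ix_(anchors, cols)]
        A_mixed = mat.values[np.ix_(members, cols)]
        nn = NearestNeighbors(n_neighbors=k_eff).fit(A_anchor)
        dists, idx = nn.kneighbors(A_mixed)
        anchor_labels = labels[anchors]
        for row, i in enumerate(members):
            labels[i] = _modal_label(anchor_labels[idx[row]], dists[row], xi)
            categories[i] = "mixed_resolved"
    return CellAssignment(cell_ids=assign.cell_ids, labels=labels,
                          categories=categories,
                          candidate_sets=assign.candidate_sets,
                          ctr=assign.ctr, cell_type_names=assign.cell_type_names)


def annotate(mat: CellFeatureMatrix, sig: SignatureMatrix,
             band=(0.001, 0.005), n_neighbors: int = 20, n_pcs: int = 30,
             k_neighbors: int = 10, backend: str = "louvain",
             max_search_iter: int = 25, seed: int = 0,
             normalize: str = "auto",
             ) -> Tuple[CellAssignment, ThresholdSet, MicroClustering]:
    """Run the full annotation pipeline and return assignment, thresholds
    and the micro-clustering.

    ``normalize="auto"`` z-scores proteomics / log-normalizes raw
    transcriptomics when the input is not yet normalized; ``"none"``
    requires pre-normalized input.
    """
    if normalize not in ("auto", "none"):
        raise ValueError("normalize must be 'auto' or 'none'")
    if not mat.normalized:
        if normalize == "none":
            raise ValueError("input matrix is not normalized")
        if mat.modality == "transcriptomics":
            mat = lognormalize(mat)
        else:
            mat = znormalize(mat)
    n_pcs = min(n_pcs, mat.n_markers, max(mat.n_cells - 1, 1))
    mc = microcluster(mat, target_band=band, seed=seed, n_neighbors=n_neighbors,
                      n_pcs=n_pcs, backend=backend,
                      max_search_iter=max_search_iter)
    logger.info("micro-clustering: k=%d at resolution %.4g (in band: %s)",
                mc.k, mc.resolution, mc.in_band)
    ctr = compute_ctr(mat, sig)
    thresholds = ThresholdSet()
    for cell_type in sig.cell_type_names:
        try:
            rm = rank_cluster_medians(ctr, mc, cell_type)
            fit = select_fit(rm.z, rm.r)
            groups = relevance_groups(fit, rm.r, mc)
            entry = optimal_threshold(ctr.column(cell_type), groups)
            entry = replace(entry, fit=fit)
            if entry.degenerate:
                # flat CTR curve or unusable relevance groups: make no
                # positive calls for this type rather than gate arbitrarily
                entry = replace(entry, theta=np.inf)
        except ValueError as exc:
            warnings.warn(f"thresholding failed for {cell_type!r}: {exc}",
                          stacklevel=2)
            entry = ThresholdEntry(theta=np.inf, objective_value=0,
                                   degenerate=True)
        thresholds.entries[cell_type] = entry
        logger.info("threshold[%s] = %.4g (objective %d%s)", cell_type,
                    entry.theta, entry.objective_value,
                    ", degenerate" if entry.degenerate else "")
    B = binarize(ctr, thresholds)
    assign = categorize(B, sig.cell_type_names, mat.cell_ids, ctr=ctr)
    logger.info("categories before deconvolution: %s", assign.counts())
    assign = deconvolve(assign, mat, sig, k_neighbors=k_neighbors)
    logger.info("categories after deconvolution: %s", assign.counts())
    return assign, thresholds, mc


class SignatureAnnotator(BaseEstimator):
    """Signature-driven cell-type annotator.

    Learns per-type CTR positivity thresholds on a cell-by-feature matrix
    (micro-clustering + segmented regression + misclassification-minimizing
    grid search) and labels every cell, resolving multi-positive cells by
    KNN in the relevant marker subspace.

    Parameters
    ----------
    signature : SignatureMatrix
        Marker x cell-type weights.
    band : (float, float)
        Target mean micro-cluster size band (fractions of n).
    n_neighbors, n_pcs : int
        SNN graph parameters for micro-clustering.
    k_neighbors : int
        Neighbors for mixed-cell deconvolution.
    backend : {"louvain", "leiden"}
    normalize : {"auto", "none"}
    seed : int

    Attributes
    ----------
    labels_ : ndarray of str
        Final per-cell labels ("Unknown" possible).
    assignment_ : CellAssignment
    thresholds_ : ThresholdSet
    microclusters_ : MicroClustering
    ctr_ : CTRMatrix
    """

    def __init__(self, signature=None, band=(0.001, 0.005), n_neighbors=20,
                 n_pcs=30, k_neighbors=10, backend="louvain",
                 max_search_iter=25, normalize="auto", seed=0):
        self.signature = signature
        self.band = band
        self.n_neighbors = n_neighbors
        self.n_pcs = n_pcs
        self.k_neighbors = k_neighbors
        self.backend = backend
        self.max_search_iter = max_search_iter
        self.normalize = normalize
        self.seed = seed

    def fit(self, X: CellFeatureMatrix, y=None):
        if self.signature is None:
            raise ValueError("a SignatureMatrix is required")
        assign, thresholds, mc = annotate(
            X, self.signature, band=self.band, n_neighbors=self.n_neighbors,
            n_pcs=self.n_pcs, k_neighbors=self.k_neighbors,
            backend=self.backend, max_search_iter=self.max_search_iter,
            seed=self.seed, normalize=self.normalize,
        )
        self.assignment_ = assign
        self.thresholds_ = thresholds
        self.microclusters_ = mc
        self.ctr_ = assign.ctr
        self.labels_ = assign.labels
        self._fitted_matrix = X
        return self

    def fit_predict(self, X: CellFeatureMatrix, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def predict(self, X: Optional[CellFeatureMatrix] = None) -> np.ndarray:
        """Labels for the fitted data, or gate new cells with the learned
        thresholds (deconvolving against the fitted clean anchors)."""
        if not hasattr(self, "labels_"):
            raise ValueError("annotator is not fitted")
        if X is None:
            return self.labels_
        if not X.normalized:
            if self.normalize == "none":
                raise ValueError("input matrix is not normalized")
            X = lognormalize(X) if X.modality == "transcriptomics" else znormalize(X)
        ctr = compute_ctr(X, self.signature)
        B = binarize(ctr, self.thresholds_)
        assign = categorize(B, self.signature.cell_type_names, X.cell_ids, ctr=ctr)
        # resolve against the anchors learned at fit time
        ref = self._fitted_matrix
        ref_norm = ref if ref.normalized else (
            lognormalize(ref) if ref.modality == "transcriptomics" else znormalize(ref)
        )
        combined = CellFeatureMatrix(
            values=np.vstack([ref_norm.values, X.values]),
            cell_ids=[f"ref::{c}" for c in ref_norm.cell_ids] + list(X.cell_ids),
            marker_names=list(ref_norm.marker_names),
            modality=ref_norm.modality, normalized=True,
        )
        base = self.assignment_
        labels = np.concatenate([base.labels, assign.labels])
        categories = np.concatenate([
            np.where(base.categories == "clean", "clean", "unknown"),
            assign.categories,
        ])
        merged = CellAssignment(
            cell_ids=combined.cell_ids, labels=labels, categories=categories,
            candidate_sets=[()] * ref_norm.n_cells + assign.candidate_sets,
            cell_type_names=list(self.signature.cell_type_names),
        )
        resolved = deconvolve(merged, combined, self.signature,
                              k_neighbors=self.k_neighbors)
        return resolved.labels[ref_norm.n_cells:]
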