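"""Per-type CTR positivity thresholds via rank-ordered segmented regression.

For one cell type, micro-cluster median CTRs ``z`` are regressed on their
ranks ``r`` with a continuous piecewise-linear (hinge) model

    z_hat(r) = alpha0 + beta0*r + sum_i beta_i * max(0, r - phi_i)

allowing g = 1, 2 or 3 breakpoints; the fit with minimal AIC wins (ties go
to fewer breakpoints).  Micro-clusters ranked at or below the lowest
breakpoint form the low-relevance group, those at or above the highest
breakpoint the high-relevance group.  The positivity threshold theta is
then the grid-search minimizer of the number of low-group cells scoring
above it plus high-group cells scoring below it.  Cells with CTR strictly
greater than theta are called positive.

Breakpoints live on the half-integer rank grid (2.5, 3.5, ..., k-1.5),
which makes group membership unambiguous (no rank ever equals a
breakpoint) and each segment hold at least two points.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .microcluster import MicroClustering
from .scoring import CTRMatrix, RankedMedians

__all__ = [
    "SegmentedFit",
    "RelevanceGroups",
    "ThresholdEntry",
    "ThresholdSet",
    "fit_segmented",
    "select_fit",
    "relevance_groups",
    "optimal_threshold",
    "binarize",
]

#: minimum number of rank points per linear segment
MIN_SEGMENT = 2
#: candidate count above which exhaustive breakpoint enumeration is replaced
#: by a coarse grid plus coordinate-descent refinement
MAX_EXHAUSTIVE = 120_000
#: chunk size (candidate tuples per batched solve) to bound memory
CHUNK = 4096
#: effective parameters charged per breakpoint in the AIC: one slope change
#: plus three effective degrees of freedom for the grid-optimized knot
#: location (free knots selected by exhaustive search absorb far more
#: residual variance than a fixed regressor; the 3-df knot cost follows the
#: established convention for adaptively placed hinge knots)
_KNOT_COST = 4
_SSE_FLOOR = 1e-300


@dataclass
class SegmentedFit:
    """A fitted continuous piecewise-linear model on ranks."""

    g: int
    breakpoints: np.ndarray
    alpha0: float
    beta0: float
    betas: np.ndarray
    sse: float
    aic: float
    k: int

    def predict(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        out = self.alpha0 + self.beta0 * r
        for phi, beta in zip(self.breakpoints, self.betas):
            out = out + beta * np.maximum(0.0, r - phi)
        return out


@dataclass
class RelevanceGroups:
    """Micro-cluster index sets below/above the outer breakpoints, and
    the row indices of their member cells."""

    phi_low: np.ndarray
    phi_high: np.ndarray
    cells_low: np.ndarray
    cells_high: np.ndarray
    degenerate: bool = False


@dataclass
class ThresholdEntry:
    theta: float
    objective_value: int
    degenerate: bool = False
    fit: Optional[SegmentedFit] = None


@dataclass
class ThresholdSet:
    """Per-cell-type positivity thresholds."""

    entries: Dict[str, ThresholdEntry] = field(default_factory=dict)

    def theta(self, cell_type: str) -> float:
        return self.entries[cell_type].theta

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, e in self.entries.items():
            rows.append({
                "cell_type": name,
                "theta": e.theta,
                "objective_value": e.objective_value,
                "degenerate": e.degenerate,
                "g": e.fit.g if e.fit else None,
                "breakpoints": ";".join(f"{b:g}" for b in e.fit.breakpoints)
                if e.fit else "",
            })
        return pd.DataFrame(rows)


def _batched_sse(r: np.ndarray, z: np.ndarray, bps: np.ndarray):
    """Least-squares SSE (and coefficients) for each breakpoint tuple.

    With the points sorted by rank, every normal-equation entry of the
    hinge model has a closed form in suffix sums of r, r^2, z and r*z, so
    each candidate costs O(p^2) instead of O(k p^2).
    """
    order = np.argsort(r, kind="stable")
    rs, zs = np.asarray(r, dtype=float)[order], np.asarray(z, dtype=float)[order]
    k = rs.size
    g = bps.shape[1]
    p = 2 + g
    # suffix sums: suf[s] = sum over points with sorted index >= s
    def suffix(v):
        out = np.zeros(v.size + 1)
        out[:-1] = np.cumsum(v[::-1])[::-1]
        return out

    C0 = suffix(np.ones(k))
    C1 = suffix(rs)
    C2 = suffix(rs * rs)
    Z0 = suffix(zs)
    Z1 = suffix(rs * zs)
    zz = float(zs @ zs)
    sum_r, sum_r2, sum_z, sum_rz = C1[0], C2[0], Z0[0], Z1[0]

    s = np.searchsorted(rs, bps.ravel()).reshape(bps.shape)  # suffix starts
    n = bps.shape[0]
    XtX = np.empty((n, p, p))
    Xtz = np.empty((n, p))
    XtX[:, 0, 0] = k
    XtX[:, 0, 1] = XtX[:, 1, 0] = sum_r
    XtX[:, 1, 1] = sum_r2
    Xtz[:, 0] = sum_z
    Xtz[:, 1] = sum_rz
    for a in range(g):
        sa, fa = s[:, a], bps[:, a]
        one_h = C1[sa] - fa * C0[sa]
        r_h = C2[sa] - fa * C1[sa]
        XtX[:, 0, 2 + a] = XtX[:, 2 + a, 0] = one_h
        XtX[:, 1, 2 + a] = XtX[:, 2 + a, 1] = r_h
        Xtz[:, 2 + a] = Z1[sa] - fa * Z0[sa]
        for b in range(a, g):
            # breakpoints are increasing, so the b-th suffix is the overlap
            sb, fb = s[:, b], bps[:, b]
            hh = C2[sb] - (fa + fb) * C1[sb] + fa * fb * C0[sb]
            XtX[:, 2 + a, 2 + b] = XtX[:, 2 + b, 2 + a] = hh
    try:
        coefs = np.linalg.solve(XtX, Xtz[..., None])[..., 0]
    except np.linalg.LinAlgError:
        coefs = (np.linalg.pinv(XtX) @ Xtz[..., None])[..., 0]
    sses = np.maximum(zz - np.einsum("np,np->n", coefs, Xtz), 0.0)
    return sses, coefs


def _grid(k: int) -> np.ndarray:
    """Half-integer breakpoint candidates leaving >= MIN_SEGMENT points
    on each side: 2.5, 3.5, ..., k - 1.5."""
    return np.arange(MIN_SEGMENT, k - MIN_SEGMENT + 1) + 0.5


def _valid_tuples(grid: np.ndarray, g: int):
    """All strictly increasing g-tuples with >= MIN_SEGMENT ranks between
    consecutive breakpoints."""
    if g == 1:
        return grid[:, None]
    out = [c for c in combinations(grid, g)
           if all(b - a >= MIN_SEGMENT for a, b in zip(c, c[1:]))]
    return np.array(out) if out else np.empty((0, g))


def _count_tuples(npos: int, g: int) -> int:
    # tuples from npos positions with gap >= MIN_SEGMENT between picks
    eff = npos - (g - 1) * (MIN_SEGMENT - 1)
    if eff < g:
        return 0
    return math.comb(eff, g)


def _coarse_refine(r: np.ndarray, z: np.ndarray, grid: np.ndarray, g: int):
    """Coarse-grid enumeration followed by per-breakpoint coordinate descent
    on the full half-integer grid.  Deterministic."""
    npos = grid.size
    max_coarse = max(int((MAX_EXHAUSTIVE * math.factorial(g)) ** (1.0 / g)), 8) \
        if g > 1 else npos
    max_coarse = min(max_coarse, 40 if g >= 3 else 400, npos)
    coarse = grid[np.unique(np.linspace(0, npos - 1, max_coarse).round().astype(int))]
    cand = _valid_tuples(coarse, g)
    if cand.shape[0] == 0:
        cand = _valid_tuples(grid, g)
        if cand.shape[0] == 0:
            return None
    sses, _ = _batched_sse(r, z, cand)
    best = cand[int(np.argmin(sses))].copy()
    best_sse = float(np.min(sses))
    # coordinate descent on the full grid
    for _ in range(25):
        improved = False
        for i in range(g):
            lo = best[i - 1] + MIN_SEGMENT if i > 0 else grid[0]
            hi = best[i + 1] - MIN_SEGMENT if i < g - 1 else grid[-1]
            options = grid[(grid >= lo) & (grid <= hi)]
            if options.size == 0:
                continue
            trial = np.tile(best, (options.size, 1))
            trial[:, i] = options
            sses, _ = _batched_sse(r, z, trial)
            j = int(np.argmin(sses))
            if sses[j] < best_sse - 1e-12:
                best_sse = float(sses[j])
                best = trial[j].copy()
                improved = True
        if not improved:
            break
    return best[None, :]


def fit_segmented(z, r, g: int) -> SegmentedFit:
    """Least-squares segmented fit with exactly ``g`` breakpoints.

    Breakpoints are optimized on the half-integer rank grid; AIC uses the
    Gaussian-likelihood form k*ln(SSE/k) + 2*(2 + 4g), counting the
    intercept, base slope, and per breakpoint one slope change plus three
    effective degrees of freedom for the optimized knot location.
    """
    z = np.asarray(z, dtype=float)
    r = np.asarray(r, dtype=float)
    if z.size != r.size:
        raise ValueError("z and r must have the same length")
    k = z.size
    if g not in (1, 2, 3):
        raise ValueError("g must be 1, 2 or 3")
    if k < 2 * g + 2:
        raise ValueError(f"insufficient clusters for {g} breakpoints (k={k})")
    grid = _grid(k)
    n_tuples = _count_tuples(grid.size, g)
    if n_tuples == 0:
        raise ValueError(f"insufficient clusters for {g} breakpoints (k={k})")
    if n_tuples <= MAX_EXHAUSTIVE:
        cand = _valid_tuples(grid, g)
    else:
        cand = _coarse_refine(r, z, grid, g)
        if cand is None:
            raise ValueError(f"insufficient clusters for {g} breakpoints (k={k})")
    sses, coefs = _batched_sse(r, z, cand)
    best = int(np.argmin(sses))  # first minimum -> smallest breakpoints win ties
    bps = cand[best]
    beta = coefs[best]
    sse = float(sses[best])
    aic = k * np.log(max(sse, _SSE_FLOOR) / k) + 2 * (2 + _KNOT_COST * g)
    return SegmentedFit(g=g, breakpoints=np.asarray(bps, dtype=float),
                        alpha0=float(beta[0]), beta0=float(beta[1]),
                        betas=np.asarray(beta[2:], dtype=float),
                        sse=sse, aic=float(aic), k=k)


def select_fit(z, r) -> SegmentedFit:
    """Fit g = 1, 2, 3 (where feasible) and return the minimum-AIC model.

    AIC ties are broken toward fewer breakpoints.
    """
    z = np.asarray(z, dtype=float)
    fits = []
    for g in (1, 2, 3):
        try:
            fits.append(fit_segmented(z, r, g))
        except ValueError:
            continue
    if not fits:
        raise ValueError("too few micro-clusters for any segmented fit")
    best = fits[0]
    for f in fits[1:]:
        if f.aic < best.aic:
            best = f
    return best


def relevance_groups(fit: SegmentedFit, r, mc: MicroClustering) -> RelevanceGroups:
    """Split micro-clusters into low/high relevance groups at the outer
    breakpoints and collect their member cells."""
    r = np.asarray(r, dtype=float)
    phi1 = fit.breakpoints[0]
    phig = fit.breakpoints[-1]
    low = np.flatnonzero(r <= phi1)
    high = np.flatnonzero(r >= phig)
    cells_low = np.flatnonzero(np.isin(mc.assignment, low + 1))
    cells_high = np.flatnonzero(np.isin(mc.assignment, high + 1))
    degenerate = low.size == 0 or high.size == 0
    if degenerate:
        warnings.warn("degenerate relevance groups (one side empty)", stacklevel=2)
    return RelevanceGroups(phi_low=low + 1, phi_high=high + 1,
                           cells_low=cells_low, cells_high=cells_high,
                           degenerate=degenerate)


def optimal_threshold(ctr_column, groups: RelevanceGroups) -> ThresholdEntry:
    """Misclassification-minimizing CTR threshold between the two groups.

    Candidates are the midpoints between consecutive sorted unique scores
    of the pooled group cells, plus one candidate below the minimum and one
    above the maximum; the objective counts low-group cells strictly above
    theta plus high-group cells strictly below theta.  Ties go to the
    smallest candidate.
    """
    col = np.asarray(ctr_column, dtype=float)
    if groups.degenerate or groups.cells_low.size == 0 or groups.cells_high.size == 0:
        warnings.warn("degenerate groups: threshold set to +inf (no positives)",
                      stacklevel=2)
        return ThresholdEntry(theta=np.inf, objective_value=0, degenerate=True)
    low = np.sort(col[groups.cells_low])
    high = np.sort(col[groups.cells_high])
    pooled = np.unique(np.concatenate([low, high]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0
    candidates = np.concatenate([[pooled[0] - 1.0], mids, [pooled[-1] + 1.0]])
    # objective(theta) = #{low > theta} + #{high < theta}
    above_low = low.size - np.searchsorted(low, candidates, side="right")
    below_high = np.searchsorted(high, candidates, side="left")
    objective = above_low + below_high
    best = int(np.argmin(objective))  # argmin returns first -> smallest theta
    degenerate = pooled.size == 1
    if degenerate:
        warnings.warn("all pooled scores identical: threshold is arbitrary",
                      stacklevel=2)
    return ThresholdEntry(theta=float(candidates[best]),
                          objective_value=int(objective[best]),
                          degenerate=degenerate)


def binarize(ctr: CTRMatrix, thresholds: ThresholdSet) -> np.ndarray:
    """Binary positivity matrix: 1 where score strictly exceeds theta."""
    missing = [t for t in ctr.cell_type_names if t not in thresholds.entries]
    if missing:
        raise ValueError(f"no threshold for cell types: {missing}")
    theta = np.array([thresholds.theta(t) for t in ctr.cell_type_names])
    return (ctr.scores > theta[None, :]).astype(np.int8)
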