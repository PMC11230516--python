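"""Seeded synthetic spatial-omics datasets with known ground truth.

The generator emulates, at fixture scale, the failure modes that make
marker-based phenotyping hard: mixed-signal doublets (two types' signals
in one segmented cell) and spillover/bleed-through (a fraction of the
nearest spatial neighbor's signal leaking across a cell boundary).

Proteomics mode draws background marker values from Normal(0, noise_sd)
and shifts each cell's signature markers by ``signal_shift`` standard
deviations (scaled by the signature weight).  Transcriptomics mode draws
Poisson counts with a background rate of 0.5 and a signature rate of
0.5 * 2**(signal_shift * weight).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .matrices import CellFeatureMatrix, SignatureMatrix

__all__ = ["SyntheticSpec", "generate"]

#: default population mix: eight types, two of them rare (1%)
DEFAULT_FRACTIONS = {
    "TypeA": 0.25, "TypeB": 0.20, "TypeC": 0.15, "TypeD": 0.14,
    "TypeE": 0.13, "TypeF": 0.11, "RareG": 0.01, "RareH": 0.01,
}
_POISSON_BG = 0.5


@dataclass
class SyntheticSpec:
    """Design of a synthetic dataset.

    ``signature_map`` maps marker name -> (cell type, weight); when None,
    markers are assigned to types round-robin with weight 1 so every type
    owns at least two unique markers at the defaults (20 markers, 8 types).
    """

    n_cells: int = 10_000
    cell_type_fractions: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTIONS))
    n_markers: int = 20
    signature_map: Optional[Dict[str, Tuple[str, float]]] = None
    signal_shift: float = 3.0
    noise_sd: float = 1.0
    doublet_fraction: float = 0.0
    spillover_rate: float = 0.0
    spatial_layout: str = "random"
    modality: str = "proteomics"
    seed: int = 0

    def __post_init__(self):
        total = sum(self.cell_type_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cell type fractions must sum to 1 (got {total})")
        for name, value in (("doublet_fraction", self.doublet_fraction),
                            ("spillover_rate", self.spillover_rate)):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_cells < 1 or self.n_markers < 1:
            raise ValueError("n_cells and n_markers must be positive")
        if self.spatial_layout not in ("random", "clustered"):
            raise ValueError("spatial_layout must be 'random' or 'clustered'")
        if self.modality not in ("proteomics", "transcriptomics"):
            raise ValueError("modality must be proteomics or transcriptomics")
        if self.n_markers < len(self.cell_type_fractions):
            raise ValueError("need at least one marker per cell type")


def _default_signature_map(spec: SyntheticSpec) -> Dict[str, Tuple[str, float]]:
    types = list(spec.cell_type_fractions)
    return {
        f"M{i + 1:02d}": (types[i % len(types)], 1.0)
        for i in range(spec.n_markers)
    }


def _type_counts(fractions: Dict[str, float], n: int) -> Dict[str, int]:
    """Largest-remainder rounding so counts sum to n and no type is empty."""
    names = list(fractions)
    raw = np.array([fractions[t] * n for t in names])
    counts = np.floor(raw).astype(int)
    counts = np.maximum(counts, 1)
    while counts.sum() > n:
        counts[int(np.argmax(counts))] -= 1
    rema = raw - np.floor(raw)
    order = np.argsort(-rema, kind="stable")
    i = 0
    while counts.sum() < n:
        counts[order[i % len(names)]] += 1
        i += 1
    return dict(zip(names, counts.tolist()))


def generate(spec: SyntheticSpec
             ) -> Tuple[CellFeatureMatrix, SignatureMatrix, pd.DataFrame]:
    """Draw one dataset: features, its signature matrix, and a truth table.

    The truth table has columns ``cell_id, label, is_doublet, parent_1,
    parent_2`` (parents equal the label for singlets).  Byte-identical
    across runs with the same spec.
    """
    rng = np.random.default_rng(spec.seed)
    sig_map = spec.signature_map or _default_signature_map(spec)
    markers = list(sig_map)
    extra = [f"M{i + 1:02d}" for i in range(len(markers), spec.n_markers)
             if f"M{i + 1:02d}" not in sig_map]
    markers = markers + extra  # extras are pure-noise markers
    types = list(spec.cell_type_fractions)
    n, m = spec.n_cells, len(markers)

    weights = np.zeros((m, len(types)))
    for i, marker in enumerate(markers):
        if marker in sig_map:
            cell_type, w = sig_map[marker]
            weights[i, types.index(cell_type)] = w
    signature = SignatureMatrix(weights=weights, marker_names=markers,
                                cell_type_names=types)

    counts = _type_counts(spec.cell_type_fractions, n)
    primary = np.concatenate([np.repeat(t, c) for t, c in counts.items()])
    rng.shuffle(primary)

    n_doublets = int(round(spec.doublet_fraction * n))
    doublet_idx = rng.choice(n, size=n_doublets, replace=False) if n_doublets else \
        np.array([], dtype=int)
    secondary = np.array([""] * n, dtype=object)
    for i in doublet_idx:
        others = [t for t in types if t != primary[i]]
        secondary[i] = others[rng.integers(len(others))]

    # per-cell mean shift per marker, scaled by signature weight
    shift = np.zeros((n, m))
    type_index = {t: j for j, t in enumerate(types)}
    for j, t in enumerate(types):
        member = primary == t
        shift[member] += weights[:, j][None, :] * spec.signal_shift
    for i in doublet_idx:
        shift[i] += weights[:, type_index[secondary[i]]] * spec.signal_shift

    coords = _layout(spec, rng, primary, types)

    if spec.modality == "proteomics":
        values = rng.normal(0.0, spec.noise_sd, size=(n, m)) + shift * spec.noise_sd
    else:
        rate = _POISSON_BG * np.exp2(shift)
        values = rng.poisson(rate).astype(float)

    if spec.spillover_rate > 0 and n > 1:
        nn = NearestNeighbors(n_neighbors=2).fit(coords)
        _, idx = nn.kneighbors(coords)
        neighbor = idx[:, 1]
        values = values + spec.spillover_rate * values[neighbor]
        if spec.modality == "transcriptomics":
            values = np.floor(values)

    cell_ids = [f"cell_{i + 1:06d}" for i in range(n)]
    mat = CellFeatureMatrix(values=values, cell_ids=cell_ids,
                            marker_names=markers, modality=spec.modality,
                            coords=coords, normalized=False)
    is_doublet = np.zeros(n, dtype=bool)
    is_doublet[doublet_idx] = True
    truth = pd.DataFrame({
        "cell_id": cell_ids,
        "label": primary,
        "is_doublet": is_doublet,
        "parent_1": primary,
        "parent_2": np.where(is_doublet, secondary, primary),
    })
    return mat, signature, truth


def _layout(spec: SyntheticSpec, rng: np.random.Generator,
            primary: np.ndarray, types) -> np.ndarray:
    side = 1000.0
    if spec.spatial_layout == "random":
        return rng.uniform(0.0, side, size=(spec.n_cells, 2))
    centers = rng.uniform(0.2 * side, 0.8 * side, size=(len(types), 2))
    coords = np.empty((spec.n_cells, 2))
    for j, t in enumerate(types):
        member = primary == t
        coords[member] = centers[j] + rng.normal(0.0, 0.08 * side,
                                                 size=(int(member.sum()), 2))
    return coords
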