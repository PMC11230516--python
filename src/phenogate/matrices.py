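"""Cell-by-feature and signature matrices: containers, I/O, normalization.

The cell-by-feature matrix ``A`` (n cells x m markers) holds antibody
intensities (proteomics) or transcript counts (transcriptomics).  The
signature matrix ``S`` (m markers x t cell types) holds expert-curated
importance weights in (0, 1] marking which markers define each type.
Scoring downstream is the plain matrix product ``A @ S``, so both objects
validate strictly at construction time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "CellFeatureMatrix",
    "SignatureMatrix",
    "load_cell_feature",
    "load_signature",
    "znormalize",
    "lognormalize",
    "bind_multimodal",
    "write_csv",
]

MODALITIES = ("proteomics", "transcriptomics", "multimodal")


@dataclass
class CellFeatureMatrix:
    """Dense per-cell marker table with optional spatial centroids.

    Parameters
    ----------
    values : ndarray of shape (n_cells, n_markers)
        Marker values; raw intensities/counts or normalized values
        depending on ``normalized``.
    cell_ids : sequence of str
        Unique cell identifiers, one per row.
    marker_names : sequence of str
        Unique marker/gene names, one per column.
    modality : {"proteomics", "transcriptomics", "multimodal"}
    coords : ndarray of shape (n_cells, 2), optional
        x/y centroids in image units.
    normalized : bool
        Whether normalization has been applied.
    """

    values: np.ndarray
    cell_ids: list = field(default_factory=list)
    marker_names: list = field(default_factory=list)
    modality: str = "proteomics"
    coords: Optional[np.ndarray] = None
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cell x marker array")
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise ValueError("matrix must have at least one cell and one marker")
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.marker_names = [str(c) for c in self.marker_names]
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(self.marker_names) != m:
            raise ValueError(f"{len(self.marker_names)} marker names for {m} columns")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell identifier")
        if len(set(self.marker_names)) != m:
            raise ValueError("duplicate marker name")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 2):
                raise ValueError("coords must have shape (n_cells, 2)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("marker values must be finite")
        if self.modality == "transcriptomics" and not self.normalized:
            if np.any(self.values < 0):
                raise ValueError("raw transcript counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Return values as a DataFrame indexed by cell id."""
        return pd.DataFrame(
            self.values, index=pd.Index(self.cell_ids, name="cell_id"),
            columns=self.marker_names,
        )

    def marker_index(self, names: Sequence[str]) -> np.ndarray:
        """Column indices for the given marker names (error if absent)."""
        pos = {m: i for i, m in enumerate(self.marker_names)}
        missing = [m for m in names if m not in pos]
        if missing:
            raise KeyError(f"markers not present in cell-feature matrix: {missing}")
        return np.array([pos[m] for m in names], dtype=int)


@dataclass
class SignatureMatrix:
    """Marker x cell-type weight table; entries are 0 or lie in (0, 1]."""

    weights: np.ndarray
    marker_names: list = field(default_factory=list)
    cell_type_names: list = field(default_factory=list)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be a 2-D marker x cell-type array")
        mm, t = self.weights.shape
        self.marker_names = [str(c) for c in self.marker_names]
        self.cell_type_names = [str(c) for c in self.cell_type_names]
        if len(self.marker_names) != mm or len(self.cell_type_names) != t:
            raise ValueError("name lists do not match weight dimensions")
        if len(set(self.cell_type_names)) != t:
            raise ValueError("duplicate cell type name")
        if len(set(self.marker_names)) != mm:
            raise ValueError("duplicate marker name")
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("signature weights must be 0 or in (0, 1]")
        zero_types = [self.cell_type_names[j]
                      for j in range(t) if not np.any(self.weights[:, j] > 0)]
        if zero_types:
            raise ValueError(f"cell type has no signature markers: {zero_types}")
        zero_rows = [self.marker_names[i]
                     for i in range(mm) if not np.any(self.weights[i] > 0)]
        if zero_rows:
            warnings.warn(
                f"markers with no signature membership: {zero_rows}", stacklevel=2
            )

    @property
    def n_types(self) -> int:
        return self.weights.shape[1]

    def markers_of(self, cell_type: str) -> list:
        """Signature markers (weight > 0) of one cell type."""
        j = self.cell_type_names.index(cell_type)
        return [m for m, w in zip(self.marker_names, self.weights[:, j]) if w > 0]

    def unique_markers(self) -> list:
        """Markers that are a signature of exactly one cell type."""
        counts = (self.weights > 0).sum(axis=1)
        return [m for m, c in zip(self.marker_names, counts) if c == 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weights, index=pd.Index(self.marker_names, name="marker"),
            columns=self.cell_type_names,
        )


def load_cell_feature(
    path,
    format: str = "csv",
    id_column: str = "cell_id",
    coord_columns: Optional[Sequence[str]] = ("x", "y"),
    modality: str = "proteomics",
    row_names_path=None,
    col_names_path=None,
) -> CellFeatureMatrix:
    """Read a cell-by-feature table from CSV/TSV or MatrixMarket triplets.

    For ``format="mtx-triplet"`` the matrix file is accompanied by
    newline-delimited row-name (cell) and column-name (marker) sidecar
    files, defaulting to ``<stem>_rows.txt`` / ``<stem>_cols.txt``.
    Row order is preserved from the file; markers are every non-ID,
    non-coordinate column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx-triplet":
        return _load_mtx_triplet(path, row_names_path, col_names_path, modality)
    if format not in ("csv", "tsv"):
        raise ValueError(f"unknown format {format!r}")
    sep = "," if format == "csv" else "\t"
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.shape[0] == 0:
        raise ValueError(f"empty file: {path}")
    if id_column not in df.columns:
        raise ValueError(f"id column {id_column!r} not found in {path}")
    ids = df[id_column].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValueError(f"duplicate cell identifier: {dup!r}")
    coords = None
    coord_cols: list = []
    if coord_columns is not None and all(c in df.columns for c in coord_columns):
        coord_cols = list(coord_columns)
        coords = df[coord_cols].to_numpy(dtype=float)
    marker_cols = [c for c in df.columns if c != id_column and c not in coord_cols]
    if not marker_cols:
        raise ValueError("no marker columns found")
    body = df[marker_cols]
    for col in marker_cols:
        converted = pd.to_numeric(body[col], errors="coerce")
        bad = converted.isna() & body[col].notna()
        if bad.any():
            row = ids[bad].iloc[0]
            raise ValueError(
                f"non-numeric marker value at cell {row!r}, column {col!r}"
            )
        if converted.isna().any():
            row = ids[converted.isna()].iloc[0]
            raise ValueError(f"missing marker value at cell {row!r}, column {col!r}")
    values = body.apply(pd.to_numeric).to_numpy(dtype=float)
    return CellFeatureMatrix(
        values=values, cell_ids=list(ids), marker_names=marker_cols,
        modality=modality, coords=coords, normalized=False,
    )


def _load_mtx_triplet(path, row_names_path, col_names_path, modality):
    stem = path.with_suffix("")
    row_names_path = Path(row_names_path) if row_names_path else Path(f"{stem}_rows.txt")
    col_names_path = Path(col_names_path) if col_names_path else Path(f"{stem}_cols.txt")
    mat = spio.mmread(path)
    if sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    cell_ids = row_names_path.read_text().split()
    marker_names = col_names_path.read_text().split()
    return CellFeatureMatrix(
        values=mat, cell_ids=cell_ids, marker_names=marker_names,
        modality=modality, normalized=False,
    )


def load_signature(path) -> SignatureMatrix:
    """Read a marker x cell-type signature CSV (first column = marker names)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty signature table: {path}")
    body = df.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        raise ValueError("signature table contains non-numeric entries")
    return SignatureMatrix(
        weights=body.to_numpy(dtype=float),
        marker_names=[str(i) for i in df.index],
        cell_type_names=[str(c) for c in df.columns],
    )


def znormalize(mat: CellFeatureMatrix) -> CellFeatureMatrix:
    """Z-score each marker column (sample sd, ddof=1).

    Zero-variance columns map to all-zeros with a warning so signature
    alignment never silently loses a marker.
    """
    if mat.normalized:
        raise ValueError("matrix is already normalized")
    if mat.n_cells < 2:
        raise ValueError("cannot z-normalize one observation")
    mean = mat.values.mean(axis=0)
    sd = mat.values.std(axis=0, ddof=1)
    flat = sd == 0
    if flat.any():
        names = [m for m, f in zip(mat.marker_names, flat) if f]
        warnings.warn(f"zero-variance markers set to 0: {names}", stacklevel=2)
    safe_sd = np.where(flat, 1.0, sd)
    values = (mat.values - mean) / safe_sd
    values[:, flat] = 0.0
    return replace(mat, values=values, normalized=True)


def lognormalize(mat: CellFeatureMatrix, scale_factor: float = 1e4) -> CellFeatureMatrix:
    """Library-size normalize counts to ``scale_factor`` per cell, then log1p.

    Cells with zero total count become all-zero rows (with a warning).
    Natural log; zero counts stay exactly zero.
    """
    if mat.normalized:
        raise ValueError("matrix is already normalized")
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    if np.any(mat.values < 0):
        raise ValueError("negative counts")
    totals = mat.values.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} cells with zero total count", stacklevel=2)
    safe = np.where(empty, 1.0, totals)
    values = np.log1p(mat.values / safe[:, None] * scale_factor)
    values[empty] = 0.0
    return replace(mat, values=values, normalized=True)


def bind_multimodal(
    proteo: CellFeatureMatrix, transcripto: CellFeatureMatrix
) -> CellFeatureMatrix:
    """Column-concatenate matched protein and transcript matrices.

    Both inputs must be normalized and share the same cell-ID set (the
    transcript rows are reordered to the protein row order).  Colliding
    marker names get ``prot:`` / ``rna:`` prefixes — protein and RNA
    measurements of the same gene are distinct features.
    """
    if not (proteo.normalized and transcripto.normalized):
        raise ValueError("both matrices must be normalized before binding")
    pset, tset = set(proteo.cell_ids), set(transcripto.cell_ids)
    if pset != tset:
        diff = sorted(pset.symmetric_difference(tset))
        raise ValueError(f"cell-ID sets differ; symmetric difference: {diff}")
    order = [transcripto.cell_ids.index(c) for c in proteo.cell_ids] \
        if proteo.cell_ids != transcripto.cell_ids else None
    tvals = transcripto.values[order] if order is not None else transcripto.values
    collide = set(proteo.marker_names) & set(transcripto.marker_names)
    pnames = [f"prot:{m}" if m in collide else m for m in proteo.marker_names]
    tnames = [f"rna:{m}" if m in collide else m for m in transcripto.marker_names]
    coords = proteo.coords if proteo.coords is not None else transcripto.coords
    return CellFeatureMatrix(
        values=np.hstack([proteo.values, tvals]),
        cell_ids=list(proteo.cell_ids),
        marker_names=pnames + tnames,
        modality="multimodal",
        coords=coords,
        normalized=True,
    )


def write_csv(mat: CellFeatureMatrix, path) -> None:
    """Write the matrix (with coordinates, when present) back to CSV."""
    df = mat.to_frame().reset_index()
    if mat.coords is not None:
        df["x"] = mat.coords[:, 0]
        df["y"] = mat.coords[:, 1]
    df.to_csv(path, index=False, float_format="%.17g")
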