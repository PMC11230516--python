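"""Benchmarking metrics against a reference labeling, and marker
enrichment strength.

Per-type confusion counts treat a predicted "Unknown" as a miss (a false
negative for the cell's reference type, never a true positive).  The
summary metrics weight each type's recall/precision by its proportion in
the reference labeling:

    weighted recall    = sum_i TP_i / (TP_i + FN_i) * proportion_i
    weighted precision = sum_i TP_i / (TP_i + FP_i) * proportion_i
    weighted F1        = harmonic mean of the two
    accuracy           = pooled (TP + TN) / (TP + FP + TN + FN)

Marker enrichment strength tests, for every marker unique to a single
signature type, whether its values in cells assigned to that type exceed
those in cells assigned to other types (log2 fold change of means plus a
one-sided Wilcoxon rank-sum test, BH-adjusted across markers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrices import CellFeatureMatrix, SignatureMatrix

__all__ = ["EvaluationReport", "confusion", "weighted_metrics", "enrichment",
           "evaluate_labels"]

UNKNOWN = "Unknown"
RARE_PROPORTION = 0.01


@dataclass
class EvaluationReport:
    per_type: pd.DataFrame          # TP/FP/FN/TN, proportion, recall, precision
    accuracy: float
    weighted_recall: float
    weighted_precision: float
    weighted_f1: float
    dominant_types: list = field(default_factory=list)   # proportion >= 1%
    rare_types: list = field(default_factory=list)       # proportion < 1%

    def to_dict(self) -> Dict:
        return {
            "accuracy": self.accuracy,
            "weighted_recall": self.weighted_recall,
            "weighted_precision": self.weighted_precision,
            "weighted_f1": self.weighted_f1,
            "dominant_types": self.dominant_types,
            "rare_types": self.rare_types,
            "per_type": self.per_type.reset_index().to_dict(orient="records"),
        }


def _labels_of(pred) -> pd.Series:
    """Accept a CellAssignment, a mapping/Series, or (ids, labels)."""
    if hasattr(pred, "cell_ids") and hasattr(pred, "labels"):
        return pd.Series(np.asarray(pred.labels, dtype=object),
                         index=[str(c) for c in pred.cell_ids])
    s = pd.Series(pred) if not isinstance(pred, pd.Series) else pred
    s.index = s.index.astype(str)
    return s.astype(object)


def confusion(pred, ref, exclude_labels: Optional[Sequence[str]] = None
              ) -> pd.DataFrame:
    """Per-type TP/FP/FN/TN over the cells shared by both labelings.

    Reference cells whose label is in ``exclude_labels`` are dropped before
    counting (e.g. reference categories like "dirt" or "undefined").
    Predicted "Unknown" counts as FN for the cell's reference type.
    """
    p = _labels_of(pred)
    r = _labels_of(ref)
    shared = p.index.intersection(r.index)
    if shared.empty:
        raise ValueError("predicted and reference labelings share no cell IDs")
    p, r = p.loc[shared], r.loc[shared]
    if exclude_labels:
        keep = ~r.isin(list(exclude_labels))
        p, r = p[keep], r[keep]
    if r.empty:
        raise ValueError("no reference cells left after exclusion")
    types = sorted(set(r.unique()) | (set(p.unique()) - {UNKNOWN}))
    n = len(r)
    rows = []
    for t in types:
        in_ref = (r == t).to_numpy()
        in_pred = (p == t).to_numpy()
        tp = int((in_ref & in_pred).sum())
        fp = int((~in_ref & in_pred).sum())
        fn = int((in_ref & ~in_pred).sum())
        tn = n - tp - fp - fn
        rows.append({"cell_type": t, "TP": tp, "FP": fp, "FN": fn, "TN": tn,
                     "proportion": in_ref.sum() / n})
    return pd.DataFrame(rows).set_index("cell_type")


def weighted_metrics(counts: pd.DataFrame) -> EvaluationReport:
    """Proportion-weighted recall/precision/F1 and pooled accuracy."""
    df = counts.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = df["TP"] / (df["TP"] + df["FN"])
        precision = df["TP"] / (df["TP"] + df["FP"])
    zero_rec = recall.isna()
    zero_pre = precision.isna()
    if zero_rec.any() or zero_pre.any():
        warnings.warn("types with zero denominator scored 0", stacklevel=2)
    df["recall"] = recall.fillna(0.0)
    df["precision"] = precision.fillna(0.0)
    w = df["proportion"]
    wr = float((df["recall"] * w).sum())
    wp = float((df["precision"] * w).sum())
    wf1 = 0.0 if wp + wr == 0 else 2.0 * wp * wr / (wp + wr)
    totals = df[["TP", "FP", "FN", "TN"]].sum()
    accuracy = float((totals["TP"] + totals["TN"]) / totals.sum())
    dominant = df.index[w >= RARE_PROPORTION].tolist()
    rare = df.index[(w > 0) & (w < RARE_PROPORTION)].tolist()
    return EvaluationReport(per_type=df, accuracy=accuracy, weighted_recall=wr,
                            weighted_precision=wp, weighted_f1=wf1,
                            dominant_types=dominant, rare_types=rare)


def evaluate_labels(pred, ref, exclude_labels=None) -> EvaluationReport:
    """Convenience: confusion + weighted metrics in one call."""
    return weighted_metrics(confusion(pred, ref, exclude_labels=exclude_labels))


def enrichment(mat: CellFeatureMatrix, assign, sig: SignatureMatrix,
               pseudocount: float = 0.01) -> pd.DataFrame:
    """Enrichment of type-unique markers in their assigned cells.

    For each marker that is a signature of exactly one type: log2 fold
    change of the mean value in cells assigned to that type versus cells
    assigned to any other type (a pseudocount guards zero means), plus a
    one-sided Wilcoxon rank-sum p-value (greater) and its BH adjustment.
    """
    labels = _labels_of(assign)
    labels = labels.reindex([str(c) for c in mat.cell_ids])
    assigned = labels.isin(sig.cell_type_names).to_numpy()
    rows = []
    type_of = {}
    for m in sig.unique_markers():
        i = sig.marker_names.index(m)
        j = int(np.flatnonzero(sig.weights[i] > 0)[0])
        type_of[m] = sig.cell_type_names[j]
    for marker, cell_type in type_of.items():
        col = mat.values[:, mat.marker_index([marker])[0]]
        in_type = assigned & (labels == cell_type).to_numpy()
        out_type = assigned & (labels != cell_type).to_numpy()
        if in_type.sum() == 0:
            warnings.warn(f"no cells assigned to {cell_type!r}; "
                          f"marker {marker!r} skipped", stacklevel=2)
            continue
        if out_type.sum() == 0:
            warnings.warn(f"no background cells for marker {marker!r}; skipped",
                          stacklevel=2)
            continue
        mean_in = col[in_type].mean()
        mean_out = col[out_type].mean()
        ratio = (mean_in + pseudocount) / (mean_out + pseudocount)
        # z-scored intensities can have negative group means; the fold
        # change is undefined there and reported as NaN
        log2fc = float(np.log2(ratio)) if ratio > 0 else float("nan")
        stat = stats.mannwhitneyu(col[in_type], col[out_type],
                                  alternative="greater")
        rows.append({"marker": marker, "cell_type": cell_type,
                     "log2fc": log2fc, "p_value": float(stat.pvalue)})
    if not rows:
        return pd.DataFrame(columns=["marker", "cell_type", "log2fc",
                                     "p_value", "p_adjusted"])
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df
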