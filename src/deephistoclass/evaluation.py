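"""Multilabel performance metrics and per-label threshold selection.

The metric suite is the standard one for multilabel image annotation:
Hamming loss, macro/micro F1, Exact Match ratio and mean Average Precision,
plus per-label confusion counts, accuracy and the Matthews correlation
coefficient (MCC).  Probability thresholds are chosen per label by a grid
search maximizing MCC, which handles the strong class imbalance between
cell types.  ROC/AUC aggregation is deliberately absent: it is not defined
for the multilabel prediction as a whole.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .config import CELL_TYPES
from .errors import ConfigError, DataError


def _check_shapes(Y_true, Y_pred) -> tuple[np.ndarray, np.ndarray]:
    Yt = np.asarray(Y_true)
    Yp = np.asarray(Y_pred)
    if Yt.shape != Yp.shape or Yt.ndim != 2:
        raise ConfigError(
            f"label matrices must share an n x C shape, got {Yt.shape} vs {Yp.shape}")
    return Yt.astype(int), Yp.astype(int)


def hamming_loss(Y_true, Y_pred) -> float:
    """Fraction of label cells that disagree with the truth."""
    Yt, Yp = _check_shapes(Y_true, Y_pred)
    return float(np.mean(Yt != Yp))


def f1_scores(Y_true, Y_pred) -> tuple[float, float]:
    """(macro F1, micro F1); per-label F1 with an empty union counts as 0."""
    Yt, Yp = _check_shapes(Y_true, Y_pred)
    tp = ((Yt == 1) & (Yp == 1)).sum(axis=0).astype(float)
    fp = ((Yt == 0) & (Yp == 1)).sum(axis=0).astype(float)
    fn = ((Yt == 1) & (Yp == 0)).sum(axis=0).astype(float)
    denom = 2 * tp + fp + fn
    per_label = np.divide(2 * tp, denom, out=np.zeros_like(tp), where=denom > 0)
    macro = float(per_label.mean())
    pooled_denom = 2 * tp.sum() + fp.sum() + fn.sum()
    micro = float(2 * tp.sum() / pooled_denom) if pooled_denom > 0 else 0.0
    return macro, micro


def exact_match(Y_true, Y_pred) -> float:
    """Fraction of rows with every label correct (the strictest metric)."""
    Yt, Yp = _check_shapes(Y_true, Y_pred)
    return float(np.mean(np.all(Yt == Yp, axis=1)))


def average_precision(y_true, scores) -> float:
    """All-point average precision of a score-descending ranking.

    Ties are broken by stable original order.  Requires at least one
    positive.
    """
    y = np.asarray(y_true).astype(int).ravel()
    s = np.asarray(scores, dtype=np.float64).ravel()
    if y.sum() == 0:
        raise DataError("average precision is undefined without positives")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    cum_tp = np.cumsum(y_sorted)
    ranks = np.arange(1, len(y) + 1)
    precision_at_pos = (cum_tp / ranks)[y_sorted == 1]
    return float(precision_at_pos.mean())


def mean_average_precision(Y_true, scores) -> float:
    """Unweighted mean AP over labels; positive-free labels are skipped."""
    Yt = np.asarray(Y_true).astype(int)
    S = np.asarray(scores, dtype=np.float64)
    if Yt.shape != S.shape or Yt.ndim != 2:
        raise ConfigError(
            f"truth and scores must share an n x C shape, got {Yt.shape} vs {S.shape}")
    aps = []
    for c in range(Yt.shape[1]):
        if Yt[:, c].sum() == 0:
            warnings.warn(f"label column {c} has no positives; skipped in mAP")
            continue
        aps.append(average_precision(Yt[:, c], S[:, c]))
    if not aps:
        raise DataError("no label with positives; mAP undefined")
    return float(np.mean(aps))


def mcc(tp: float, fp: float, fn: float, tn: float) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    num = tp * tn - fp * fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float(num / np.sqrt(denom))


DEFAULT_MCC_GRID = tuple(np.round(np.arange(0.01, 1.00, 0.01), 2))


@dataclass
class ThresholdSet:
    """Per-label probability thresholds (and optional DHC cutoffs)."""

    cell_types: tuple
    prob_thresholds: np.ndarray
    dhc_cutoffs: np.ndarray | None = None
    mcc_values: np.ndarray | None = None

    def as_frame(self) -> pd.DataFrame:
        d = {"cell_type": list(self.cell_types),
             "prob_threshold": self.prob_thresholds}
        if self.mcc_values is not None:
            d["mcc"] = self.mcc_values
        if self.dhc_cutoffs is not None:
            d["dhc_cutoff"] = self.dhc_cutoffs
        return pd.DataFrame(d)


def grid_search_thresholds(Y_true, scores, grid=DEFAULT_MCC_GRID,
                           cell_types=CELL_TYPES) -> ThresholdSet:
    """Per-label MCC-maximizing probability threshold over a fixed grid.

    Scores >= threshold count as positive.  Ties take the lowest threshold,
    making the search reproducible for a fixed grid.
    """
    Yt = np.asarray(Y_true).astype(int)
    S = np.asarray(scores, dtype=np.float64)
    grid = np.asarray(grid, dtype=np.float64)
    if grid.size == 0 or grid.min() <= 0 or grid.max() >= 1:
        raise ConfigError("threshold grid must be a non-empty subset of (0, 1)")
    if Yt.shape != S.shape:
        raise ConfigError("truth and scores must share a shape")
    C = Yt.shape[1]
    best_thr = np.empty(C)
    best_mcc = np.empty(C)
    for c in range(C):
        y = Yt[:, c]
        # vectorized confusion counts over the whole grid
        pred = S[:, c][None, :] >= grid[:, None]          # G x n
        tp = (pred & (y == 1)).sum(axis=1)
        fp = (pred & (y == 0)).sum(axis=1)
        fn = ((~pred) & (y == 1)).sum(axis=1)
        tn = ((~pred) & (y == 0)).sum(axis=1)
        vals = np.array([mcc(*cnt) for cnt in zip(tp, fp, fn, tn)])
        j = int(np.argmax(vals))                           # first max = lowest thr
        best_thr[c] = grid[j]
        best_mcc[c] = vals[j]
    return ThresholdSet(tuple(cell_types)[:C], best_thr, mcc_values=best_mcc)


@dataclass
class EvaluationReport:
    """Dataset-level multilabel metrics plus per-label confusion summaries."""

    hamming_loss: float
    macro_f1: float
    micro_f1: float
    exact_match: float
    mean_average_precision: float | None
    per_label: pd.DataFrame = field(repr=False)
    n_images: int = 0

    def to_dict(self) -> dict:
        return {
            "n_images": self.n_images,
            "hamming_loss": self.hamming_loss,
            "macro_f1": self.macro_f1,
            "micro_f1": self.micro_f1,
            "exact_match": self.exact_match,
            "mean_average_precision": self.mean_average_precision,
            "per_label": self.per_label.to_dict(orient="records"),
        }

    def summary(self) -> str:
        lines = [
            "Multilabel evaluation",
            "=====================",
            f"images               {self.n_images}",
            f"Hamming loss         {self.hamming_loss:.4f}",
            f"Macro F1             {self.macro_f1:.4f}",
            f"Micro F1             {self.micro_f1:.4f}",
            f"Exact Match ratio    {self.exact_match:.4f}",
        ]
        if self.mean_average_precision is not None:
            lines.append(f"mAP                  {self.mean_average_precision:.4f}")
        lines.append("")
        lines.append(self.per_label.to_string(index=False))
        return "\n".join(lines)

    def confusion_quadrants(self) -> str:
        """Per-label 2x2 confusion blocks (TN FN / FP TP quadrant layout)."""
        blocks = []
        for row in self.per_label.itertuples(index=False):
            blocks.append(
                f"{row.cell_type}\n"
                f"  TN {row.tn:5d}   FN {row.fn:5d}\n"
                f"  FP {row.fp:5d}   TP {row.tp:5d}")
        return "\n".join(blocks)


def evaluate(Y_true, Y_pred, scores=None, cell_types=CELL_TYPES) -> EvaluationReport:
    """Full metric suite; ``scores`` (n x C floats) enables mAP."""
    Yt, Yp = _check_shapes(Y_true, Y_pred)
    n, C = Yt.shape
    macro, micro = f1_scores(Yt, Yp)
    rows = []
    for c in range(C):
        tp = int(((Yt[:, c] == 1) & (Yp[:, c] == 1)).sum())
        fp = int(((Yt[:, c] == 0) & (Yp[:, c] == 1)).sum())
        fn = int(((Yt[:, c] == 1) & (Yp[:, c] == 0)).sum())
        tn = int(((Yt[:, c] == 0) & (Yp[:, c] == 0)).sum())
        rows.append({
            "cell_type": cell_types[c] if c < len(cell_types) else f"label_{c}",
            "tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "accuracy": (tp + tn) / n,
            "mcc": mcc(tp, fp, fn, tn),
        })
    mAP = None
    if scores is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mAP = mean_average_precision(Yt, scores)
    return EvaluationReport(
        hamming_loss=hamming_loss(Yt, Yp),
        macro_f1=macro, micro_f1=micro,
        exact_match=exact_match(Yt, Yp),
        mean_average_precision=mAP,
        per_label=pd.DataFrame(rows),
        n_images=n,
    )


def kendall_label_correlation(intensity_matrix) -> np.ndarray:
    """Pairwise tie-corrected Kendall tau-b between intensity columns.

    Symmetric C x C matrix with unit diagonal; a constant column correlates
    0 with everything (with a warning), since tau is undefined there.
    """
    X = np.asarray(intensity_matrix)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ConfigError(f"need an n x C matrix with n >= 2, got {X.shape}")
    n, C = X.shape
    out = np.eye(C)
    constant = [c for c in range(C) if np.all(X[:, c] == X[0, c])]
    if constant:
        warnings.warn(f"constant intensity column(s) {constant}: "
                      "correlations set to 0")
    for a in range(C):
        for b in range(a + 1, C):
            if a in constant or b in constant:
                tau = 0.0
            else:
                tau = kendalltau(X[:, a], X[:, b]).statistic
                if not np.isfinite(tau):
                    tau = 0.0
            out[a, b] = out[b, a] = tau
    return out


def groupby_accuracy(records: pd.DataFrame, by: str) -> pd.DataFrame:
    """Accuracy of ``call`` vs ``manual_label`` grouped by an annotation field.

    Generic report over the long prediction table (e.g. ``by='intensity'`` or
    ``by='location'`` once those columns are merged in), the mechanism behind
    stratified per-intensity / per-location accuracy tables.
    """
    needed = {"call", "manual_label", by}
    missing = needed - set(records.columns)
    if missing:
        raise ConfigError(f"records missing column(s) {sorted(missing)}")
    df = records.copy()
    df["correct"] = (df["call"].astype(int) ==
                     df["manual_label"].astype(int)).astype(float)
    out = (df.groupby(["cell_type", by], observed=True)["correct"]
             .agg(["mean", "size"]).reset_index()
             .rename(columns={"mean": "accuracy", "size": "n"}))
    return out
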