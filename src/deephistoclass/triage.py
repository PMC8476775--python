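"""DHC-based triage: auto-accept confident predictions, flag the rest.

Predictions are ranked per label by normalized DHC score.  A per-label
cutoff — selected on a validation set, or taken from a named preset —
splits the scored set into retained (auto-labeled) and discarded (manual
review) predictions.  Because misclassified images concentrate at low DHC,
retained accuracy rises with the cutoff at the price of a growing discard
fraction; the accuracy/discard curve makes that trade-off explicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CELL_TYPES, DHC_CUTOFF_PRESETS
from .errors import ConfigError, DataError


def _label_frame(records: pd.DataFrame, label: str) -> pd.DataFrame:
    df = records[records["cell_type"] == label]
    if df.empty:
        raise ConfigError(f"no records scored on label {label!r}")
    return df


def rank_by_dhc(records: pd.DataFrame, label: str,
                column: str = "dhc_normalized") -> list[str]:
    """Image ids in ascending DHC order (ties broken lexicographically)."""
    df = _label_frame(records, label)
    df = df.sort_values([column, "image_id"], kind="stable")
    return df["image_id"].tolist()


def _correct_mask(df: pd.DataFrame) -> np.ndarray:
    manual = df["manual_label"]
    if manual.isna().any() or (manual.astype(str) == "").any():
        raise DataError("triage with accuracy needs manual_label on every record")
    return (df["call"].astype(int) == manual.astype(int)).to_numpy()


def select_cutoff(validation_records: pd.DataFrame, label: str,
                  target_accuracy: float = 0.95,
                  min_retained_fraction: float = 0.5,
                  column: str = "dhc_normalized") -> float:
    """Smallest cutoff whose retained accuracy reaches the target.

    Candidates are the observed scores plus 0.  A cutoff is admissible when
    it retains at least ``min_retained_fraction`` of the validation set; if
    no admissible cutoff reaches ``target_accuracy``, the accuracy-maximizing
    admissible cutoff is returned with a warning.
    """
    if not 0.0 < target_accuracy <= 1.0:
        raise ConfigError(f"target_accuracy must be in (0, 1], got {target_accuracy}")
    df = _label_frame(validation_records, label)
    scores = df[column].to_numpy(dtype=float)
    correct = _correct_mask(df)
    n = len(df)
    candidates = np.unique(np.concatenate([[0.0], scores]))
    best_cut, best_acc = 0.0, -1.0
    for c in candidates:
        keep = scores >= c
        frac = keep.mean()
        if frac < min_retained_fraction or keep.sum() == 0:
            continue
        acc = correct[keep].mean()
        if acc >= target_accuracy:
            return float(c)
        if acc > best_acc:
            best_acc, best_cut = acc, float(c)
    warnings.warn(
        f"{label}: target accuracy {target_accuracy:.3f} unattainable with "
        f">= {min_retained_fraction:.0%} retained; using accuracy-maximizing "
        f"cutoff {best_cut:.4g} (accuracy {max(best_acc, 0):.3f})")
    return best_cut


@dataclass
class TriageResult:
    """Per-label retain/discard split with a tabular summary."""

    cell_types: tuple
    cutoffs: dict
    retained_ids: dict = field(repr=False)
    discarded_ids: dict = field(repr=False)
    retained_accuracy: dict = field(default_factory=dict)
    overall_accuracy: dict = field(default_factory=dict)
    discard_fraction: dict = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for ct in self.cell_types:
            rows.append({
                "cell_type": ct,
                "dhc_cutoff": self.cutoffs[ct],
                "accuracy": self.overall_accuracy.get(ct, np.nan),
                "retained_accuracy": self.retained_accuracy.get(ct, np.nan),
                "discard_fraction": self.discard_fraction[ct],
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.summary_frame().copy()
        df["discard_%"] = 100 * df.pop("discard_fraction")
        return df.to_string(index=False, float_format=lambda v: f"{v:.4g}")


def apply_cutoffs(records: pd.DataFrame, cutoffs,
                  cell_types=CELL_TYPES,
                  column: str = "dhc_normalized") -> TriageResult:
    """Split scored predictions per label at the given DHC cutoffs.

    ``cutoffs`` is a mapping cell_type -> cutoff, a preset name from
    :data:`DHC_CUTOFF_PRESETS`, or a single float for all labels.  Retained
    accuracy is computed when manual labels are present; with everything
    discarded it is reported as NaN (absent).
    """
    if isinstance(cutoffs, str):
        if cutoffs not in DHC_CUTOFF_PRESETS:
            raise ConfigError(f"unknown DHC preset {cutoffs!r}")
        cutoffs = DHC_CUTOFF_PRESETS[cutoffs]
    if np.isscalar(cutoffs):
        cutoffs = {ct: float(cutoffs) for ct in cell_types}
    missing = set(cell_types) - set(cutoffs)
    if missing:
        raise ConfigError(f"no cutoff for label(s) {sorted(missing)}")

    have_truth = ("manual_label" in records.columns and
                  not (records["manual_label"].astype(str) == "").any() and
                  not records["manual_label"].isna().any())
    result = TriageResult(tuple(cell_types), {ct: float(cutoffs[ct]) for ct in cell_types},
                          retained_ids={}, discarded_ids={})
    for ct in cell_types:
        df = _label_frame(records, ct)
        scores = df[column].to_numpy(dtype=float)
        keep = scores >= result.cutoffs[ct]
        result.retained_ids[ct] = df["image_id"][keep].tolist()
        result.discarded_ids[ct] = df["image_id"][~keep].tolist()
        result.discard_fraction[ct] = float((~keep).mean())
        if have_truth:
            correct = _correct_mask(df)
            result.overall_accuracy[ct] = float(correct.mean())
            result.retained_accuracy[ct] = (
                float(correct[keep].mean()) if keep.any() else float("nan"))
    return result


def accuracy_discard_curve(records: pd.DataFrame, label: str,
                           column: str = "dhc_normalized") -> pd.DataFrame:
    """(cutoff, retained_accuracy, discard_fraction) at every distinct score.

    Discard fraction is non-decreasing in the cutoff by construction.
    """
    df = _label_frame(records, label)
    scores = df[column].to_numpy(dtype=float)
    correct = _correct_mask(df)
    n = len(df)
    rows = []
    for c in np.unique(np.concatenate([[0.0], scores])):
        keep = scores >= c
        rows.append({
            "cutoff": float(c),
            "retained_accuracy": float(correct[keep].mean()) if keep.any() else np.nan,
            "discard_fraction": float((~keep).mean()),
            "n_retained": int(keep.sum()),
        })
    return pd.DataFrame(rows)


def confidence_map_data(records: pd.DataFrame, label: str,
                        column: str = "dhc_normalized") -> pd.DataFrame:
    """Per-prediction (rank, dhc, correct) sorted ascending by DHC.

    The tabular form of a confidence map: green/red dot per prediction in
    DHC order, with the cutoff drawn as a vertical line by the plot helper.
    """
    df = _label_frame(records, label).copy()
    df["correct"] = _correct_mask(df)
    df = df.sort_values([column, "image_id"], kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df[["rank", "image_id", column, "correct"]].rename(
        columns={column: "dhc"})


def plot_confidence_maps(records: pd.DataFrame, cutoffs=None,
                         cell_types=CELL_TYPES, path=None):
    """Render per-label confidence maps (green correct / red incorrect dots,
    blue cutoff line); returns the matplotlib figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    C = len(cell_types)
    ncols = 4
    nrows = int(np.ceil(C / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows),
                             squeeze=False)
    for i, ct in enumerate(cell_types):
        ax = axes[i // ncols][i % ncols]
        data = confidence_map_data(records, ct)
        colors = np.where(data["correct"], "green", "red")
        ax.scatter(data["rank"], data["dhc"], c=colors, s=8)
        if cutoffs is not None:
            cut = (DHC_CUTOFF_PRESETS[cutoffs][ct] if isinstance(cutoffs, str)
                   else cutoffs[ct])
            ax.axhline(cut, color="blue", lw=1)
        ax.set_title(ct, fontsize=9)
        ax.set_xlabel("rank (ascending DHC)")
        ax.set_ylabel("DHC (normalized)")
    for j in range(C, nrows * ncols):
        axes[j // ncols][j % ncols].axis("off")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
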