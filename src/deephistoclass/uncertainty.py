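"""Predictive uncertainty: entropies, CPPD and the DHC confidence score.

Given T stochastic forward passes through the drop-weights network, each
label behaves as an independent Bernoulli with Monte-Carlo mean mu.  Per
label we compute

* the predictive mean ``mu`` (the point prediction),
* the plug-in binary entropy ``H(mu)`` in bits (so it lives in [0, 1]),
* the jackknife bias-corrected entropy
  ``H_J = T*H(mu) - (T-1) * mean_i H(mu_{-i})`` over the T leave-one-out
  means (the plug-in estimate is downward-biased at finite T),
* the mutual information ``H(mu) - mean_t H(p_t)`` (epistemic component),
* the jackknife bias-corrected mutual information
  ``MI_J = H_J - mean_t H(p_t)`` (the model-disagreement, i.e. epistemic,
  uncertainty; the per-sample entropy term is unbiased so the jackknife
  acts on the first term only),
* the class predictive probability distance ``CPPD = |2 mu - 1|`` (the gap
  between the two Bernoulli outcome probabilities), and
* the DHC confidence score ``CPPD / max(MI_J, eps)``.

A low DHC flags an uncertain prediction that should go to manual review; a
high DHC marks a prediction whose class-probability margin dwarfs the model
uncertainty.  Raw scores are min-max normalized per label over the scored
batch for reporting and cutoff selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CELL_TYPES
from .errors import ConfigError

#: Denominator floor: jackknife entropies can undershoot to ~0 (or slightly
#: below) near mu in {0, 1}; the floor keeps the ratio finite and matches the
#: smallest published per-cell cutoff scale (1e-10).
DHC_EPSILON = 1e-10
#: Cap keeping reported raw scores finite; ranking treats the cap as top rank.
DHC_CAP = 1e6


@dataclass
class MCPredictionSet:
    """T stochastic forward-pass probability vectors for one image."""

    image_id: str
    samples: np.ndarray  # T x C, entries in [0, 1]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ConfigError(
                f"samples must be a T x C matrix, got shape {self.samples.shape}")
        if self.samples.size and (self.samples.min() < 0 or self.samples.max() > 1):
            raise ConfigError("sample probabilities must lie in [0, 1]")

    @property
    def T(self) -> int:
        return self.samples.shape[0]

    @property
    def n_labels(self) -> int:
        return self.samples.shape[1]


def predictive_mean(samples) -> np.ndarray | float:
    """Arithmetic mean over the MC axis (axis 0 for matrices)."""
    s = np.asarray(samples, dtype=np.float64)
    if s.size == 0:
        raise ConfigError("predictive_mean needs at least one sample")
    return s.mean(axis=0)


def binary_entropy(p) -> np.ndarray | float:
    """Shannon entropy of a Bernoulli(p) in bits: -p log2 p - (1-p) log2(1-p).

    Maximum 1 at p = 0.5; 0 at p in {0, 1} (0 log 0 := 0).
    """
    p = np.asarray(p, dtype=np.float64)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ConfigError("probabilities must lie in [0, 1]")
    out = np.zeros_like(p, dtype=np.float64)
    interior = (p > 0) & (p < 1)
    q = p[interior]
    out[interior] = -q * np.log2(q) - (1 - q) * np.log2(1 - q)
    return out if out.ndim else float(out)


def jackknife_entropy(samples) -> np.ndarray | float:
    """Jackknife bias-corrected plug-in entropy over the MC axis.

    ``H_J = T * H(mu) - (T-1) * mean_i H(mu_{-i})`` where ``mu_{-i}`` is the
    leave-one-out mean.  Vectorized over labels when given a T x C matrix.
    Can be slightly negative near degenerate means (jackknife overshoot).
    """
    s = np.asarray(samples, dtype=np.float64)
    scalar = s.ndim == 1
    s = np.atleast_2d(s.T).T if scalar else s  # keep T on axis 0
    T = s.shape[0]
    if T < 2:
        raise ConfigError(f"jackknife entropy needs T >= 2 samples, got {T}")
    mu = s.mean(axis=0)
    loo = (T * mu[None, :] - s) / (T - 1)          # T x C leave-one-out means
    loo = np.clip(loo, 0.0, 1.0)                   # guard FP round-off
    hj = T * binary_entropy(mu) - (T - 1) * binary_entropy(loo).mean(axis=0)
    return float(hj[0]) if scalar else hj


def mutual_information(samples) -> np.ndarray | float:
    """Epistemic component: H(mean) minus the mean per-pass entropy, >= 0."""
    s = np.asarray(samples, dtype=np.float64)
    scalar = s.ndim == 1
    s = np.atleast_2d(s.T).T if scalar else s
    if s.shape[0] < 2:
        raise ConfigError("mutual information needs T >= 2 samples")
    mi = binary_entropy(s.mean(axis=0)) - binary_entropy(s).mean(axis=0)
    mi = np.maximum(mi, 0.0)
    return float(mi[0]) if scalar else mi


def jackknife_mutual_information(samples) -> np.ndarray | float:
    """Jackknife bias-corrected mutual information over the MC axis.

    The plug-in MI is ``H(mu) - mean_t H(p_t)``; only the first term is a
    nonlinear function of the sample mean and hence biased at finite T, so
    the jackknife correction acts on it alone and the corrected estimator
    collapses to ``jackknife_entropy(samples) - mean_t H(p_t)``.  This is
    the model-disagreement (epistemic) uncertainty that the DHC confidence
    score divides by; unlike the predictive entropy it grows with
    MC-sample dispersion at a fixed predictive mean.  May be slightly
    negative from estimator noise near degenerate means.
    """
    s = np.asarray(samples, dtype=np.float64)
    scalar = s.ndim == 1
    s = np.atleast_2d(s.T).T if scalar else s
    if s.shape[0] < 2:
        raise ConfigError("jackknife mutual information needs T >= 2 samples")
    mij = jackknife_entropy(s) - binary_entropy(s).mean(axis=0)
    return float(np.atleast_1d(mij)[0]) if scalar else mij


def cppd(samples, mode: str = "per_label") -> np.ndarray | float:
    """Class predictive probability distance.

    ``per_label`` (default): each sigmoid label is a Bernoulli whose two
    outcome probabilities are mu and 1-mu, so the best/next-best gap is
    ``|2 mu - 1|``.  ``across_labels``: the gap between the largest and
    second-largest per-label predictive means of the image (single float).
    """
    s = np.asarray(samples, dtype=np.float64)
    scalar = s.ndim == 1
    mu = predictive_mean(s)
    if mode == "per_label":
        out = np.abs(2.0 * np.asarray(mu) - 1.0)
        return float(out) if scalar else out
    if mode == "across_labels":
        mu = np.atleast_1d(mu)
        if mu.size < 2:
            raise ConfigError("across_labels CPPD needs >= 2 labels")
        top2 = np.sort(mu)[-2:]
        return float(top2[1] - top2[0])
    raise ConfigError(f"unknown cppd mode {mode!r}")


def dhc_score(samples, epsilon: float = DHC_EPSILON, cap: float = DHC_CAP,
              mode: str = "per_label"):
    """Raw DHC confidence score: CPPD over bias-corrected model uncertainty.

    ``dhc_raw = cppd / max(MI_J, epsilon)`` (capped), where ``MI_J`` is the
    jackknife bias-corrected mutual information — the disagreement between
    stochastic drop-weights passes.  Returns ``(dhc_raw, components)`` with
    the intermediate quantities (mu, H_plugin, H_jackknife, mi_jackknife,
    mutual_info, cppd).  A ratio near 1 means margin and uncertainty are
    commensurate; near 0 means uncertainty dwarfs the margin (route to
    manual review); large values mean uncertainty is negligible next to the
    margin (auto-accept).
    """
    s = np.asarray(samples, dtype=np.float64)
    mu = predictive_mean(s)
    hj = jackknife_entropy(s)
    mij = jackknife_mutual_information(s)
    c = cppd(s, mode=mode)
    raw = np.minimum(np.asarray(c) / np.maximum(np.asarray(mij), epsilon), cap)
    components = {
        "mu": mu,
        "H_plugin": binary_entropy(mu),
        "H_jackknife": hj,
        "mi_jackknife": mij,
        "mutual_info": mutual_information(s),
        "cppd": c,
    }
    if s.ndim == 1:
        raw = float(raw)
    return raw, components


def normalize_dhc(raw_scores) -> np.ndarray:
    """Min-max rescale raw scores over a scored batch to [0, 1].

    An all-equal batch maps to all ones (every prediction is equally and
    fully concordant with the batch's best).  The map is affine, so rank
    order is preserved.
    """
    x = np.asarray(raw_scores, dtype=np.float64)
    if x.size == 0:
        raise ConfigError("normalize_dhc needs at least one score")
    if not np.all(np.isfinite(x)):
        raise ConfigError("raw DHC scores must be finite (cap before normalizing)")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.ones_like(x)
    return (x - lo) / (hi - lo)


def score_predictions(mc_sets: list[MCPredictionSet],
                      cell_types=CELL_TYPES,
                      prob_thresholds=None,
                      y_true: np.ndarray | None = None,
                      epsilon: float = DHC_EPSILON,
                      cap: float = DHC_CAP) -> pd.DataFrame:
    """Turn MC prediction sets into the long uncertainty table.

    One row per (image, cell type) with mu, entropies, CPPD, raw and
    per-label min-max normalized DHC, the thresholded call, and the manual
    label when ``y_true`` (n x C) is given.  ``prob_thresholds`` is a
    per-label array (default 0.5 everywhere).
    """
    if not mc_sets:
        raise ConfigError("score_predictions needs at least one MCPredictionSet")
    C = len(cell_types)
    thr = np.full(C, 0.5) if prob_thresholds is None else np.asarray(prob_thresholds)
    if thr.shape != (C,):
        raise ConfigError(f"prob_thresholds must have shape ({C},)")
    n = len(mc_sets)
    mus = np.empty((n, C)); hps = np.empty((n, C)); hjs = np.empty((n, C))
    mijs = np.empty((n, C)); mis = np.empty((n, C)); cps = np.empty((n, C))
    raws = np.empty((n, C))
    for i, ms in enumerate(mc_sets):
        if ms.n_labels != C:
            raise ConfigError(
                f"{ms.image_id}: expected {C} labels, got {ms.n_labels}")
        raw, comp = dhc_score(ms.samples, epsilon=epsilon, cap=cap)
        mus[i], hps[i], hjs[i] = comp["mu"], comp["H_plugin"], comp["H_jackknife"]
        mijs[i], mis[i] = comp["mi_jackknife"], comp["mutual_info"]
        cps[i], raws[i] = comp["cppd"], raw
    norm = np.column_stack([normalize_dhc(raws[:, c]) for c in range(C)])
    calls = (mus >= thr[None, :]).astype(int)
    rows = []
    for i, ms in enumerate(mc_sets):
        for c, ct in enumerate(cell_types):
            rows.append({
                "image_id": ms.image_id, "cell_type": ct,
                "mu": mus[i, c], "H_plugin": hps[i, c],
                "H_jackknife": hjs[i, c], "mi_jackknife": mijs[i, c],
                "mutual_info": mis[i, c],
                "cppd": cps[i, c], "dhc_raw": raws[i, c],
                "dhc_normalized": norm[i, c], "call": calls[i, c],
                "manual_label": (int(y_true[i, c]) if y_true is not None else ""),
            })
    return pd.DataFrame(rows)
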