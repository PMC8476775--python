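"""Repeated multilabel-stratified k-fold splitting.

Plain random folds distort rare-label prevalence badly.  Iterative
stratification assigns examples one at a time, always placing an example
carrying the currently rarest label into the fold that most needs that
label, which keeps every fold's per-label prevalence close to the global
one.  Fold capacities are enforced so fold sizes differ by at most one.

When a group column is supplied (e.g. antibody id), whole groups are
assigned to folds so that the 1-3 replicate images of one antibody never
straddle a train/test boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError


@dataclass
class SplitPlan:
    """Fold assignments: ``assignments[rep][fold]`` is a list of indices/ids."""

    n_folds: int
    n_repeats: int
    seed: int
    assignments: list = field(repr=False, default_factory=list)
    ids: list | None = None

    def fold_indices(self, rep: int, fold: int) -> np.ndarray:
        return np.asarray(self.assignments[rep][fold], dtype=int)

    def train_test(self, rep: int, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = self.fold_indices(rep, fold)
        train = np.concatenate([self.fold_indices(rep, f)
                                for f in range(self.n_folds) if f != fold])
        return np.sort(train), np.sort(test)

    def to_frame(self):
        import pandas as pd
        rows = []
        for rep, folds in enumerate(self.assignments):
            for fold, idxs in enumerate(folds):
                for i in idxs:
                    rows.append({
                        "image_id": self.ids[i] if self.ids else i,
                        "repetition": rep, "fold": fold,
                    })
        return pd.DataFrame(rows)


def _iterative_stratify(Y: np.ndarray, n_folds: int,
                        rng: np.random.Generator) -> list[list[int]]:
    """One repetition of iterative stratification.

    Greedy phase: repeatedly take the label with the fewest remaining
    positives and hand its examples to the fold that most needs that label
    (ties: fold with the largest remaining overall desire, then random).
    Rebalance phase: move examples from over-full to under-full folds,
    choosing the example the receiving fold needs most, until fold sizes
    differ by at most one.
    """
    n, C = Y.shape
    label_totals = Y.sum(axis=0).astype(float)
    desired = np.tile(label_totals / n_folds, (n_folds, 1))   # F x C
    desired_total = np.full(n_folds, n / n_folds)

    unassigned = set(range(n))
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    remaining_per_label = Y.sum(axis=0).astype(int)

    def assign(i: int, f: int) -> None:
        folds[f].append(i)
        unassigned.discard(i)
        desired_total[f] -= 1
        pos = np.where(Y[i] == 1)[0]
        desired[f, pos] -= 1
        remaining_per_label[pos] -= 1

    while unassigned:
        active = np.where(remaining_per_label > 0)[0]
        if active.size:
            lbl = active[np.argmin(remaining_per_label[active])]
            pool = [i for i in unassigned if Y[i, lbl] == 1]
            if not pool:
                remaining_per_label[lbl] = 0
                continue
        else:
            lbl = None
            pool = list(unassigned)
        for i in sorted(pool):
            score = desired[:, lbl] if lbl is not None else desired_total
            best = np.where(score == score.max())[0]
            if len(best) > 1:
                tot = desired_total[best]
                best = best[tot == tot.max()]
            f = int(best[rng.integers(len(best))]) if len(best) > 1 \
                else int(best[0])
            assign(i, f)

    # size rebalancing: fold sizes must differ by at most one
    sizes = np.array([len(f) for f in folds])
    while sizes.max() - sizes.min() > 1:
        src = int(np.argmax(sizes))
        dst = int(np.argmin(sizes))
        # move the example with the largest desire differential, so the
        # receiver gains labels it lacks and the source sheds its surplus
        gains = [(float((desired[dst, Y[i] == 1]
                         - desired[src, Y[i] == 1]).sum()), i)
                 for i in folds[src]]
        _, mv = max(gains)
        folds[src].remove(mv)
        folds[dst].append(mv)
        pos = np.where(Y[mv] == 1)[0]
        desired[src, pos] += 1
        desired[dst, pos] -= 1
        sizes[src] -= 1
        sizes[dst] += 1

    _refine_by_swaps(Y, folds)
    return [sorted(f) for f in folds]


def _refine_by_swaps(Y: np.ndarray, folds: list[list[int]],
                     max_swaps: int = 400) -> None:
    """Greedy size-preserving swaps minimizing squared prevalence deviation.

    Repeatedly takes the worst (fold, label) count deviation, pairs the
    fold with the opposite-deviation fold on that label, and performs the
    single swap that most reduces the summed squared deviation from the
    proportional per-fold label targets.  Stops at a local optimum.
    """
    n, C = Y.shape
    k = len(folds)
    label_totals = Y.sum(axis=0).astype(float)
    sizes = np.array([len(f) for f in folds], dtype=float)
    target = sizes[:, None] / n * label_totals[None, :]
    counts = np.stack([Y[f].sum(axis=0) for f in folds]).astype(float)
    for _ in range(max_swaps):
        D = counts - target
        f = int(np.argmax(np.abs(D).max(axis=1)))
        lbl = int(np.argmax(np.abs(D[f])))
        g = int(np.argmin(D[:, lbl])) if D[f, lbl] > 0 else \
            int(np.argmax(D[:, lbl]))
        if f == g:
            break
        src, dst = (f, g) if D[f, lbl] > 0 else (g, f)
        cand_i = [i for i in folds[src] if Y[i, lbl] == 1]
        cand_j = [j for j in folds[dst] if Y[j, lbl] == 0]
        if not cand_i or not cand_j:
            break
        base = float((D[src] ** 2 + D[dst] ** 2).sum())
        Yi = Y[cand_i].astype(float)               # a x C
        Yj = Y[cand_j].astype(float)               # b x C
        # after swapping i<->j: D[src] += Yj_j - Yi_i ; D[dst] += Yi_i - Yj_j
        diff = Yj[None, :, :] - Yi[:, None, :]     # a x b x C
        new_src = D[src][None, None, :] + diff
        new_dst = D[dst][None, None, :] - diff
        obj = (new_src ** 2).sum(axis=2) + (new_dst ** 2).sum(axis=2)
        a, b = np.unravel_index(np.argmin(obj), obj.shape)
        if obj[a, b] < base - 1e-9:
            i, j = cand_i[a], cand_j[b]
            folds[src].remove(i); folds[src].append(j)
            folds[dst].remove(j); folds[dst].append(i)
            counts[src] += Y[j] - Y[i]
            counts[dst] += Y[i] - Y[j]
        else:
            break


def multilabel_stratified_split(Y, n_folds: int = 10, n_repeats: int = 10,
                                seed: int = 0, groups=None,
                                ids=None) -> SplitPlan:
    """Repeated stratified k-fold plan over an n x C binary label matrix.

    With ``groups`` (length-n array of hashables), stratification operates on
    groups — a group counts as positive for a label when any member is — and
    whole groups land in one fold.
    """
    Y = np.asarray(Y).astype(int)
    if Y.ndim != 2:
        raise ConfigError(f"Y must be n x C binary, got shape {Y.shape}")
    n = Y.shape[0]
    if n_folds < 2 or n < n_folds:
        raise ConfigError(f"need n >= n_folds >= 2, got n={n}, n_folds={n_folds}")
    rng = np.random.default_rng(seed)

    if groups is not None:
        groups = np.asarray(groups)
        if groups.shape[0] != n:
            raise ConfigError("groups must have one entry per row of Y")
        uniq, inverse = np.unique(groups, return_inverse=True)
        if len(uniq) < n_folds:
            raise ConfigError(
                f"need at least n_folds={n_folds} groups, got {len(uniq)}")
        Yg = np.zeros((len(uniq), Y.shape[1]), dtype=int)
        np.maximum.at(Yg, inverse, Y)
        members = [np.where(inverse == g)[0].tolist() for g in range(len(uniq))]
    else:
        Yg = Y
        members = None

    assignments = []
    for _ in range(n_repeats):
        g_folds = _iterative_stratify(Yg, n_folds, rng)
        if members is None:
            assignments.append(g_folds)
        else:
            assignments.append([sorted(i for g in fold for i in members[g])
                                for fold in g_folds])
    return SplitPlan(n_folds=n_folds, n_repeats=n_repeats, seed=seed,
                     assignments=assignments,
                     ids=list(ids) if ids is not None else None)


def fold_prevalence_gap(Y, plan: SplitPlan) -> float:
    """Max over folds/labels of |fold prevalence - global prevalence|."""
    Y = np.asarray(Y).astype(int)
    global_prev = Y.mean(axis=0)
    worst = 0.0
    for rep in range(plan.n_repeats):
        for fold in range(plan.n_folds):
            idx = plan.fold_indices(rep, fold)
            gap = np.abs(Y[idx].mean(axis=0) - global_prev).max()
            worst = max(worst, float(gap))
    return worst


def fold_variance_report(metric_per_fold) -> tuple[float, float]:
    """Sample mean and sample standard deviation (n-1) across folds."""
    x = np.asarray(metric_per_fold, dtype=np.float64)
    if x.size < 2:
        raise ConfigError("need at least two fold values")
    return float(x.mean()), float(x.std(ddof=1))
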