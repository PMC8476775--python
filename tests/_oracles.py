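"""Independent brute-force oracles shared by the metric test modules.

Deliberately written as per-cell Python tallies (no vectorization) so they
cannot share a bug with the implementations they check.
"""

import math


def bf_hamming(Yt, Yp):
    n, C = Yt.shape
    return sum(int(Yt[i, c] != Yp[i, c]) for i in range(n)
               for c in range(C)) / (n * C)


def bf_f1(Yt, Yp):
    n, C = Yt.shape
    per = []
    TP = FP = FN = 0
    for c in range(C):
        tp = sum(int(Yt[i, c] == 1 and Yp[i, c] == 1) for i in range(n))
        fp = sum(int(Yt[i, c] == 0 and Yp[i, c] == 1) for i in range(n))
        fn = sum(int(Yt[i, c] == 1 and Yp[i, c] == 0) for i in range(n))
        per.append(2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0)
        TP += tp; FP += fp; FN += fn
    micro = 2 * TP / (2 * TP + FP + FN) if 2 * TP + FP + FN else 0.0
    return sum(per) / C, micro


def bf_exact(Yt, Yp):
    return sum(int(all(Yt[i, c] == Yp[i, c] for c in range(Yt.shape[1])))
               for i in range(Yt.shape[0])) / Yt.shape[0]


def bf_ap(y, s):
    order = sorted(range(len(y)), key=lambda i: (-s[i], i))
    hits = 0
    precisions = []
    for rank, i in enumerate(order, start=1):
        if y[i] == 1:
            hits += 1
            precisions.append(hits / rank)
    return sum(precisions) / len(precisions)


def bf_mcc(tp, fp, fn, tn):
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def bf_jackknife_entropy(samples):
    s = list(samples)
    T = len(s)
    H = lambda p: 0.0 if p in (0.0, 1.0) else \
        -p * math.log2(p) - (1 - p) * math.log2(1 - p)
    mu = sum(s) / T
    loo = [H((sum(s) - x) / (T - 1)) for x in s]
    return T * H(mu) - (T - 1) * sum(loo) / T
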