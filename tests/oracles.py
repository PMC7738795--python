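"""Independent brute-force reference implementations.

Pure-Python, loop-based re-derivations of the selection operations, kept
deliberately free of the package's vectorized code paths so they can serve
as oracles in equivalence tests.
"""

import math


def brute_predicted_counts(P):
    C = len(P[0])
    counts = [0] * C
    for row in P:
        best = max(row)
        counts[row.index(best) if isinstance(row, list) else int(_first_argmax(row))] += 1
    return counts


def _first_argmax(row):
    best, best_i = -math.inf, 0
    for i, v in enumerate(row):
        if v > best:
            best, best_i = v, i
    return best_i


def brute_thresholds(P, p):
    """Per-class thresholds by explicit sort; NaN for empty classes."""
    C = len(P[0])
    groups = {c: [] for c in range(C)}
    for row in P:
        groups[_first_argmax(row)].append(row[_first_argmax(row)])
    thresholds = []
    for c in range(C):
        vals = sorted(groups[c], reverse=True)
        if not vals:
            thresholds.append(math.nan)
        else:
            rank = math.ceil(p * len(vals))
            thresholds.append(vals[rank - 1])
    return thresholds


def brute_class_balanced(P, thresholds, eps=1e-12):
    """Sample-by-sample exhaustive ratio comparison; -1 means IGNORED."""
    labels = []
    for row in P:
        best_c, best_r = None, -math.inf
        for c, (pv, t) in enumerate(zip(row, thresholds)):
            if math.isnan(t):
                continue
            r = pv / t
            if r > best_r:  # strict keeps the lowest class index on ties
                best_r, best_c = r, c
        if best_c is not None and best_r >= 1 - eps:
            labels.append(best_c)
        else:
            labels.append(-1)
    return labels


def brute_vanilla(P, k):
    """Global cutoff exp(-k), strict comparison, argmax ties to lowest index."""
    cutoff = math.exp(-k)
    labels = []
    for row in P:
        c = _first_argmax(row)
        labels.append(c if row[c] > cutoff else -1)
    return labels
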