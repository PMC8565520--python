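"""Independent brute-force references used to validate the fast implementations.

These are deliberately written with plain loops and their own arithmetic so
they share no code path with the package.
"""

import math

import numpy as np


def mann_whitney_auc(values, labels, positive) -> float:
    """AUC as the exhaustive pairwise-comparison probability (ties count 1/2)."""
    pos = [v for v, l in zip(values, labels) if l == positive]
    neg = [v for v, l in zip(values, labels) if l != positive]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def _discretize3(column):
    x = list(column)
    lo, hi = np.quantile(x, [1.0 / 3.0, 2.0 / 3.0])
    codes = []
    for v in x:
        if v <= lo:
            codes.append(0)
        elif v <= hi:
            codes.append(1)
        else:
            codes.append(2)
    return codes


def _mi_loops(a, b) -> float:
    n = len(a)
    counts = {}
    ca, cb = {}, {}
    for x, y in zip(a, b):
        counts[(x, y)] = counts.get((x, y), 0) + 1
        ca[x] = ca.get(x, 0) + 1
        cb[y] = cb.get(y, 0) + 1
    mi = 0.0
    for (x, y), c in counts.items():
        pxy = c / n
        mi += pxy * math.log(pxy / (ca[x] / n * cb[y] / n))
    return mi


def mrmr_greedy(table, labels, k, criterion="MID"):
    """Reference greedy MRMR on a pandas DataFrame of feature columns."""
    cols = list(table.columns)
    codes = {c: _discretize3(table[c].to_numpy()) for c in cols}
    uniq = sorted(set(labels))
    y = [uniq.index(l) for l in labels]
    relevance = {c: _mi_loops(codes[c], y) for c in cols}
    selected = []
    while len(selected) < k:
        best, best_score = None, None
        for c in cols:
            if c in selected:
                continue
            if not selected:
                score = relevance[c]
            else:
                red = sum(_mi_loops(codes[c], codes[s]) for s in selected) / len(selected)
                if criterion == "MID":
                    score = relevance[c] - red
                else:
                    score = relevance[c] / max(red, 1e-12)
            # earliest column wins ties (same 1e-10 tolerance as the package)
            if best_score is None or score > best_score + 1e-10:
                best, best_score = c, score
        selected.append(best)
    return selected
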