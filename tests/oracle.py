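"""Brute-force reference implementations for tiny problems.

Everything here is written by direct enumeration with no shared code with
the package internals: exhaustive scans over all feature/threshold pairs,
recursive tree growth on explicit index lists, and importance recomputed by
walking the resulting node dictionaries.  Only meant for n <= ~50.
"""

from __future__ import annotations

import numpy as np


def sse(y):
    y = np.asarray(y, dtype=float)
    return float(((y - y.mean()) ** 2).sum())


def enumerate_splits(x):
    """All candidate midpoint thresholds for one feature column."""
    uniq = np.unique(np.asarray(x, dtype=float))
    return [(uniq[i] + uniq[i + 1]) / 2.0 for i in range(len(uniq) - 1)]


def best_split(X, y, idx, min_leaf, n_total):
    """Exhaustive best primary split on the samples in idx.

    Returns (feature, threshold, risk_reduction) or None.  Ties break to the
    lowest feature index, then the lowest threshold (strict > comparisons
    while scanning in ascending order).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    idx = np.asarray(idx, dtype=int)
    parent = sse(y[idx])
    # improvements below tie_tol count as ties -> keep the earlier candidate
    tie_tol = 1e-12 * parent / n_total
    best = None
    best_red = 0.0
    for f in range(X.shape[1]):
        for thr in enumerate_splits(X[idx, f]):
            left = idx[X[idx, f] < thr]
            right = idx[X[idx, f] >= thr]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            red = (parent - sse(y[left]) - sse(y[right])) / n_total
            if red > best_red + tie_tol:
                best_red = red
                best = (f, thr, red)
    return best


def best_surrogates(X, y, idx, primary_feature, primary_threshold, max_surr, n_total):
    """Exhaustive surrogate search mimicking the primary partition."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    idx = np.asarray(idx, dtype=int)
    nn = len(idx)
    go_left = X[idx, primary_feature] < primary_threshold
    p_min = min(go_left.sum(), nn - go_left.sum()) / nn
    parent = sse(y[idx])
    found = []
    for f in range(X.shape[1]):
        if f == primary_feature:
            continue
        best = None  # (agree, -thr) maximized => scan ascending, strict >
        for thr in enumerate_splits(X[idx, f]):
            s_left = X[idx, f] < thr
            agree = int((s_left == go_left).sum())
            if best is None or agree > best[0]:
                best = (agree, thr, s_left)
        if best is None:
            continue
        agree, thr, s_left = best
        lam = (p_min - (1 - agree / nn)) / p_min
        if lam <= 0:
            continue
        red = (parent - sse(y[idx[s_left]]) - sse(y[idx[~s_left]])) / n_total
        found.append({"feature": f, "threshold": thr, "lambda": lam, "rr": red})
    found.sort(key=lambda s: (-s["lambda"], s["feature"]))
    return found[:max_surr]


def grow(X, y, min_leaf=1, max_surr=10):
    """Exhaustive recursive tree; returns nested node dicts."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n_total = len(y)

    def build(idx):
        idx = np.asarray(idx, dtype=int)
        node = {
            "idx": idx,
            "n": len(idx),
            "prediction": float(y[idx].mean()),
            "sse": sse(y[idx]),
            "risk": sse(y[idx]) / n_total,
        }
        if len(idx) < 2 * min_leaf or node["sse"] <= 1e-12 * len(idx):
            return node
        split = best_split(X, y, idx, min_leaf, n_total)
        if split is None:
            return node
        f, thr, red = split
        node["split"] = {"feature": f, "threshold": thr, "rr": red}
        node["surrogates"] = best_surrogates(X, y, idx, f, thr, max_surr, n_total)
        node["left"] = build(idx[X[idx, f] < thr])
        node["right"] = build(idx[X[idx, f] >= thr])
        return node

    return build(np.arange(n_total))


def walk(node):
    yield node
    if "split" in node:
        yield from walk(node["left"])
        yield from walk(node["right"])


def importance(root, p):
    """Per-feature summed risk reductions / branch count, from node dicts."""
    imp = np.zeros(p)
    n_branch = 0
    for node in walk(root):
        if "split" in node:
            n_branch += 1
            imp[node["split"]["feature"]] += node["split"]["rr"]
            for s in node["surrogates"]:
                imp[s["feature"]] += s["rr"]
    return imp / n_branch if n_branch else imp


def predict(root, X):
    X = np.asarray(X, dtype=float)
    out = np.empty(len(X))
    for i, row in enumerate(X):
        node = root
        while "split" in node:
            if row[node["split"]["feature"]] < node["split"]["threshold"]:
                node = node["left"]
            else:
                node = node["right"]
        out[i] = node["prediction"]
    return out
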