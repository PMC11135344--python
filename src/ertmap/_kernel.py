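"""Numba kernels for growing surrogate-split regression trees.

The tree representation is flat: parallel arrays indexed by node id, plus a
flat surrogate-split table tagged with node ids.  All randomness inside the
kernel comes from ``np.random.seed`` with a caller-supplied 31-bit seed, so a
tree is a pure function of ``(X, y, params, seed)``.

Split search uses the presort strategy: every feature column is argsorted
once at the root, and the per-feature sorted orders are maintained through
stable partitions as the tree grows, so each node's split and surrogate scans
are linear in the node size.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LEAF = -1


@njit(cache=True)
def _grow(X, y, min_leaf, mtry, max_surr, seed):
    """Grow one regression tree; returns flat node and surrogate arrays.

    Split quality is the reduction in node risk (probability-weighted MSE,
    probabilities relative to this training set), i.e. delta-SSE / n_total.
    Candidate thresholds are midpoints of adjacent distinct sorted values.
    Ties break toward the lowest feature index, then the lowest threshold.
    """
    n, p = X.shape
    np.random.seed(seed)

    max_nodes = 2 * n + 1
    node_left = np.full(max_nodes, -1, np.int64)
    node_right = np.full(max_nodes, -1, np.int64)
    node_feature = np.full(max_nodes, LEAF, np.int64)
    node_threshold = np.zeros(max_nodes, np.float64)
    node_n = np.zeros(max_nodes, np.int64)
    node_pred = np.zeros(max_nodes, np.float64)
    node_sse = np.zeros(max_nodes, np.float64)
    node_rr = np.zeros(max_nodes, np.float64)  # primary risk reduction

    surr_per_node = min(max_surr, p - 1) if p > 1 else 0
    surr_cap = max(1, (n + 1) * max(surr_per_node, 0))
    surr_node = np.empty(surr_cap, np.int64)
    surr_feat = np.empty(surr_cap, np.int64)
    surr_thr = np.empty(surr_cap, np.float64)
    surr_lam = np.empty(surr_cap, np.float64)
    surr_rr = np.empty(surr_cap, np.float64)
    n_surr = 0

    # per-feature sample ids in feature-sorted order, maintained per node
    order = np.empty((p, n), np.int64)
    for f in range(p):
        order[f, :] = np.argsort(X[:, f], kind="mergesort")
    tmp = np.empty(n, np.int64)
    goes_left = np.zeros(n, np.uint8)

    feat_pool = np.arange(p)
    cand = np.empty(p, np.int64)
    cf = np.empty(p, np.int64)
    ct = np.empty(p, np.float64)
    cl = np.empty(p, np.float64)
    cr = np.empty(p, np.float64)

    stack = np.empty((max_nodes, 3), np.int64)
    stack[0, 0] = 0
    stack[0, 1] = 0
    stack[0, 2] = n
    top = 1
    n_nodes = 1

    while top > 0:
        top -= 1
        node = stack[top, 0]
        start = stack[top, 1]
        end = stack[top, 2]
        nn = end - start

        s = 0.0
        for i in range(start, end):
            s += y[order[0, i]]
        mean = s / nn
        sse = 0.0
        for i in range(start, end):
            d = y[order[0, i]] - mean
            sse += d * d
        node_n[node] = nn
        node_pred[node] = mean
        node_sse[node] = sse

        if nn < 2 * min_leaf or sse <= 1e-12 * nn:
            continue

        # draw the mtry candidate features (without replacement), sorted
        m = mtry if mtry < p else p
        if m < p:
            for j in range(m):
                k = j + np.random.randint(p - j)
                t = feat_pool[j]
                feat_pool[j] = feat_pool[k]
                feat_pool[k] = t
            for j in range(m):
                cand[j] = feat_pool[j]
            for a in range(1, m):  # insertion sort: lowest-index tie-break
                v = cand[a]
                b = a - 1
                while b >= 0 and cand[b] > v:
                    cand[b + 1] = cand[b]
                    b -= 1
                cand[b + 1] = v
        else:
            for j in range(p):
                cand[j] = j

        syt = 0.0
        syt2 = 0.0
        for i in range(start, end):
            d = y[order[0, i]] - mean
            syt += d
            syt2 += d * d

        # improvements below tie_tol are ties -> keep the earlier candidate
        # (lowest feature index, then lowest threshold)
        tie_tol = 1e-12 * sse
        best_red = 0.0
        best_feat = -1
        best_thr = 0.0
        for j in range(m):
            f = cand[j]
            of = order[f]
            syl = 0.0
            syl2 = 0.0
            for i in range(nn - 1):
                sid = of[start + i]
                v = y[sid] - mean
                syl += v
                syl2 += v * v
                nl = i + 1
                nr = nn - nl
                if nl < min_leaf or nr < min_leaf:
                    continue
                lo = X[sid, f]
                hi = X[of[start + i + 1], f]
                if hi <= lo:
                    continue
                syr = syt - syl
                syr2 = syt2 - syl2
                red = sse - (syl2 - syl * syl / nl) - (syr2 - syr * syr / nr)
                if red > best_red + tie_tol:
                    best_red = red
                    best_feat = f
                    best_thr = 0.5 * (lo + hi)

        if best_feat < 0 or best_red <= 0.0:
            continue

        node_feature[node] = best_feat
        node_threshold[node] = best_thr
        node_rr[node] = best_red / n  # risk units

        nl_tot = 0
        for i in range(start, end):
            sid = order[0, i]
            if X[sid, best_feat] < best_thr:
                goes_left[sid] = 1
                nl_tot += 1
            else:
                goes_left[sid] = 0
        nr_tot = nn - nl_tot
        p_min = min(nl_tot, nr_tot) / nn

        # surrogate search over every other feature
        if surr_per_node > 0:
            ncand = 0
            for f in range(p):
                if f == best_feat:
                    continue
                of = order[f]
                cum_l = 0
                syl = 0.0
                syl2 = 0.0
                best_agree = -1
                best_pos = -1
                bsyl = 0.0
                bsyl2 = 0.0
                bthr = 0.0
                for i in range(nn - 1):
                    sid = of[start + i]
                    if goes_left[sid] == 1:
                        cum_l += 1
                    v = y[sid] - mean
                    syl += v
                    syl2 += v * v
                    lo = X[sid, f]
                    hi = X[of[start + i + 1], f]
                    if hi <= lo:
                        continue
                    # rows at sorted positions <= i go left under the surrogate
                    agree = cum_l + (nr_tot - (i + 1 - cum_l))
                    if agree > best_agree:
                        best_agree = agree
                        best_pos = i
                        bsyl = syl
                        bsyl2 = syl2
                        bthr = 0.5 * (lo + hi)
                if best_pos < 0:
                    continue
                p_agree = best_agree / nn
                lam = (p_min - (1.0 - p_agree)) / p_min
                if lam <= 0.0:
                    continue
                # risk reduction of the surrogate's own partition
                nl = best_pos + 1
                nr = nn - nl
                syr = syt - bsyl
                syr2 = syt2 - bsyl2
                red = sse - (bsyl2 - bsyl * bsyl / nl) - (syr2 - syr * syr / nr)
                cf[ncand] = f
                ct[ncand] = bthr
                cl[ncand] = lam
                cr[ncand] = red / n
                ncand += 1

            # keep the top max_surr by lambda (desc), feature index asc on ties
            keep = max_surr if max_surr < ncand else ncand
            for a in range(keep):
                bi = a
                for b in range(a + 1, ncand):
                    if cl[b] > cl[bi] or (cl[b] == cl[bi] and cf[b] < cf[bi]):
                        bi = b
                if bi != a:
                    cf[a], cf[bi] = cf[bi], cf[a]
                    ct[a], ct[bi] = ct[bi], ct[a]
                    cl[a], cl[bi] = cl[bi], cl[a]
                    cr[a], cr[bi] = cr[bi], cr[a]
                surr_node[n_surr] = node
                surr_feat[n_surr] = cf[a]
                surr_thr[n_surr] = ct[a]
                surr_lam[n_surr] = cl[a]
                surr_rr[n_surr] = cr[a]
                n_surr += 1

        # stable partition of every feature's sorted order
        for f in range(p):
            of = order[f]
            a = 0
            b = 0
            for i in range(start, end):
                sid = of[i]
                if goes_left[sid] == 1:
                    tmp[a] = sid
                    a += 1
                else:
                    tmp[nl_tot + b] = sid
                    b += 1
            for i in range(nn):
                of[start + i] = tmp[i]

        lid = n_nodes
        rid = n_nodes + 1
        n_nodes += 2
        node_left[node] = lid
        node_right[node] = rid
        stack[top, 0] = lid
        stack[top, 1] = start
        stack[top, 2] = start + nl_tot
        top += 1
        stack[top, 0] = rid
        stack[top, 1] = start + nl_tot
        stack[top, 2] = end
        top += 1

    return (
        node_left[:n_nodes].copy(),
        node_right[:n_nodes].copy(),
        node_feature[:n_nodes].copy(),
        node_threshold[:n_nodes].copy(),
        node_n[:n_nodes].copy(),
        node_pred[:n_nodes].copy(),
        node_sse[:n_nodes].copy(),
        node_rr[:n_nodes].copy(),
        surr_node[:n_surr].copy(),
        surr_feat[:n_surr].copy(),
        surr_thr[:n_surr].copy(),
        surr_lam[:n_surr].copy(),
        surr_rr[:n_surr].copy(),
    )


@njit(cache=True)
def _predict(node_left, node_right, node_feature, node_threshold, node_pred, X):
    n = X.shape[0]
    out = np.empty(n, np.float64)
    for i in range(n):
        node = 0
        while node_feature[node] >= 0:
            if X[i, node_feature[node]] < node_threshold[node]:
                node = node_left[node]
            else:
                node = node_right[node]
        out[i] = node_pred[node]
    return out


@njit(cache=True)
def _importance(node_feature, node_rr, surr_feat, surr_rr, p):
    imp = np.zeros(p, np.float64)
    n_branch = 0
    for i in range(node_feature.shape[0]):
        if node_feature[i] >= 0:
            n_branch += 1
            imp[node_feature[i]] += node_rr[i]
    for i in range(surr_feat.shape[0]):
        imp[surr_feat[i]] += surr_rr[i]
    if n_branch > 0:
        imp /= n_branch
    return imp, n_branch
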