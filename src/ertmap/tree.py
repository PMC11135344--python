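"""Surrogate-split regression trees with node-risk importance.

A tree is grown by greedy recursive partitioning.  At each node an
``mtry``-subset of features is scanned; the split maximizing the reduction in
node risk is kept, where node risk is the node's mean squared error weighted
by the fraction of training samples it holds.  After the primary split is
chosen, up to ``max_surrogates`` surrogate splits on other features are
attached: each is the threshold that best mimics the primary left/right
partition, kept only if its predictive measure of association is positive.

Per-feature importance sums the risk reductions of every split on that
feature — primary and surrogate — over all branch nodes, divided by the
number of branch nodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from . import _kernel

__all__ = [
    "Split",
    "TreeNode",
    "TreeParams",
    "RegressionTree",
    "fit_tree",
    "predict_tree",
    "predictor_importance",
    "find_surrogates",
]


@dataclass(frozen=True)
class Split:
    """One split (primary or surrogate); rows with value < threshold go left."""

    feature_index: int
    threshold: float
    risk_reduction: float
    kind: Literal["primary", "surrogate"]
    association: float | None = None  # lambda, surrogates only

    def __post_init__(self) -> None:
        if self.risk_reduction < 0:
            raise ValueError("risk_reduction must be >= 0")
        if self.kind == "surrogate" and not (self.association or 0) > 0:
            raise ValueError("surrogate splits require association > 0")


@dataclass(frozen=True)
class TreeNode:
    """Read-only view of one node of a fitted tree."""

    node_id: int
    n_samples: int
    probability: float
    mse: float
    risk: float
    prediction: float
    primary_split: Split | None
    surrogates: tuple[Split, ...]
    children: tuple[int, int] | None

    @property
    def is_leaf(self) -> bool:
        return self.primary_split is None


@dataclass(frozen=True)
class TreeParams:
    min_leaf: int = 5
    max_surrogates: int = 10
    mtry: int | Literal["all"] = "all"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if self.max_surrogates < 0:
            raise ValueError("max_surrogates must be >= 0")
        if self.mtry != "all" and self.mtry < 1:
            raise ValueError("mtry must be >= 1 or 'all'")


@dataclass
class RegressionTree:
    """Fitted tree in flat-array form (node id 0 is the root)."""

    feature_count: int
    n_samples: int
    params: TreeParams
    node_left: np.ndarray
    node_right: np.ndarray
    node_feature: np.ndarray  # -1 for leaves
    node_threshold: np.ndarray
    node_n: np.ndarray
    node_pred: np.ndarray
    node_sse: np.ndarray
    node_rr: np.ndarray  # primary-split risk reduction per node
    surr_node: np.ndarray
    surr_feat: np.ndarray
    surr_thr: np.ndarray
    surr_lam: np.ndarray
    surr_rr: np.ndarray
    _surr_index: dict[int, list[int]] | None = field(default=None, repr=False)

    @property
    def _surr_by_node(self) -> dict[int, list[int]]:
        # built lazily: only node inspection needs it, not fitting/predicting
        if self._surr_index is None:
            by_node: dict[int, list[int]] = {}
            for k, nid in enumerate(self.surr_node):
                by_node.setdefault(int(nid), []).append(k)
            self._surr_index = by_node
        return self._surr_index

    @property
    def n_nodes(self) -> int:
        return len(self.node_feature)

    @property
    def n_branch_nodes(self) -> int:
        return int((self.node_feature >= 0).sum())

    @property
    def leaf_ids(self) -> np.ndarray:
        return np.flatnonzero(self.node_feature < 0)

    @property
    def branch_ids(self) -> np.ndarray:
        return np.flatnonzero(self.node_feature >= 0)

    def node(self, node_id: int) -> TreeNode:
        nid = int(node_id)
        nn = int(self.node_n[nid])
        mse = float(self.node_sse[nid]) / nn
        primary = None
        children = None
        surrogates: tuple[Split, ...] = ()
        if self.node_feature[nid] >= 0:
            primary = Split(
                feature_index=int(self.node_feature[nid]),
                threshold=float(self.node_threshold[nid]),
                risk_reduction=float(self.node_rr[nid]),
                kind="primary",
            )
            children = (int(self.node_left[nid]), int(self.node_right[nid]))
            surrogates = tuple(
                Split(
                    feature_index=int(self.surr_feat[k]),
                    threshold=float(self.surr_thr[k]),
                    risk_reduction=float(self.surr_rr[k]),
                    kind="surrogate",
                    association=float(self.surr_lam[k]),
                )
                for k in self._surr_by_node.get(nid, [])
            )
        return TreeNode(
            node_id=nid,
            n_samples=nn,
            probability=nn / self.n_samples,
            mse=mse,
            risk=float(self.node_sse[nid]) / self.n_samples,
            prediction=float(self.node_pred[nid]),
            primary_split=primary,
            surrogates=surrogates,
            children=children,
        )

    def nodes(self) -> list[TreeNode]:
        return [self.node(i) for i in range(self.n_nodes)]

    def assign_samples(self, X: np.ndarray) -> dict[int, np.ndarray]:
        """Route rows of X through primary splits; per-node row-index sets."""
        X = np.asarray(X, dtype=float)
        members: dict[int, list[int]] = {i: [] for i in range(self.n_nodes)}
        for i, row in enumerate(X):
            nid = 0
            members[0].append(i)
            while self.node_feature[nid] >= 0:
                if row[self.node_feature[nid]] < self.node_threshold[nid]:
                    nid = int(self.node_left[nid])
                else:
                    nid = int(self.node_right[nid])
                members[nid].append(i)
        return {k: np.asarray(v, dtype=int) for k, v in members.items()}

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        nodes = []
        for i in range(self.n_nodes):
            node = {
                "id": i,
                "n": int(self.node_n[i]),
                "prediction": float(self.node_pred[i]),
                "sse": float(self.node_sse[i]),
            }
            if self.node_feature[i] >= 0:
                node["split"] = {
                    "feature": int(self.node_feature[i]),
                    "threshold": float(self.node_threshold[i]),
                    "risk_reduction": float(self.node_rr[i]),
                }
                node["children"] = [int(self.node_left[i]), int(self.node_right[i])]
                node["surrogates"] = [
                    {
                        "feature": int(self.surr_feat[k]),
                        "threshold": float(self.surr_thr[k]),
                        "association": float(self.surr_lam[k]),
                        "risk_reduction": float(self.surr_rr[k]),
                    }
                    for k in self._surr_by_node.get(i, [])
                ]
            nodes.append(node)
        return {
            "feature_count": self.feature_count,
            "n_samples": self.n_samples,
            "params": {
                "min_leaf": self.params.min_leaf,
                "max_surrogates": self.params.max_surrogates,
                "mtry": self.params.mtry,
                "rng_seed": self.params.rng_seed,
            },
            "nodes": nodes,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RegressionTree":
        nodes = payload["nodes"]
        n = len(nodes)
        left = np.full(n, -1, dtype=np.int64)
        right = np.full(n, -1, dtype=np.int64)
        feat = np.full(n, -1, dtype=np.int64)
        thr = np.zeros(n)
        nn = np.zeros(n, dtype=np.int64)
        pred = np.zeros(n)
        sse = np.zeros(n)
        rr = np.zeros(n)
        s_node, s_feat, s_thr, s_lam, s_rr = [], [], [], [], []
        for node in nodes:
            i = node["id"]
            nn[i] = node["n"]
            pred[i] = node["prediction"]
            sse[i] = node["sse"]
            if "split" in node:
                feat[i] = node["split"]["feature"]
                thr[i] = node["split"]["threshold"]
                rr[i] = node["split"]["risk_reduction"]
                left[i], right[i] = node["children"]
                for s in node.get("surrogates", []):
                    s_node.append(i)
                    s_feat.append(s["feature"])
                    s_thr.append(s["threshold"])
                    s_lam.append(s["association"])
                    s_rr.append(s["risk_reduction"])
        params = payload["params"]
        return cls(
            feature_count=payload["feature_count"],
            n_samples=payload["n_samples"],
            params=TreeParams(**params),
            node_left=left,
            node_right=right,
            node_feature=feat,
            node_threshold=thr,
            node_n=nn,
            node_pred=pred,
            node_sse=sse,
            node_rr=rr,
            surr_node=np.asarray(s_node, dtype=np.int64),
            surr_feat=np.asarray(s_feat, dtype=np.int64),
            surr_thr=np.asarray(s_thr, dtype=float),
            surr_lam=np.asarray(s_lam, dtype=float),
            surr_rr=np.asarray(s_rr, dtype=float),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "RegressionTree":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_tree(X: np.ndarray, y: np.ndarray, params: TreeParams | None = None) -> RegressionTree:
    """Grow one surrogate-split regression tree on (X, y)."""
    params = params or TreeParams()
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if len(y) != X.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {len(y)} values")
    if len(y) < 1:
        raise ValueError("need at least one sample")
    n, p = X.shape
    mtry = p if params.mtry == "all" else min(int(params.mtry), p)
    out = _kernel._grow(
        X,
        y,
        params.min_leaf,
        mtry,
        params.max_surrogates,
        int(params.rng_seed) & 0x7FFFFFFF,
    )
    return RegressionTree(p, n, params, *out)


def predict_tree(tree: RegressionTree, X: np.ndarray) -> np.ndarray:
    """Route each row to a leaf by the primary splits; return leaf means."""
    X = np.ascontiguousarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != tree.feature_count:
        raise ValueError(
            f"X must have {tree.feature_count} columns, got shape {X.shape}"
        )
    return _kernel._predict(
        tree.node_left,
        tree.node_right,
        tree.node_feature,
        tree.node_threshold,
        tree.node_pred,
        X,
    )


def predictor_importance(tree: RegressionTree) -> np.ndarray:
    """Summed risk reductions per feature (primary + surrogate splits),
    divided by the number of branch nodes; zero vector for a pure leaf."""
    imp, _ = _kernel._importance(
        tree.node_feature,
        tree.node_rr,
        tree.surr_feat,
        tree.surr_rr,
        tree.feature_count,
    )
    return imp


def find_surrogates(
    node: TreeNode,
    X: np.ndarray,
    y: np.ndarray,
    sample_indices: np.ndarray,
    params: TreeParams | None = None,
) -> list[Split]:
    """Reference surrogate search for one branch node (pure Python).

    For every feature other than the primary one, finds the threshold that
    best mimics the primary split's left/right partition of the node's
    samples, computes the predictive measure of association

        lambda = (min(pL, pR) - (1 - p_agree)) / min(pL, pR),

    and keeps surrogates with lambda > 0, ordered by descending lambda
    (ties: lowest feature index), truncated to ``max_surrogates``.  Each
    surrogate's risk reduction is the reduction its own partition achieves on
    the node's y.  ``fit_tree`` computes the same quantity in compiled code;
    this routine exists for inspection and cross-checking.
    """
    if node.primary_split is None:
        raise ValueError("node has no primary split")
    params = params or TreeParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    idx = np.asarray(sample_indices, dtype=int)
    nn = len(idx)
    n_total = len(y)
    prim = node.primary_split
    go_left = X[idx, prim.feature_index] < prim.threshold
    n_left = int(go_left.sum())
    n_right = nn - n_left
    p_min = min(n_left, n_right) / nn
    yc = y[idx] - y[idx].mean()
    sse = float(yc @ yc)

    results: list[Split] = []
    for f in range(X.shape[1]):
        if f == prim.feature_index:
            continue
        vals = X[idx, f]
        order = np.argsort(vals, kind="mergesort")
        sv = vals[order]
        sl = go_left[order]
        best_agree, best_pos = -1, -1
        cum_l = 0
        for i in range(nn - 1):
            cum_l += int(sl[i])
            if sv[i + 1] <= sv[i]:
                continue
            agree = cum_l + (n_right - (i + 1 - cum_l))
            if agree > best_agree:
                best_agree, best_pos = agree, i
        if best_pos < 0:
            continue
        lam = (p_min - (1.0 - best_agree / nn)) / p_min
        if lam <= 0:
            continue
        yl = yc[order[: best_pos + 1]]
        yr = yc[order[best_pos + 1 :]]
        red = (
            sse
            - (yl @ yl - yl.sum() ** 2 / len(yl))
            - (yr @ yr - yr.sum() ** 2 / len(yr))
        )
        results.append(
            Split(
                feature_index=f,
                threshold=0.5 * (sv[best_pos] + sv[best_pos + 1]),
                risk_reduction=max(red, 0.0) / n_total,
                kind="surrogate",
                association=lam,
            )
        )
    results.sort(key=lambda s: (-s.association, s.feature_index))
    return results[: params.max_surrogates]
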