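"""Bagged / random-forest ensembles of surrogate-split regression trees.

Each of ``n_learners`` trees (default 50) is fitted on an independent
bootstrap resample of the training rows; with ``mtry_fraction < 1`` each
node additionally draws a random feature subset, giving random-forest
behaviour, while ``mtry_fraction = 1`` reproduces pure bagging.  Predictions
and predictor importances are unweighted means over the trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tree import RegressionTree, TreeParams, fit_tree, predict_tree, predictor_importance

__all__ = ["EnsembleConfig", "Ensemble", "fit_ensemble", "predict_ensemble", "ensemble_importance"]


@dataclass(frozen=True)
class EnsembleConfig:
    n_learners: int = 50
    bootstrap: bool = True
    #: Fraction of features drawn per node; 1/3 is random-forest style,
    #: 1.0 is pure bagging.
    mtry_fraction: float = 1.0 / 3.0
    tree_params: TreeParams = field(default_factory=TreeParams)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_learners < 1:
            raise ValueError("n_learners must be >= 1")
        if not (0 < self.mtry_fraction <= 1):
            raise ValueError("mtry_fraction must be in (0, 1]")


@dataclass
class Ensemble:
    trees: list[RegressionTree]
    config: EnsembleConfig
    feature_count: int


def fit_ensemble(X: np.ndarray, y: np.ndarray, config: EnsembleConfig | None = None) -> Ensemble:
    """Fit the ensemble; per-tree seeds derive deterministically from rng_seed."""
    config = config or EnsembleConfig()
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    mtry = max(1, round(config.mtry_fraction * p))
    seeds = np.random.SeedSequence(config.rng_seed).generate_state(
        2 * config.n_learners, np.uint32
    )
    trees = []
    for t in range(config.n_learners):
        boot_rng = np.random.default_rng(int(seeds[2 * t]))
        tree_seed = int(seeds[2 * t + 1]) & 0x7FFFFFFF
        params = TreeParams(
            min_leaf=config.tree_params.min_leaf,
            max_surrogates=config.tree_params.max_surrogates,
            mtry=mtry,
            rng_seed=tree_seed,
        )
        if config.bootstrap:
            rows = boot_rng.integers(0, n, size=n)
            trees.append(fit_tree(X[rows], y[rows], params))
        else:
            trees.append(fit_tree(X, y, params))
    return Ensemble(trees=trees, config=config, feature_count=p)


def predict_ensemble(ens: Ensemble, X: np.ndarray) -> np.ndarray:
    """Unweighted mean of per-tree predictions."""
    X = np.ascontiguousarray(X, dtype=float)
    if X.shape[1] != ens.feature_count:
        raise ValueError(
            f"X must have {ens.feature_count} columns, got {X.shape[1]}"
        )
    out = np.zeros(X.shape[0])
    for tree in ens.trees:
        out += predict_tree(tree, X)
    return out / len(ens.trees)


def ensemble_importance(ens: Ensemble) -> np.ndarray:
    """Elementwise mean of per-tree predictor importance.

    Trees with no branch nodes contribute zero vectors.
    """
    imp = np.zeros(ens.feature_count)
    for tree in ens.trees:
        imp += predictor_importance(tree)
    return imp / len(ens.trees)
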