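"""Repeated 90/10 train/test resampling and the label-shuffled null.

Each iteration draws a uniformly random train/test partition (train size =
round(train_frac * n)), fits an ensemble on the training portion, and
records the held-out MSE, the Pearson correlation between predicted and
actual test scores, and the ensemble's predictor-importance vector.  The
permutation null repeats the same procedure after shuffling the score
vector, computing one NI profile per shuffled run; the pooled distribution
of those NI values calibrates the significance threshold.

All randomness is a deterministic function of the base seed and the
iteration index, so results are bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .ensemble import Ensemble, EnsembleConfig, ensemble_importance, fit_ensemble, predict_ensemble
from .ni import compute_ni

logger = logging.getLogger(__name__)

__all__ = ["IterationResults", "PermutationDistribution", "run_iterations", "run_permutation_null"]


@dataclass
class IterationResults:
    """Per-iteration test MSE, Pearson r, and importance vectors.

    ``corr`` holds NaN where the correlation is undefined (test set smaller
    than two, or zero variance on either side); such iterations still carry
    a valid MSE.
    """

    n_iter: int
    train_frac: float
    mse: np.ndarray
    corr: np.ndarray
    importance: np.ndarray  # (n_iter, n_regions)
    seeds: np.ndarray
    group: str = ""
    biomarker: str = ""
    target: str = ""

    @property
    def n_undefined_corr(self) -> int:
        return int(np.isnan(self.corr).sum())

    def summary(self) -> dict:
        defined = self.corr[np.isfinite(self.corr)]
        return {
            "mse_mean": float(self.mse.mean()),
            "mse_sd": float(self.mse.std(ddof=1)) if len(self.mse) > 1 else 0.0,
            "corr_mean": float(defined.mean()) if defined.size else float("nan"),
            "corr_sd": float(defined.std(ddof=1)) if defined.size > 1 else 0.0,
            "n_undefined_corr": self.n_undefined_corr,
        }

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "biomarker": self.biomarker,
            "target": self.target,
            "n_iter": self.n_iter,
            "train_frac": self.train_frac,
            "mse": self.mse.tolist(),
            "corr": [None if not np.isfinite(c) else float(c) for c in self.corr],
            "importance": self.importance.tolist(),
            "seeds": self.seeds.tolist(),
            "summary": self.summary(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))


@dataclass
class PermutationDistribution(IterationResults):
    """Iteration results produced with shuffled score labels, plus per-run NI."""

    shuffled: bool = True
    ni_per_perm: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def to_dict(self) -> dict:
        payload = super().to_dict()
        payload["shuffled"] = True
        payload["ni_per_perm"] = [
            [None if not np.isfinite(v) else float(v) for v in row]
            for row in self.ni_per_perm
        ]
        return payload


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2:
        return float("nan")
    sa = a.std()
    sb = b.std()
    if sa == 0 or sb == 0:
        return float("nan")
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def _train_size(n: int, train_frac: float) -> int:
    # explicit round-half-up for determinism
    return int(np.floor(train_frac * n + 0.5))


def _one_iteration(
    X: np.ndarray,
    y: np.ndarray,
    train_frac: float,
    ens_config: EnsembleConfig,
    split_rng: np.random.Generator,
    ens_seed: int,
    stratify_labels: np.ndarray | None,
) -> tuple[float, float, np.ndarray]:
    n = len(y)
    n_train = _train_size(n, train_frac)
    if stratify_labels is None:
        perm = split_rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
    else:
        # proportional allocation per label, remainders to the largest strata
        train_parts = []
        test_parts = []
        labels, counts = np.unique(stratify_labels, return_counts=True)
        quotas = {
            lab: int(np.floor(train_frac * c + 0.5)) for lab, c in zip(labels, counts)
        }
        # adjust to hit the global train size exactly
        excess = sum(quotas.values()) - n_train
        for lab in sorted(quotas, key=lambda la: -quotas[la]):
            while excess > 0 and quotas[lab] > 0:
                quotas[lab] -= 1
                excess -= 1
            while excess < 0 and quotas[lab] < int(counts[labels == lab][0]):
                quotas[lab] += 1
                excess += 1
        for lab in labels:
            members = np.flatnonzero(stratify_labels == lab)
            members = split_rng.permutation(members)
            train_parts.append(members[: quotas[lab]])
            test_parts.append(members[quotas[lab] :])
        train_idx = np.concatenate(train_parts)
        test_idx = np.concatenate(test_parts)
    if len(test_idx) == 0:
        raise ValueError("test split is empty; reduce train_frac or add samples")

    config = replace(ens_config, rng_seed=ens_seed)
    ens = fit_ensemble(X[train_idx], y[train_idx], config)
    pred = predict_ensemble(ens, X[test_idx])
    mse = float(((pred - y[test_idx]) ** 2).mean())
    corr = _pearson(pred, y[test_idx])
    return mse, corr, ensemble_importance(ens)


def run_iterations(
    X: np.ndarray,
    y: np.ndarray,
    n_iter: int = 500,
    train_frac: float = 0.9,
    ens_config: EnsembleConfig | None = None,
    seed: int = 0,
    stratify_labels: np.ndarray | None = None,
) -> IterationResults:
    """Run the repeated train/test scheme and collect per-iteration results."""
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    ens_config = ens_config or EnsembleConfig()
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least two samples")
    state = np.random.SeedSequence(seed).generate_state(2 * n_iter, np.uint32)
    mse = np.empty(n_iter)
    corr = np.empty(n_iter)
    importance = np.empty((n_iter, p))
    seeds = (state[0::2] & 0x7FFFFFFF).astype(np.int64)
    for i in range(n_iter):
        split_rng = np.random.default_rng(int(seeds[i]))
        mse[i], corr[i], importance[i] = _one_iteration(
            X, y, train_frac, ens_config,
            split_rng, int(state[2 * i + 1]) & 0x7FFFFFFF, stratify_labels,
        )
    n_undef = int(np.isnan(corr).sum())
    if n_undef:
        logger.info("%d/%d iterations with undefined correlation", n_undef, n_iter)
    return IterationResults(
        n_iter=n_iter,
        train_frac=train_frac,
        mse=mse,
        corr=corr,
        importance=importance,
        seeds=seeds,
    )


def run_permutation_null(
    X: np.ndarray,
    y: np.ndarray,
    n_perm: int = 500,
    train_frac: float = 0.9,
    ens_config: EnsembleConfig | None = None,
    seed: int = 0,
    stratify_labels: np.ndarray | None = None,
) -> PermutationDistribution:
    """Shuffle the score vector n_perm times; one train/test run per shuffle.

    The NI profile is computed per permutation run from that run's
    importance vector; runs whose ensembles record no splits at all yield a
    NaN NI row (counted and logged, excluded from threshold pooling).
    """
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    ens_config = ens_config or EnsembleConfig()
    n, p = X.shape
    state = np.random.SeedSequence((seed, 0x5EED)).generate_state(
        3 * n_perm, np.uint32
    )
    mse = np.empty(n_perm)
    corr = np.empty(n_perm)
    importance = np.empty((n_perm, p))
    ni_per_perm = np.empty((n_perm, p))
    seeds = (state[0::3] & 0x7FFFFFFF).astype(np.int64)
    n_degenerate = 0
    for i in range(n_perm):
        shuffle_rng = np.random.default_rng(int(state[3 * i + 1]) & 0x7FFFFFFF)
        y_shuf = shuffle_rng.permutation(y)
        split_rng = np.random.default_rng(int(seeds[i]))
        mse[i], corr[i], importance[i] = _one_iteration(
            X, y_shuf, train_frac, ens_config,
            split_rng, int(state[3 * i + 2]) & 0x7FFFFFFF, stratify_labels,
        )
        if np.any(importance[i] > 0):
            ni_per_perm[i] = compute_ni(importance[i : i + 1])
        else:
            ni_per_perm[i] = np.nan
            n_degenerate += 1
    if n_degenerate:
        logger.warning(
            "%d/%d permutation runs recorded no splits; NI rows set to NaN",
            n_degenerate,
            n_perm,
        )
    return PermutationDistribution(
        n_iter=n_perm,
        train_frac=train_frac,
        mse=mse,
        corr=corr,
        importance=importance,
        seeds=seeds,
        ni_per_perm=ni_per_perm,
    )
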