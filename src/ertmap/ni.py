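"""Normalized importance (NI), permutation thresholds, ranking, consensus.

NI converts iteration-averaged predictor importance into a dimensionless
per-region profile: take column means of the importance matrix, square-root
them, and divide by the cross-region mean of the square roots, so that NI
averages exactly one over a panel's regions.  Significance is declared where
NI strictly exceeds a permutation threshold — the mean plus two standard
deviations of NI values obtained after shuffling the cognitive scores.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "NIProfile",
    "ConsensusMap",
    "compute_ni",
    "compute_threshold",
    "flag_and_rank",
    "standardize_across_groups",
    "consensus",
]


@dataclass
class NIProfile:
    biomarker: str
    group: str
    target: str
    ni: np.ndarray
    threshold: float
    significant: np.ndarray
    rank_order: np.ndarray

    def __post_init__(self) -> None:
        self.ni = np.asarray(self.ni, dtype=float)
        self.significant = np.asarray(self.significant, dtype=bool)
        self.rank_order = np.asarray(self.rank_order, dtype=int)
        if abs(self.ni.mean() - 1.0) > 1e-9:
            raise ValueError(
                f"NI must average 1 across regions, got {self.ni.mean()!r}"
            )
        if not np.array_equal(self.significant, self.ni > self.threshold):
            raise ValueError("significance flags inconsistent with threshold")

    @classmethod
    def build(
        cls,
        biomarker: str,
        group: str,
        target: str,
        ni: np.ndarray,
        threshold: float,
    ) -> "NIProfile":
        significant, rank_order = flag_and_rank(ni, threshold)
        return cls(
            biomarker=biomarker,
            group=group,
            target=target,
            ni=np.asarray(ni, dtype=float),
            threshold=float(threshold),
            significant=significant,
            rank_order=rank_order,
        )

    def to_dict(self) -> dict:
        return {
            "biomarker": self.biomarker,
            "group": self.group,
            "target": self.target,
            "ni": self.ni.tolist(),
            "threshold": self.threshold,
            "significant": self.significant.tolist(),
            "rank_order": self.rank_order.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "NIProfile":
        return cls(
            biomarker=payload["biomarker"],
            group=payload["group"],
            target=payload["target"],
            ni=np.asarray(payload["ni"], dtype=float),
            threshold=float(payload["threshold"]),
            significant=np.asarray(payload["significant"], dtype=bool),
            rank_order=np.asarray(payload["rank_order"], dtype=int),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "NIProfile":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ConsensusMap:
    """Per-region count (0-3) of cognitive scores for which it is significant."""

    biomarker: str
    group: str
    consensus: np.ndarray

    def __post_init__(self) -> None:
        self.consensus = np.asarray(self.consensus, dtype=int)
        if self.consensus.min(initial=0) < 0 or self.consensus.max(initial=0) > 3:
            raise ValueError("consensus counts must lie in {0, 1, 2, 3}")


def compute_ni(importance: np.ndarray) -> np.ndarray:
    """NI per region from an (n_iter x n_regions) importance matrix."""
    importance = np.atleast_2d(np.asarray(importance, dtype=float))
    if np.any(importance < 0):
        raise ValueError("importance must be non-negative")
    m = importance.mean(axis=0)
    if not np.any(m > 0):
        raise ValueError("no splits recorded; NI undefined")
    s = np.sqrt(m)
    return s / s.mean()


def compute_threshold(
    perm_ni: np.ndarray, ddof: int = 1, per_region: bool = False
) -> float | np.ndarray:
    """Permutation threshold: pooled mean + 2 x pooled SD of permuted NI.

    All entries of the (n_perm x n_regions) permuted-NI matrix are pooled
    into one scalar per (biomarker, group, target).  Rows from degenerate
    permutation runs may carry NaN and are ignored.  Sample SD (ddof=1) is
    the default convention; at hundreds of permutations the difference from
    the population SD is negligible.  ``per_region=True`` returns instead a
    vector of per-column thresholds for sensitivity analyses.
    """
    perm_ni = np.atleast_2d(np.asarray(perm_ni, dtype=float))
    if per_region:
        if np.isfinite(perm_ni).sum(axis=0).min() < 2:
            raise ValueError("need at least two permuted NI values per region")
        mean = np.nanmean(perm_ni, axis=0)
        sd = np.nanstd(perm_ni, axis=0, ddof=ddof)
        return mean + 2.0 * sd
    pooled = perm_ni.ravel()
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size < 2:
        raise ValueError("need at least two permuted NI values")
    sd = pooled.std(ddof=ddof)
    if sd == 0:
        logger.warning("degenerate permutation distribution: zero spread")
    return float(pooled.mean() + 2.0 * sd)


def flag_and_rank(ni: np.ndarray, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Strictly-above-threshold flags and a descending-NI region ranking.

    Ties in NI break toward the lower region index.
    """
    ni = np.asarray(ni, dtype=float)
    significant = ni > threshold
    rank_order = np.lexsort((np.arange(len(ni)), -ni))
    return significant, rank_order


def standardize_across_groups(profiles: list[NIProfile]) -> np.ndarray:
    """Joint min-max rescaling of several groups' NI profiles to [0, 1].

    Used for color mapping when the same biomarker/target is displayed
    across analysis groups; returns one row per profile.
    """
    if not profiles:
        raise ValueError("no profiles given")
    first = profiles[0]
    for prof in profiles[1:]:
        if prof.biomarker != first.biomarker or prof.target != first.target:
            raise ValueError("profiles must share biomarker and target")
        if len(prof.ni) != len(first.ni):
            raise ValueError("profiles must share the region order")
    pooled = np.vstack([prof.ni for prof in profiles])
    lo = pooled.min()
    hi = pooled.max()
    if hi == lo:
        return np.zeros_like(pooled)
    return (pooled - lo) / (hi - lo)


def consensus(profiles: list[NIProfile]) -> ConsensusMap:
    """Per-region count of significant flags across the three score targets."""
    if len(profiles) != 3:
        raise ValueError("consensus requires one profile per cognitive score")
    first = profiles[0]
    targets = {prof.target for prof in profiles}
    if len(targets) != 3:
        raise ValueError("profiles must cover three distinct targets")
    for prof in profiles[1:]:
        if prof.biomarker != first.biomarker or prof.group != first.group:
            raise ValueError("profiles must share biomarker and group")
        if len(prof.ni) != len(first.ni):
            raise ValueError("profiles must share the region order")
    counts = np.sum([prof.significant.astype(int) for prof in profiles], axis=0)
    return ConsensusMap(
        biomarker=first.biomarker, group=first.group, consensus=counts
    )
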