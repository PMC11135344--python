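"""End-to-end orchestration: resampling -> NI -> consensus -> stats.

For every (group x biomarker x target) cell the pipeline runs the repeated
train/test iterations and the permutation null, derives the NI profile with
its significance threshold, and writes JSON outputs under
``out_dir/<group>/<biomarker>/<target>/``.  Per (group x biomarker) a
consensus CSV counts, for each region, how many of the three cognitive
scores flag it as significant.  A manifest records configuration, per-cell
seeds, and any per-cell failures (remaining cells still run).
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_stats import anova_from_raw, tukey_hsd
from .data_model import Cohort, GroupSpec, Target, select_group
from .ensemble import EnsembleConfig
from .ni import NIProfile, compute_ni, compute_threshold, consensus
from .resampling import run_iterations, run_permutation_null
from .tree import TreeParams

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PROFILES", "run_pipeline", "cell_profile"]

#: Named execution profiles.  ``paper`` is the full-scale protocol
#: (500 iterations, 500 permutations, 50 learners); ``ci`` is a desk-scale
#: profile for continuous testing.
PROFILES: dict[str, dict] = {
    "ci": {"iterations": 100, "permutations": 100, "n_learners": 15},
    "paper": {"iterations": 500, "permutations": 500, "n_learners": 50},
}


@dataclass
class PipelineConfig:
    groups: list[str] = field(
        default_factory=lambda: ["HC_MCI", "HC_AD", "MCI_AD", "HC_MCI_AD"]
    )
    biomarkers: list[str] | None = None  # None = every matrix in the cohort
    targets: list[Target] = field(default_factory=lambda: list(Target))
    profile: str = "ci"
    iterations: int | None = None
    permutations: int | None = None
    n_learners: int | None = None
    train_frac: float = 0.9
    mtry_fraction: float = 1.0 / 3.0
    bootstrap: bool = True
    min_leaf: int = 5
    max_surrogates: int = 10
    stratify: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        prof = PROFILES[self.profile]
        if self.iterations is None:
            self.iterations = prof["iterations"]
        if self.permutations is None:
            self.permutations = prof["permutations"]
        if self.n_learners is None:
            self.n_learners = prof["n_learners"]
        if self.profile == "paper" and (
            self.iterations != 500
            or self.permutations != 500
            or self.n_learners != 50
            or self.train_frac != 0.9
        ):
            raise ValueError(
                "paper profile requires 500 iterations, 500 permutations, "
                "50 learners, train_frac 0.9"
            )

    def ensemble_config(self, rng_seed: int = 0) -> EnsembleConfig:
        return EnsembleConfig(
            n_learners=self.n_learners,
            bootstrap=self.bootstrap,
            mtry_fraction=self.mtry_fraction,
            tree_params=TreeParams(
                min_leaf=self.min_leaf, max_surrogates=self.max_surrogates
            ),
            rng_seed=rng_seed,
        )

    def to_dict(self) -> dict:
        return {
            "groups": list(self.groups),
            "biomarkers": list(self.biomarkers) if self.biomarkers else None,
            "targets": [t.value for t in self.targets],
            "profile": self.profile,
            "iterations": self.iterations,
            "permutations": self.permutations,
            "n_learners": self.n_learners,
            "train_frac": self.train_frac,
            "mtry_fraction": self.mtry_fraction,
            "bootstrap": self.bootstrap,
            "min_leaf": self.min_leaf,
            "max_surrogates": self.max_surrogates,
            "stratify": self.stratify,
            "seed": self.seed,
        }


def cell_seed(base_seed: int, group: str, biomarker: str, target: str) -> int:
    """Deterministic per-cell seed, recorded in the manifest."""
    tag = zlib.crc32(f"{group}/{biomarker}/{target}".encode()) & 0x7FFFFFFF
    entropy = np.random.SeedSequence((base_seed, tag))
    return int(entropy.generate_state(1, np.uint32)[0]) & 0x7FFFFFFF


def cell_profile(
    cohort: Cohort,
    group: str,
    biomarker: str,
    target: Target,
    config: PipelineConfig,
    seed: int,
) -> tuple[NIProfile, dict]:
    """Run one (group, biomarker, target) cell in isolation.

    Returns the NI profile plus a payload with iteration results, the
    permutation null, and summaries — everything the manifest needs to make
    the cell reproducible.
    """
    from .data_model import diagnoses_of

    X, y, ids = select_group(cohort, group, biomarker, target)
    strat = None
    if config.stratify:
        strat = diagnoses_of(cohort, ids)
    ens = config.ensemble_config()
    iters = run_iterations(
        X, y, config.iterations, config.train_frac, ens,
        seed=seed, stratify_labels=strat,
    )
    null = run_permutation_null(
        X, y, config.permutations, config.train_frac, ens,
        seed=seed + 1, stratify_labels=strat,
    )
    ni = compute_ni(iters.importance)
    threshold = compute_threshold(null.ni_per_perm)
    profile = NIProfile.build(
        biomarker=biomarker, group=group, target=target.value,
        ni=ni, threshold=threshold,
    )
    iters.group = null.group = group
    iters.biomarker = null.biomarker = biomarker
    iters.target = null.target = target.value
    return profile, {"iterations": iters, "null": null}


def run_pipeline(
    cohort: Cohort,
    config: PipelineConfig,
    out_dir: str | Path,
) -> dict:
    """Run every cell; write outputs and a manifest under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    biomarkers = config.biomarkers or sorted(cohort.matrices)
    manifest: dict = {
        "config": config.to_dict(),
        "cells": [],
        "consensus": [],
        "stats": {},
    }
    profiles: dict[tuple[str, str], dict[str, NIProfile]] = {}
    mse_by_cell: dict[tuple[str, str], dict[str, np.ndarray]] = {}

    for group in config.groups:
        GroupSpec.from_name(group)  # validate early
        for biomarker in biomarkers:
            for target in config.targets:
                seed = cell_seed(config.seed, group, biomarker, target.value)
                cell_id = f"{group}/{biomarker}/{target.value}"
                t0 = time.time()
                try:
                    profile, payload = cell_profile(
                        cohort, group, biomarker, target, config, seed
                    )
                except Exception as exc:  # record and continue
                    logger.error("cell %s failed: %s", cell_id, exc)
                    manifest["cells"].append(
                        {"cell": cell_id, "seed": seed, "error": str(exc)}
                    )
                    continue
                cell_dir = out_dir / group / biomarker / target.value
                cell_dir.mkdir(parents=True, exist_ok=True)
                payload["iterations"].to_json(cell_dir / "iterations.json")
                payload["null"].to_json(cell_dir / "null.json")
                profile.to_json(cell_dir / "ni.json")
                profiles.setdefault((group, biomarker), {})[target.value] = profile
                mse_by_cell.setdefault((group, target.value), {})[biomarker] = (
                    payload["iterations"].mse
                )
                manifest["cells"].append(
                    {
                        "cell": cell_id,
                        "seed": seed,
                        "elapsed_s": round(time.time() - t0, 3),
                        "n_significant": int(profile.significant.sum()),
                        "threshold": profile.threshold,
                        "summary": payload["iterations"].summary(),
                    }
                )
                logger.info(
                    "cell %s done in %.1fs (%d significant regions)",
                    cell_id, time.time() - t0, int(profile.significant.sum()),
                )

    # consensus maps per (group, biomarker) with all three targets present
    for (group, biomarker), by_target in profiles.items():
        if len(by_target) != 3:
            continue
        cmap = consensus([by_target[t.value] for t in Target])
        region_names = cohort.matrices[biomarker].region_names
        frame = pd.DataFrame(
            {
                "region": region_names,
                "consensus": cmap.consensus,
                "ni_mmse": by_target["MMSE"].ni,
                "ni_cdrsb": by_target["CDRSB"].ni,
                "ni_adas": by_target["ADAS"].ni,
            }
        )
        path = out_dir / group / biomarker / "consensus.csv"
        frame.to_csv(path, index=False)
        manifest["consensus"].append(
            {
                "group": group,
                "biomarker": biomarker,
                "n_consensus_3": int((cmap.consensus == 3).sum()),
            }
        )

    # biomarker comparison: one-way ANOVA + Tukey on per-iteration MSE
    for (group, target), by_biomarker in mse_by_cell.items():
        if len(by_biomarker) < 2:
            continue
        values = np.concatenate(list(by_biomarker.values()))
        labels = np.concatenate(
            [np.repeat(b, len(v)) for b, v in by_biomarker.items()]
        )
        anova = anova_from_raw(values, labels)
        tukey = tukey_hsd(by_biomarker, fwer=0.01)
        manifest["stats"][f"{group}/{target}"] = {
            "anova_f": anova.f,
            "anova_p": anova.p,
            "tukey_significant_pairs": int(tukey["significant"].sum()),
        }

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
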