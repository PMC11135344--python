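"""Synthetic cohort generator with the statistical structure the analysis assumes.

The generator emulates a three-cohort (HC / MCI / AD) study: per-group
cognitive-score distributions taken from the published summary table of the
structural-MRI subsample, per-group sex ratios and age distributions, and
per-biomarker region matrices.  Region values are a fixed per-region
baseline plus optional planted linear effects of the (cohort-standardized)
cognitive scores, active only in configured diagnosis groups, plus Gaussian
noise.  Everything is reproducible from a single integer seed.

Scores are drawn from a normal whose location is adjusted so that after
clipping to the score's legal range the expected value equals the requested
group mean (a plain clip would bias means near a bound, e.g. MMSE in
healthy controls); draws beyond four SD are redrawn first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .data_model import (
    BiomarkerMatrix,
    Cohort,
    Diagnosis,
    SCORE_RANGES,
    Sex,
    SubjectRecord,
    Target,
)
from .regions import CANONICAL_REGION_COUNTS, default_region_names

__all__ = [
    "EffectSpec",
    "SimulationConfig",
    "simulate_cohort",
    "make_fixture",
    "TABLE1_SMRI_SCORES",
    "PLANTED_SLOPE",
]

#: Per-(diagnosis, target) score mean and SD of the sMRI subsample.
TABLE1_SMRI_SCORES: dict[tuple[Diagnosis, Target], tuple[float, float]] = {
    (Diagnosis.HC, Target.MMSE): (29.06, 1.18),
    (Diagnosis.MCI, Target.MMSE): (27.63, 1.89),
    (Diagnosis.AD, Target.MMSE): (23.08, 2.67),
    (Diagnosis.HC, Target.CDRSB): (0.04, 0.14),
    (Diagnosis.MCI, Target.CDRSB): (1.28, 0.74),
    (Diagnosis.AD, Target.CDRSB): (4.48, 1.80),
    (Diagnosis.HC, Target.ADAS): (8.61, 4.06),
    (Diagnosis.MCI, Target.ADAS): (15.01, 6.22),
    (Diagnosis.AD, Target.ADAS): (29.23, 8.20),
}

TABLE1_SMRI_N: dict[Diagnosis, int] = {
    Diagnosis.HC: 265,
    Diagnosis.MCI: 274,
    Diagnosis.AD: 227,
}

TABLE1_SMRI_AGE: dict[Diagnosis, tuple[float, float]] = {
    Diagnosis.HC: (73.91, 5.57),
    Diagnosis.MCI: (73.48, 7.38),
    Diagnosis.AD: (74.43, 7.97),
}

TABLE1_SMRI_P_MALE: dict[Diagnosis, float] = {
    Diagnosis.HC: 124 / 265,
    Diagnosis.MCI: 160 / 274,
    Diagnosis.AD: 122 / 227,
}

#: Slope (feature units per standardized-score unit) of the planted effects
#: in the ``planted`` fixture, chosen so that a planted region's univariate
#: R^2 with each score is about 0.2 within the HC/AD selection when the
#: effect is active in AD only (see docs/methods.md).
PLANTED_SLOPE = 0.03


@dataclass(frozen=True)
class EffectSpec:
    """A planted monotone association between one region and one score.

    The region's value gains ``slope * z`` where z is the target score
    standardized over the whole generated cohort, applied only to subjects
    whose diagnosis is in ``active_groups``.  Sign is free: atrophy-like
    measures decrease with worse scores while diffusivity/amyloid increase.
    """

    biomarker: str
    region_index: int
    target: Target
    slope: float
    active_groups: frozenset[Diagnosis]

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")


@dataclass
class SimulationConfig:
    n_per_group: dict[Diagnosis, int] = field(
        default_factory=lambda: dict(TABLE1_SMRI_N)
    )
    score_params: dict[tuple[Diagnosis, Target], tuple[float, float]] = field(
        default_factory=lambda: dict(TABLE1_SMRI_SCORES)
    )
    age_params: dict[Diagnosis, tuple[float, float]] = field(
        default_factory=lambda: dict(TABLE1_SMRI_AGE)
    )
    sex_probs: dict[Diagnosis, float] = field(
        default_factory=lambda: dict(TABLE1_SMRI_P_MALE)
    )
    #: biomarker name -> number of regions
    biomarkers: dict[str, int] = field(
        default_factory=lambda: dict(CANONICAL_REGION_COUNTS)
    )
    #: per-region baseline offsets are drawn once from N(mean, sd)
    baseline: dict[str, tuple[float, float]] = field(default_factory=dict)
    #: per-subject measurement noise SD
    noise_sd: dict[str, float] = field(default_factory=dict)
    effects: list[EffectSpec] = field(default_factory=list)
    seed: int = 0

    DEFAULT_BASELINE: tuple[float, float] = (1.0, 0.1)
    DEFAULT_NOISE_SD: float = 0.1

    def __post_init__(self) -> None:
        for diag, n in self.n_per_group.items():
            if n < 0:
                raise ValueError(f"n_per_group[{diag}] must be >= 0")
        for key, (_, sd) in self.score_params.items():
            if sd <= 0:
                raise ValueError(f"score sd for {key} must be > 0")
        for diag, prob in self.sex_probs.items():
            if not 0 <= prob <= 1:
                raise ValueError(f"sex_probs[{diag}] must be in [0, 1]")
        for eff in self.effects:
            n_regions = self.biomarkers.get(eff.biomarker)
            if n_regions is None:
                raise ValueError(f"effect on unknown biomarker {eff.biomarker}")
            if not 0 <= eff.region_index < n_regions:
                raise ValueError(
                    f"effect region {eff.region_index} outside "
                    f"{eff.biomarker}'s {n_regions} regions"
                )


def _clip_matched_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Location mu such that E[clip(N(mu, sd), lo, hi)] equals ``mean``."""

    def clipped_mean(mu: float) -> float:
        a = (lo - mu) / sd
        b = (hi - mu) / sd
        return (
            lo * stats.norm.cdf(a)
            + hi * stats.norm.sf(b)
            + mu * (stats.norm.cdf(b) - stats.norm.cdf(a))
            + sd * (stats.norm.pdf(a) - stats.norm.pdf(b))
        )

    if clipped_mean(mean) == mean:  # no boundary mass at working precision
        return mean
    lo_b, hi_b = lo - 8 * sd, hi + 8 * sd
    return float(optimize.brentq(lambda m: clipped_mean(m) - mean, lo_b, hi_b))


def _draw_scores(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    mu = _clip_matched_loc(mean, sd, lo, hi)
    x = rng.normal(mu, sd, size=n)
    for _ in range(100):
        wild = np.abs(x - mu) > 4 * sd
        if not wild.any():
            break
        x[wild] = rng.normal(mu, sd, size=int(wild.sum()))
    return np.clip(x, lo, hi)


def simulate_cohort(config: SimulationConfig | None = None) -> Cohort:
    """Generate a cohort according to ``config`` (bit-reproducible from seed)."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)

    subjects: list[SubjectRecord] = []
    diagnoses: list[Diagnosis] = []
    scores: dict[Target, list[float]] = {t: [] for t in Target}
    counter = 0
    for diag in (Diagnosis.HC, Diagnosis.MCI, Diagnosis.AD):
        n = config.n_per_group.get(diag, 0)
        if n == 0:
            continue
        age_mean, age_sd = config.age_params[diag]
        ages = np.clip(rng.normal(age_mean, age_sd, size=n), 40.0, 110.0)
        males = rng.random(n) < config.sex_probs[diag]
        per_target = {}
        for target in Target:
            mean, sd = config.score_params[(diag, target)]
            lo, hi = SCORE_RANGES[target]
            per_target[target] = _draw_scores(rng, n, mean, sd, lo, hi)
        for i in range(n):
            counter += 1
            subjects.append(
                SubjectRecord(
                    subject_id=f"S{counter:05d}",
                    diagnosis=diag,
                    sex=Sex.M if males[i] else Sex.F,
                    age=float(ages[i]),
                    mmse=float(per_target[Target.MMSE][i]),
                    cdrsb=float(per_target[Target.CDRSB][i]),
                    adas=float(per_target[Target.ADAS][i]),
                )
            )
            diagnoses.append(diag)
            for target in Target:
                scores[target].append(float(per_target[target][i]))

    n_total = len(subjects)
    diag_arr = np.asarray([d.value for d in diagnoses])
    z: dict[Target, np.ndarray] = {}
    for target in Target:
        vec = np.asarray(scores[target])
        sd = vec.std()
        z[target] = (vec - vec.mean()) / sd if sd > 0 else np.zeros(n_total)

    subject_ids = [s.subject_id for s in subjects]
    matrices: dict[str, BiomarkerMatrix] = {}
    for name in sorted(config.biomarkers):
        n_regions = config.biomarkers[name]
        base_mean, base_sd = config.baseline.get(name, config.DEFAULT_BASELINE)
        noise_sd = config.noise_sd.get(name, config.DEFAULT_NOISE_SD)
        baselines = rng.normal(base_mean, base_sd, size=n_regions)
        values = np.tile(baselines, (n_total, 1))
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, size=(n_total, n_regions))
        for eff in config.effects:
            if eff.biomarker != name:
                continue
            active = np.isin(
                diag_arr, [d.value for d in eff.active_groups]
            ).astype(float)
            values[:, eff.region_index] += eff.slope * z[eff.target] * active
        matrices[name] = BiomarkerMatrix(
            biomarker=name,
            region_names=default_region_names(name, n_regions),
            subject_ids=list(subject_ids),
            values=values,
        )
    return Cohort(subjects=subjects, matrices=matrices)


def planted_effects() -> list[EffectSpec]:
    """The documented planted-effect set of the ``planted`` fixture.

    Three of the 30 regions of the PANEL30 biomarker are each associated
    with all three cognitive scores, active only in the AD cohort, so that
    AD-containing analysis groups carry recoverable signal while the HC/MCI
    group does not.  Signs follow the scores' orientations (thickness-like
    decline: positive with MMSE, negative with CDRSB/ADAS severity).  One
    PANEL10 region is additionally tied to ADAS from the MCI stage onward.
    """
    effects = []
    for region in (4, 13, 22):
        for target, sign in (
            (Target.MMSE, +1.0),
            (Target.CDRSB, -1.0),
            (Target.ADAS, -1.0),
        ):
            effects.append(
                EffectSpec(
                    biomarker="PANEL30",
                    region_index=region,
                    target=target,
                    slope=sign * PLANTED_SLOPE,
                    active_groups=frozenset({Diagnosis.AD}),
                )
            )
    effects.append(
        EffectSpec(
            biomarker="PANEL10",
            region_index=2,
            target=Target.ADAS,
            slope=-0.6 * PLANTED_SLOPE,
            active_groups=frozenset({Diagnosis.MCI, Diagnosis.AD}),
        )
    )
    return effects


def make_fixture(name: str, seed: int = 0) -> Cohort:
    """Standard test cohorts: ``tiny``, ``paper_like``, or ``planted``.

    tiny
        12 subjects (4 per diagnosis), two 4-region synthetic panels; small
        enough for exhaustive oracle checks.
    paper_like
        Summary-table sample sizes and score distributions, all nine
        canonical biomarker panels, no planted effects.
    planted
        Same cohort structure with two synthetic panels (30 and 10 regions)
        carrying the documented planted effects.
    """
    if name == "tiny":
        config = SimulationConfig(
            n_per_group={Diagnosis.HC: 4, Diagnosis.MCI: 4, Diagnosis.AD: 4},
            biomarkers={"SYN_A": 4, "SYN_B": 4},
            seed=seed,
        )
    elif name == "paper_like":
        config = SimulationConfig(seed=seed)
    elif name == "planted":
        config = SimulationConfig(
            biomarkers={"PANEL30": 30, "PANEL10": 10},
            effects=planted_effects(),
            seed=seed,
        )
    else:
        raise ValueError(f"unknown fixture {name!r}; use tiny/paper_like/planted")
    return simulate_cohort(config)
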