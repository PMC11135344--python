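"""Cohort-level statistical comparisons.

One-way ANOVA is available both from raw values and reconstructed from
printed per-group summaries (n, mean, SD) — the latter makes the inferential
statistics of published demographic tables reproducible without
subject-level data.  Categorical contrasts use Pearson's chi-squared without
continuity correction; pairwise biomarker comparisons use Tukey's HSD with a
configurable family-wise error rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "anova_from_summaries",
    "anova_from_raw",
    "chi_squared",
    "tukey_hsd",
    "correlation_summary",
]


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: need n >= 2, got {self.n}")
        if self.sd <= 0:
            raise ValueError(f"group {self.label!r}: sd must be > 0")


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float


def anova_from_summaries(groups: list[GroupSummary]) -> AnovaResult:
    """One-way ANOVA reconstructed from per-group (n, mean, sd).

    SSB = sum n_i (mean_i - grand)^2 with the n-weighted grand mean;
    SSW = sum (n_i - 1) sd_i^2; F = MSB / MSW.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups], dtype=float)
    sds = np.array([g.sd for g in groups], dtype=float)
    n_total = ns.sum()
    k = len(groups)
    grand = float((ns * means).sum() / n_total)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df_b = k - 1
    df_w = int(n_total) - k
    f = (ssb / df_b) / (ssw / df_w)
    return AnovaResult(
        f=f, df_between=df_b, df_within=df_w, p=float(stats.f.sf(f, df_b, df_w))
    )


def anova_from_raw(values: np.ndarray, labels: np.ndarray) -> AnovaResult:
    """Classical one-way ANOVA on raw values grouped by labels."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    samples = [values[labels == u] for u in uniq]
    for u, s in zip(uniq, samples):
        if len(s) < 2:
            raise ValueError(f"group {u!r}: need at least two values")
    f, p = stats.f_oneway(*samples)
    k = len(samples)
    return AnovaResult(
        f=float(f),
        df_between=k - 1,
        df_within=len(values) - k,
        p=float(p),
    )


def chi_squared(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared on a 2 x k contingency table (no Yates correction)."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    x2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(x2), float(p)


def tukey_hsd(samples: dict[str, np.ndarray], fwer: float = 0.01) -> pd.DataFrame:
    """All pairwise mean comparisons via Tukey's HSD at the given FWER.

    Uses the studentized-range criterion with pooled within-group variance
    and the Tukey-Kramer adjustment for unequal sample sizes.  Returns one
    row per pair: (group1, group2, difference, lower, upper, significant).

    When the supplied vectors are per-iteration errors from a shared
    resampling loop, iterations are not independent across biomarkers; the
    test is reported as-is and this caveat is logged.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    for label, vec in samples.items():
        if len(np.asarray(vec)) < 2:
            raise ValueError(f"sample {label!r}: need at least two values")
    logger.warning(
        "tukey_hsd: iteration vectors sharing subjects/splits are not "
        "independent; interpret p-values accordingly"
    )
    endog = np.concatenate([np.asarray(v, dtype=float) for v in samples.values()])
    labels = np.concatenate(
        [np.repeat(label, len(v)) for label, v in samples.items()]
    )
    res = pairwise_tukeyhsd(endog, labels, alpha=fwer)
    frame = pd.DataFrame(
        res.summary().data[1:],
        columns=[str(c) for c in res.summary().data[0]],
    )
    return pd.DataFrame(
        {
            "group1": frame["group1"],
            "group2": frame["group2"],
            "difference": frame["meandiff"].astype(float),
            "lower": frame["lower"].astype(float),
            "upper": frame["upper"].astype(float),
            "significant": frame["reject"].astype(bool),
        }
    )


def correlation_summary(results) -> tuple[float, float, int]:
    """Mean, SD, and defined count of per-iteration Pearson correlations."""
    corr = np.asarray(results.corr, dtype=float)
    defined = corr[np.isfinite(corr)]
    if defined.size == 0:
        return float("nan"), float("nan"), 0
    sd = float(defined.std(ddof=1)) if defined.size > 1 else 0.0
    return float(defined.mean()), sd, int(defined.size)
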