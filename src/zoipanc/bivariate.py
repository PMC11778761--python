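"""Descriptive statistics and unadjusted-association screening.

Covers the pre-model stages of the analysis: per-year mean/SD/CI of the
visit counts, percent distributions of the covariates, group mean tables,
Kruskal-Wallis tests of unadjusted association, and pairwise Mann-Whitney
U comparisons for covariates with more than two levels.  Kruskal-Wallis
and Mann-Whitney come from :mod:`scipy.stats` (tie corrections included);
visit counts are heavily tied so tie handling is always on.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import COVARIATES, LEVELS, OUTCOME, YEAR, YEAR_LEVELS

logger = logging.getLogger(__name__)

__all__ = [
    "GroupTestResult",
    "mean_ci",
    "normal_ci",
    "percent_distribution",
    "kruskal_wallis",
    "mann_whitney_pairwise",
    "group_mean_table",
    "analyze_covariate",
]


def normal_ci(mean: float, sd: float, n: int, z: float = 1.96) -> tuple[float, float]:
    """Normal-approximation 95% CI for a mean from summary statistics."""
    half = z * sd / np.sqrt(n)
    return mean - half, mean + half


def mean_ci(y) -> tuple[float, float, float, float]:
    """Sample mean, SD (n-1 denominator) and normal-approximation 95% CI."""
    y = np.asarray(y, dtype=float)
    if y.shape[0] < 2:
        raise ValueError("need at least two observations for a mean and CI")
    mean = float(np.mean(y))
    sd = float(np.std(y, ddof=1))
    lo, hi = normal_ci(mean, sd, y.shape[0])
    return mean, sd, lo, hi


def percent_distribution(df: pd.DataFrame, covariate: str,
                         by_year: bool = True) -> pd.DataFrame:
    """Column-percent distribution of a covariate, per survey year and pooled.

    Each column sums to 100 up to rounding.
    """
    if covariate not in COVARIATES:
        raise KeyError(f"unknown covariate {covariate!r}")
    levels = LEVELS[covariate]
    out = pd.DataFrame(index=pd.Index(levels, name=covariate))
    if by_year:
        for year in YEAR_LEVELS:
            sub = df.loc[df[YEAR] == year, covariate]
            if len(sub):
                out[year] = (sub.value_counts(normalize=True)
                             .reindex(levels, fill_value=0.0) * 100.0)
    out["pooled"] = (df[covariate].value_counts(normalize=True)
                     .reindex(levels, fill_value=0.0) * 100.0)
    return out


def kruskal_wallis(y, groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p-value.

    All-identical values across two or more groups give H = 0 and p = 1.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    samples = [y[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be nonempty")
    if np.all(y == y[0]):
        return 0.0, 1.0
    H, p = stats.kruskal(*samples)
    return float(H), float(p)


def mann_whitney_pairwise(y, groups, pairs=None, *, bonferroni: bool = False,
                          use_continuity: bool = True):
    """Two-sided Mann-Whitney U tests for level pairs of one covariate.

    Uses the tie-corrected normal approximation; raw (unadjusted) p-values
    are reported, with optional Bonferroni adjustment over the requested
    pairs.  Returns a list of ``(pair, U, p)`` tuples.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if pairs is None:
        pairs = list(itertools.combinations(pd.unique(groups), 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        ya, yb = y[groups == a], y[groups == b]
        if len(ya) == 0 or len(yb) == 0:
            raise ValueError(f"empty group in pair ({a!r}, {b!r})")
        U, p = stats.mannwhitneyu(ya, yb, alternative="two-sided",
                                  method="asymptotic",
                                  use_continuity=use_continuity)
        if bonferroni:
            p = min(1.0, p * m)
        out.append(((a, b), float(U), float(p)))
    return out


def group_mean_table(df: pd.DataFrame, covariate: str,
                     by_year: bool = True) -> pd.DataFrame:
    """Mean outcome per covariate level, by survey year and pooled.

    Empty cells are reported as missing (NaN), never as zero.
    """
    if covariate not in COVARIATES:
        raise KeyError(f"unknown covariate {covariate!r}")
    levels = LEVELS[covariate]
    out = pd.DataFrame(index=pd.Index(levels, name=covariate))
    if by_year:
        for year in YEAR_LEVELS:
            sub = df[df[YEAR] == year]
            out[year] = sub.groupby(covariate, observed=False)[OUTCOME].mean().reindex(levels)
    out["pooled"] = df.groupby(covariate, observed=False)[OUTCOME].mean().reindex(levels)
    return out.astype(float)


@dataclass
class GroupTestResult:
    """Unadjusted association of one covariate with the outcome."""

    covariate: str
    group_means: dict[str, float]
    kw_statistic: float
    kw_p: float
    #: (level pair, U statistic, p-value); filled only for covariates with
    #: more than two levels whose Kruskal-Wallis test is significant.
    pairwise: list[tuple[tuple[str, str], float, float]] = field(default_factory=list)


def analyze_covariate(df: pd.DataFrame, covariate: str, *, alpha: float = 0.05,
                      bonferroni: bool = False) -> GroupTestResult:
    """Kruskal-Wallis screen with Mann-Whitney follow-up.

    Pairwise comparisons run only when the covariate has more than two
    observed levels and the Kruskal-Wallis p-value falls below ``alpha``.
    """
    y = df[OUTCOME].to_numpy(dtype=float)
    groups = df[covariate].to_numpy()
    H, p = kruskal_wallis(y, groups)
    means = df.groupby(covariate, observed=True)[OUTCOME].mean().to_dict()
    result = GroupTestResult(covariate=covariate,
                             group_means={k: float(v) for k, v in means.items()},
                             kw_statistic=H, kw_p=p)
    observed_levels = [lv for lv in LEVELS[covariate] if lv in means]
    if len(observed_levels) > 2 and p < alpha:
        pairs = list(itertools.combinations(observed_levels, 2))
        result.pairwise = mann_whitney_pairwise(y, groups, pairs,
                                                bonferroni=bonferroni)
    return result
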