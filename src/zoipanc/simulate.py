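"""Synthetic pooled-survey generator with known ZOIP truth.

The real mother-level records come from restricted-access Demographic and
Health Survey files, so every pipeline stage is exercised on synthetic
datasets instead.  The generator emulates the pooled four-wave sample:

* per-year sample sizes 6,956 / 4,304 / 4,819 / 4,712 (pooled 20,791);
* covariates drawn independently within year from the published per-year
  category percentages (independence is a stated simplification — the
  real covariates are dependent);
* outcomes drawn from the ZOIP mixture with ``log lam_i = x_i' beta``
  using the published coefficient vector (year coded 1-4 with a
  rural-by-year interaction) and inflation masses 0.172 / 0.011.

One master seed spawns per-stage child streams so covariates, outcomes
and missingness are individually reproducible.  The published 2022
marginal for terminated pregnancy sums to 108%; all marginals are
renormalised (with a log warning for inconsistent ones).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    ANALYSIS_COLUMNS,
    COVARIATES,
    DESIGN_COLUMNS,
    LEVELS,
    OUTCOME,
    YEAR,
    YEAR_LEVELS,
    build_design_matrix,
)
from .zoip import zoip_sample

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_N_PER_YEAR",
    "DEFAULT_BETA",
    "DEFAULT_PHI0",
    "DEFAULT_PHI1",
    "TABLE_MARGINALS",
    "SyntheticConfig",
    "generate_covariates",
    "generate_outcomes",
    "generate_pooled_dataset",
]

DEFAULT_N_PER_YEAR: dict[str, int] = {
    "2011": 6956, "2014": 4304, "2017-18": 4819, "2022": 4712,
}

#: Published per-year category percentages, keyed covariate -> level ->
#: (2011, 2014, 2017-18, 2022).  Renormalised to probabilities at sampling
#: time.
TABLE_MARGINALS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "residence": {
        "urban": (31.6, 32.2, 34.4, 32.9),
        "rural": (68.4, 67.8, 65.6, 67.1),
    },
    "maternal_age": {
        "<20": (25.8, 28.0, 24.2, 19.1),
        "20-34": (68.5, 67.4, 71.2, 74.7),
        ">34": (5.7, 4.6, 4.6, 6.2),
    },
    "maternal_edu": {
        "none": (17.8, 13.1, 6.1, 5.2),
        "primary": (29.7, 27.1, 27.5, 22.8),
        "secondary": (43.7, 48.0, 47.9, 52.6),
        "higher": (8.8, 11.8, 18.4, 19.4),
    },
    "paternal_edu": {
        "none": (26.5, 22.4, 13.7, 14.5),
        "primary": (28.9, 30.0, 33.5, 29.6),
        "secondary": (30.2, 31.9, 33.1, 34.7),
        "higher": (14.4, 15.7, 19.8, 21.2),
    },
    "wealth": {
        "poor": (39.8, 39.5, 41.6, 40.5),
        "middle": (19.2, 19.2, 18.0, 19.8),
        "rich": (41.0, 41.3, 40.4, 39.7),
    },
    "birth_order": {
        "first": (33.9, 40.7, 38.0, 37.1),
        "second_third": (47.6, 45.5, 50.0, 53.3),
        "above_third": (18.6, 13.8, 12.0, 9.6),
    },
    "working": {
        "non_working": (90.2, 78.6, 62.7, 74.8),
        "working": (9.8, 21.4, 37.3, 25.2),
    },
    "media": {
        "non_exposed": (34.3, 37.4, 35.8, 40.4),
        "exposed": (65.7, 62.6, 64.2, 59.6),
    },
    "decision": {
        "no": (24.9, 27.3, 15.0, 18.4),
        "yes": (75.1, 72.7, 85.0, 81.6),
    },
    "violence_opinion": {
        "non_justified": (67.3, 71.8, 82.0, 88.2),
        "justified": (32.7, 28.2, 18.0, 11.8),
    },
    "wanted_pregnancy": {
        "no": (13.4, 10.1, 8.2, 7.4),
        "yes": (86.6, 89.9, 91.8, 92.6),
    },
    # the published 2022 column for this covariate sums to 108.0; it is
    # renormalised like every other marginal
    "terminated_pregnancy": {
        "no": (81.9, 85.2, 83.0, 89.9),
        "yes": (18.1, 14.8, 17.0, 18.1),
    },
}

#: Published regression coefficients in design-column order.
DEFAULT_BETA: dict[str, float] = {
    "Intercept": 0.103,
    "residence[rural]": -0.523,
    "maternal_age[20-34]": 0.032,
    "maternal_age[>34]": 0.148,
    "maternal_edu[primary]": 0.326,
    "maternal_edu[secondary]": 0.490,
    "maternal_edu[higher]": 0.618,
    "paternal_edu[primary]": 0.079,
    "paternal_edu[secondary]": 0.201,
    "paternal_edu[higher]": 0.316,
    "wealth[middle]": 0.125,
    "wealth[rich]": 0.211,
    "birth_order[second_third]": -0.032,
    "birth_order[above_third]": -0.222,
    "working[working]": 0.077,
    "media[exposed]": 0.243,
    "decision[yes]": 0.087,
    "violence_opinion[justified]": -0.061,
    "wanted_pregnancy[yes]": 0.140,
    "terminated_pregnancy[yes]": 0.104,
    YEAR: 0.034,
    f"{YEAR}:residence[rural]": 0.114,
}
DEFAULT_PHI0 = 0.172
DEFAULT_PHI1 = 0.011


def _default_beta_vector() -> np.ndarray:
    return np.array([DEFAULT_BETA[c] for c in DESIGN_COLUMNS])


def _normalized_marginal(cov: str, year_idx: int,
                         marginals: dict) -> tuple[list[str], np.ndarray]:
    levels = LEVELS[cov]
    raw = np.array([marginals[cov][lv][year_idx] for lv in levels], dtype=float)
    if np.any(raw < 0) or raw.sum() <= 0:
        raise ValueError(f"invalid marginal for {cov!r}, year index {year_idx}")
    total = raw.sum()
    if abs(total - 100.0) > 0.5 and abs(total - 1.0) > 0.05:
        logger.warning("marginal for %r (%s) sums to %.1f; renormalising",
                       cov, YEAR_LEVELS[year_idx], total)
    return levels, raw / total


@dataclass
class SyntheticConfig:
    """Generating truth for one synthetic pooled dataset.

    Defaults reproduce the pooled study conditions: per-year sizes summing
    to 20,791, the published covariate marginals and regression
    coefficients, and inflation masses (0.172, 0.011).  ``missing_rate``
    (a float applied to every covariate field, or a ``{field: rate}``
    mapping) injects missingness completely at random to exercise the
    complete-case filter.
    """

    n_per_year: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_PER_YEAR))
    marginals: dict = field(default_factory=lambda: {
        cov: dict(levels) for cov, levels in TABLE_MARGINALS.items()})
    beta: np.ndarray = field(default_factory=_default_beta_vector)
    phi0: float = DEFAULT_PHI0
    phi1: float = DEFAULT_PHI1
    seed: int = 0
    missing_rate: float | dict[str, float] = 0.0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        unknown = set(self.n_per_year) - set(YEAR_LEVELS)
        if unknown:
            raise ValueError(f"unknown survey year(s) in n_per_year: {sorted(unknown)}")

    def child_seeds(self) -> dict[str, np.random.SeedSequence]:
        ss = np.random.SeedSequence(self.seed)
        names = ["covariates", "outcomes", "missing"]
        return dict(zip(names, ss.spawn(len(names))))

    def truth(self) -> dict:
        return {
            "beta": {c: float(b) for c, b in zip(DESIGN_COLUMNS, self.beta)},
            "phi0": self.phi0,
            "phi1": self.phi1,
            "n_per_year": dict(self.n_per_year),
            "seed": self.seed,
            "missing_rate": self.missing_rate,
            "marginals": {cov: {lv: list(map(float, v)) for lv, v in levels.items()}
                          for cov, levels in self.marginals.items()},
        }


def generate_covariates(config: SyntheticConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw covariate records (outcome unset), independently within year."""
    if rng is None:
        rng = np.random.default_rng(config.child_seeds()["covariates"])
    frames = []
    for year_idx, year in enumerate(YEAR_LEVELS):
        n = int(config.n_per_year.get(year, 0))
        if n == 0:
            continue
        cols: dict[str, np.ndarray] = {YEAR: np.full(n, year, dtype=object)}
        for cov in COVARIATES:
            levels, probs = _normalized_marginal(cov, year_idx, config.marginals)
            if len(probs) != len(LEVELS[cov]):
                raise ValueError(f"marginal for {cov!r} has wrong length")
            idx = rng.choice(len(levels), size=n, p=probs)
            cols[cov] = np.array(levels, dtype=object)[idx]
        frames.append(pd.DataFrame(cols))
    out = pd.concat(frames, ignore_index=True)
    return out


def generate_outcomes(df: pd.DataFrame, config: SyntheticConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Attach ZOIP outcomes with ``log lam_i = x_i' beta`` to covariate records."""
    if rng is None:
        rng = np.random.default_rng(config.child_seeds()["outcomes"])
    design = build_design_matrix(df, require_outcome=False)
    if config.beta.shape[0] != design.p:
        raise ValueError(
            f"beta has length {config.beta.shape[0]} but the design has "
            f"{design.p} columns")
    lam = np.exp(design.X @ config.beta)
    y = zoip_sample(lam, config.phi0, config.phi1, seed=rng)
    out = df.copy()
    out[OUTCOME] = y
    return out[[c for c in ANALYSIS_COLUMNS if c in out.columns]]


def _inject_missing(df: pd.DataFrame, config: SyntheticConfig,
                    rng: np.random.Generator) -> pd.DataFrame:
    rates = config.missing_rate
    if not isinstance(rates, dict):
        rates = {c: float(rates) for c in COVARIATES}
    out = df.copy()
    for col, rate in rates.items():
        if rate <= 0:
            continue
        mask = rng.random(len(out)) < rate
        out.loc[mask, col] = pd.NA
    return out


def generate_pooled_dataset(config: SyntheticConfig,
                            csv_path: str | Path | None = None,
                            truth_path: str | Path | None = None,
                            ) -> tuple[pd.DataFrame, dict]:
    """Full synthetic dataset plus the truth sidecar used by recovery tests.

    Returns ``(records, truth)`` and, when paths are given, writes the
    analysis-ready CSV (missing cells as empty fields) and a JSON sidecar
    recording the generating parameters.
    """
    seeds = config.child_seeds()
    df = generate_covariates(config, np.random.default_rng(seeds["covariates"]))
    df = generate_outcomes(df, config, np.random.default_rng(seeds["outcomes"]))
    if (isinstance(config.missing_rate, dict) and any(v > 0 for v in config.missing_rate.values())) \
            or (not isinstance(config.missing_rate, dict) and config.missing_rate > 0):
        df = _inject_missing(df, config, np.random.default_rng(seeds["missing"]))
    truth = config.truth()
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if truth_path is not None:
        Path(truth_path).write_text(json.dumps(truth, indent=2, sort_keys=True))
    logger.info("generated %d synthetic records (seed %d)", len(df), config.seed)
    return df, truth
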