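"""Interaction contrasts: residence gaps and per-year trends with delta-method CIs.

The regression codes the survey year as a quantitative variable t = 1..4
with a rural-by-year interaction, so two families of mean ratios follow
directly from linear contrasts ``a`` of the coefficient vector:

* rural vs urban within survey year t: ``exp(b_rural + t * b_int)``;
* per-coded-year trend: ``exp(b_year)`` in urban areas and
  ``exp(b_year + b_int)`` in rural areas.

For a contrast ratio ``r = exp(a' beta)`` the delta method gives
``SE(r) = r * sqrt(a' V a)``; intervals are formed on the log scale and
exponentiated by default so the bounds stay positive, with a
symmetric-on-ratio alternative behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import YEAR
from .fit import ZOIPFitResult

__all__ = ["ContrastRatio", "contrast_mean_ratio", "rural_urban_trend_table"]

_RURAL = "residence[rural]"
_INTERACTION = f"{YEAR}:residence[rural]"


@dataclass
class ContrastRatio:
    """A mean ratio ``exp(a' beta)`` with delta-method uncertainty."""

    description: str
    contrast: np.ndarray
    ratio: float
    se: float
    ci_low: float
    ci_high: float


def _contrast_vector(fit: ZOIPFitResult, a) -> np.ndarray:
    p = len(fit.column_labels)
    if isinstance(a, dict):
        vec = np.zeros(p)
        for label, w in a.items():
            if label not in fit.column_labels:
                raise KeyError(f"no coefficient labelled {label!r} in the fit")
            vec[fit.column_labels.index(label)] = w
        return vec
    vec = np.asarray(a, dtype=float)
    if vec.shape != (p,):
        raise ValueError(f"contrast length {vec.shape} does not match p={p}")
    return vec


def contrast_mean_ratio(fit: ZOIPFitResult, a, *, description: str = "",
                        z: float = 1.96, symmetric: bool = False) -> ContrastRatio:
    """Mean ratio for a linear contrast of the regression coefficients.

    ``a`` is either a vector over the fit's coefficient labels or a
    ``{label: weight}`` mapping (unnamed coefficients get weight 0).
    """
    vec = _contrast_vector(fit, a)
    p = len(fit.column_labels)
    V = fit.vcov[:p, :p]
    if not np.all(np.isfinite(np.diag(V))):
        raise ValueError("fit carries no usable variance-covariance matrix")
    est = float(vec @ fit.params.beta)
    var = float(vec @ V @ vec)
    sd = np.sqrt(max(var, 0.0))
    ratio = float(np.exp(est))
    se = ratio * sd
    if symmetric:
        lo, hi = ratio - z * se, ratio + z * se
    else:
        lo, hi = ratio * np.exp(-z * sd), ratio * np.exp(z * sd)
    return ContrastRatio(description=description, contrast=vec, ratio=ratio,
                         se=se, ci_low=float(lo), ci_high=float(hi))


def rural_urban_trend_table(fit: ZOIPFitResult, *, symmetric: bool = False):
    """Both contrast families from one fit.

    Returns ``(gap, trend)``: four rural-vs-urban ratios (one per survey
    year code) and the two area-specific per-year trend ratios.
    """
    for needed in (_RURAL, YEAR, _INTERACTION):
        if needed not in fit.column_labels:
            raise KeyError(f"fit lacks the required coefficient {needed!r}")
    gap = [
        contrast_mean_ratio(
            fit, {_RURAL: 1.0, _INTERACTION: float(t)},
            description=f"rural vs urban, year code {t}", symmetric=symmetric)
        for t in (1, 2, 3, 4)
    ]
    trend = [
        contrast_mean_ratio(fit, {YEAR: 1.0},
                            description="per-year trend, urban",
                            symmetric=symmetric),
        contrast_mean_ratio(fit, {YEAR: 1.0, _INTERACTION: 1.0},
                            description="per-year trend, rural",
                            symmetric=symmetric),
    ]
    return gap, trend
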