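"""The zero-and-one-inflated Poisson (ZOIP) probability model.

A ZOIP outcome is a three-component mixture: a point mass at zero with
probability ``phi0`` (structural zeros), a point mass at one with
probability ``phi1`` (structural ones), and a Poisson(lambda) component
with the remaining probability ``phi2 = 1 - phi0 - phi1``:

    P(Y = 0) = phi0 + phi2 * exp(-lam)
    P(Y = 1) = phi1 + phi2 * lam * exp(-lam)
    P(Y = y) = phi2 * lam**y * exp(-lam) / y!          for y > 1

Covariates enter through a log link on the Poisson mean,
``log(lam_i) = x_i' beta``; the inflation masses carry no covariates.
This module holds the pmf/log-pmf, the mixture mean, a sampler, and the
regression log-likelihood; estimation lives in :mod:`zoipanc.fit`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .data_model import DesignMatrix

__all__ = ["ZOIPParams", "zoip_pmf", "zoip_logpmf", "zoip_mean", "zoip_sample", "zoip_loglik"]

#: Linear predictors beyond this overflow exp(); evaluation is refused, not clipped.
_ETA_MAX = 700.0


def _check_masses(phi0: float, phi1: float, allow_boundary: bool = True) -> None:
    if not (np.isfinite(phi0) and np.isfinite(phi1)):
        raise ValueError("inflation masses must be finite")
    lo = 0.0
    if (phi0 < lo) or (phi1 < lo) or (phi0 + phi1 >= 1.0):
        raise ValueError(
            f"invalid inflation masses phi0={phi0}, phi1={phi1}: "
            "need phi0 >= 0, phi1 >= 0 and phi0 + phi1 < 1")


def _check_lam(lam) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if not np.all(np.isfinite(lam)) or np.any(lam <= 0):
        raise ValueError("lam must be finite and > 0")
    return lam


@dataclass
class ZOIPParams:
    """Full parameter set of the ZOIP regression.

    ``beta`` are the regression coefficients on the log-lambda scale;
    ``phi0`` and ``phi1`` are the structural zero/one masses, with
    ``phi2 = 1 - phi0 - phi1`` the Poisson-component weight.
    """

    beta: np.ndarray
    phi0: float
    phi1: float

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")
        _check_masses(self.phi0, self.phi1)

    @property
    def phi2(self) -> float:
        return 1.0 - self.phi0 - self.phi1


def zoip_logpmf(y, lam, phi0: float, phi1: float) -> np.ndarray:
    """Log probability mass, stable for counts up to the hundreds.

    The y=0 and y=1 branches are sums of a point mass and a Poisson term;
    they are combined with log-sum-exp so that neither addend underflows
    the other for large ``lam``.
    """
    _check_masses(phi0, phi1)
    lam = _check_lam(lam)
    y = np.asarray(y)
    if np.any(y < 0) or not np.issubdtype(np.asarray(y).dtype, np.integer):
        y = np.asarray(y, dtype=float)
        if np.any((y < 0) | (y != np.floor(y))):
            raise ValueError("y must contain non-negative integers")
    y, lam = np.broadcast_arrays(np.asarray(y, dtype=float), lam)
    phi2 = 1.0 - phi0 - phi1
    log_phi2 = np.log(phi2)
    with np.errstate(divide="ignore"):
        log_lam = np.log(lam)
    base = log_phi2 + y * log_lam - lam - gammaln(y + 1.0)
    out = np.array(base, dtype=float)
    m0 = y == 0
    if np.any(m0):
        pois0 = log_phi2 - lam[m0]
        out[m0] = np.logaddexp(np.log(phi0), pois0) if phi0 > 0 else pois0
    m1 = y == 1
    if np.any(m1):
        pois1 = log_phi2 + log_lam[m1] - lam[m1]
        out[m1] = np.logaddexp(np.log(phi1), pois1) if phi1 > 0 else pois1
    return out if out.ndim else float(out)


def zoip_pmf(y, lam, phi0: float, phi1: float) -> np.ndarray:
    """Probability mass of the ZOIP mixture."""
    return np.exp(zoip_logpmf(y, lam, phi0, phi1))


def zoip_mean(lam, phi0: float, phi1: float):
    """Mixture mean: ``phi1 + phi2 * lam`` (structural zeros contribute 0)."""
    _check_masses(phi0, phi1)
    lam = _check_lam(lam)
    out = phi1 + (1.0 - phi0 - phi1) * lam
    return out if out.ndim else float(out)


def zoip_sample(lam, phi0: float, phi1: float, *, n: int | None = None,
                seed=None) -> np.ndarray:
    """Draw ZOIP variates.

    ``lam`` may be a scalar (with ``n`` giving the sample size) or a vector
    of per-observation Poisson means.  ``phi0 = 1`` is tolerated here as a
    degenerate testing boundary.  Deterministic for a fixed ``seed``.
    """
    if not (0 <= phi0 <= 1 and 0 <= phi1 <= 1 and phi0 + phi1 <= 1):
        raise ValueError("inflation masses must lie in the probability simplex")
    lam = np.asarray(lam, dtype=float)
    if lam.ndim == 0:
        if n is None or n <= 0:
            raise ValueError("scalar lam requires a positive sample size n")
        lam = np.full(n, float(lam))
    elif n is not None and n != lam.shape[0]:
        raise ValueError("n disagrees with len(lam)")
    if lam.shape[0] <= 0:
        raise ValueError("sample size must be positive")
    _check_lam(lam)
    rng = np.random.default_rng(seed)
    u = rng.random(lam.shape[0])
    pois = rng.poisson(lam)
    return np.where(u < phi0, 0, np.where(u < phi0 + phi1, 1, pois))


def zoip_loglik(params: ZOIPParams, design: DesignMatrix) -> float:
    """Regression log-likelihood ``A + B + C``.

    ``A`` sums ``log(phi0 + phi2 exp(-lam_i))`` over zero counts, ``B``
    sums ``log(phi1 + phi2 lam_i exp(-lam_i))`` over one counts, and ``C``
    sums ``y_i log lam_i - lam_i + log phi2 - log y_i!`` over counts above
    one, with ``lam_i = exp(x_i' beta)``.  Identical to the sum of
    :func:`zoip_logpmf` over observations.
    """
    if design.y is None:
        raise ValueError("design has no outcome vector")
    if design.X.shape[1] != params.beta.shape[0]:
        raise ValueError(
            f"dimension mismatch: X has {design.X.shape[1]} columns, "
            f"beta has {params.beta.shape[0]} entries")
    eta = design.X @ params.beta
    if not np.all(np.isfinite(eta)) or np.max(np.abs(eta)) > _ETA_MAX:
        raise FloatingPointError(
            "linear predictor overflows exp(); largest |x_i' beta| = "
            f"{np.max(np.abs(eta)):.3g}")
    y = np.asarray(design.y)
    lam = np.exp(eta)
    phi0, phi1 = params.phi0, params.phi1
    phi2 = params.phi2
    log_phi2 = np.log(phi2)

    m0, m1 = y == 0, y == 1
    m2 = ~m0 & ~m1
    a_terms = log_phi2 - lam[m0]
    if phi0 > 0:
        a_terms = np.logaddexp(np.log(phi0), a_terms)
    b_terms = log_phi2 + eta[m1] - lam[m1]
    if phi1 > 0:
        b_terms = np.logaddexp(np.log(phi1), b_terms)
    A = float(np.sum(a_terms))
    B = float(np.sum(b_terms))
    C = float(np.sum(y[m2] * eta[m2] - lam[m2] + log_phi2 - gammaln(y[m2] + 1.0)))
    return A + B + C
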