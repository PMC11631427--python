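"""Negative binomial distribution: PMF, median, and maximum-likelihood fit.

Parameterization
----------------
The PMF used throughout is

    P(k | n, p) = C(k + n - 1, n - 1) * p**n * (1 - p)**k,   k = 0, 1, 2, ...

with dispersion/size ``n > 0`` (real, generalized through the gamma
function) and success probability ``p in (0, 1)``, so that

    mean = n * (1 - p) / p,      variance = n * (1 - p) / p**2.

This matches ``scipy.stats.nbinom(n, p)``.  Some libraries swap the roles
of ``p`` and ``1 - p``; conversions are the caller's responsibility.

Fitting minimizes the negative log-likelihood with a derivative-free
simplex search on transformed coordinates ``(log n, logit p)`` so the
constraints ``n > 0``, ``0 < p < 1`` hold by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, gammaln, logit

from .errors import DegenerateDataError

__all__ = [
    "NBParams",
    "FitConfig",
    "FitDiagnostics",
    "nb_pmf",
    "nb_logpmf",
    "nb_median",
    "nb_moment_estimate",
    "fit_nb_mle",
]

# Clips applied inside optimizer objectives so that wandering simplex
# vertices can never produce NaN likelihoods.
_N_MIN, _N_MAX = 1e-9, 1e9
_P_EPS = 1e-12


@dataclass(frozen=True)
class NBParams:
    """Parameters (n, p) of one negative binomial component."""

    n: float
    p: float

    def __post_init__(self) -> None:
        if not (self.n > 0 and math.isfinite(self.n)):
            raise ValueError(f"n must be a positive finite real, got {self.n}")
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"p must lie in (0, 1), got {self.p}")

    @property
    def mean(self) -> float:
        return self.n * (1.0 - self.p) / self.p

    @property
    def variance(self) -> float:
        return self.n * (1.0 - self.p) / self.p**2

    def to_dict(self) -> dict:
        return {"n": self.n, "p": self.p}


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for the simplex NLL minimization."""

    tol: float = 1e-8          # convergence tolerance on the NLL
    maxiter: int = 500         # simplex iterations for a single NB fit
    maxiter_mixture: int = 2000  # iterations for 5-parameter mixture fits


@dataclass(frozen=True)
class FitDiagnostics:
    """Goodness-of-fit and optimizer bookkeeping for one fit."""

    nll: float
    aic: float
    bic: float
    converged: bool
    iterations: int
    sample_size: int
    n_free: int = field(default=2)

    def to_dict(self) -> dict:
        return {
            "nll": self.nll, "aic": self.aic, "bic": self.bic,
            "converged": self.converged, "iterations": self.iterations,
            "sample_size": self.sample_size, "n_free": self.n_free,
        }


def information_criteria(nll: float, n_free: int, n_obs: int) -> tuple[float, float]:
    """AIC and BIC from a negative log-likelihood.

    aic = 2 * n_free + 2 * nll;  bic = n_free * ln(n_obs) + 2 * nll.
    """
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    aic = 2.0 * n_free + 2.0 * nll
    bic = n_free * math.log(n_obs) + 2.0 * nll
    return aic, bic


def _validate_k(k) -> np.ndarray:
    k = np.asarray(k)
    if k.size and (np.any(k < 0) or np.any(k != np.floor(k))):
        raise ValueError("k must contain nonnegative integers")
    return k.astype(np.int64)


def nb_logpmf(k, params: NBParams):
    """Log-PMF via log-gamma; numerically safe for very large k."""
    k = _validate_k(k)
    n, p = params.n, params.p
    out = (
        gammaln(k + n) - gammaln(n) - gammaln(k + 1)
        + n * math.log(p) + k * math.log1p(-p)
    )
    return out if out.shape else float(out)


def nb_pmf(k, params: NBParams):
    """PMF of the negative binomial, C(k+n-1, n-1) p^n (1-p)^k."""
    out = np.exp(nb_logpmf(k, params))
    return out if np.ndim(out) else float(out)


def nb_median(params: NBParams) -> int:
    """Smallest integer m with CDF(m) >= 0.5."""
    return int(stats.nbinom.ppf(0.5, params.n, params.p))


def nb_moment_estimate(counts) -> NBParams:
    """Method-of-moments (n, p); near-Poisson fallback when not overdispersed.

    Used only as an initialization / fallback, never as the reported fit.
    """
    counts = np.asarray(counts, dtype=float)
    m = counts.mean()
    v = counts.var(ddof=1) if counts.size > 1 else 0.0
    m = max(m, 1e-6)
    if v > m:
        p = m / v
        n = m * m / (v - m)
    else:  # under/equi-dispersed: large n approximates a Poisson with this mean
        n = 100.0
        p = n / (n + m)
    return NBParams(n=float(np.clip(n, _N_MIN, _N_MAX)),
                    p=float(np.clip(p, _P_EPS, 1 - 1e-9)))


def _weighted_nll(unique: np.ndarray, weights: np.ndarray, n: float, p: float) -> float:
    lp = (
        gammaln(unique + n) - gammaln(n) - gammaln(unique + 1)
        + n * math.log(p) + unique * math.log1p(-p)
    )
    return float(-(weights * lp).sum())


def fit_nb_mle(
    counts,
    init: NBParams | None = None,
    config: FitConfig | None = None,
) -> tuple[NBParams, FitDiagnostics]:
    """Maximum-likelihood fit of a single negative binomial to counts.

    The default start is (n, p) = (1, 1) with p clipped just inside the
    open domain; the simplex then searches in (log n, logit p).

    Raises
    ------
    ValueError
        If ``counts`` is empty.
    DegenerateDataError
        If all counts are identical (zero variance admits no interior MLE).
    """
    counts = _validate_k(counts)
    if counts.size == 0:
        raise ValueError("cannot fit on empty counts")
    unique, weights = np.unique(counts, return_counts=True)
    if unique.size < 2:
        raise DegenerateDataError(
            f"all {counts.size} counts equal {int(unique[0])}: zero-variance data "
            "has no interior NB MLE; handle this case upstream"
        )
    config = config or FitConfig()
    if init is None:
        init = NBParams(n=1.0, p=1.0 - 1e-6)
    x0 = np.array([math.log(init.n), logit(init.p)])
    w = weights.astype(float)

    def objective(x: np.ndarray) -> float:
        n = float(np.clip(np.exp(x[0]), _N_MIN, _N_MAX))
        p = float(np.clip(expit(x[1]), _P_EPS, 1 - _P_EPS))
        return _weighted_nll(unique, w, n, p)

    res = optimize.minimize(
        objective, x0, method="Nelder-Mead",
        options={"fatol": config.tol, "xatol": 1e-6,
                 "maxiter": config.maxiter, "maxfev": 4 * config.maxiter},
    )
    params = NBParams(
        n=float(np.clip(np.exp(res.x[0]), _N_MIN, _N_MAX)),
        p=float(np.clip(expit(res.x[1]), _P_EPS, 1 - _P_EPS)),
    )
    nll = float(res.fun)
    aic, bic = information_criteria(nll, 2, counts.size)
    diag = FitDiagnostics(nll=nll, aic=aic, bic=bic, converged=bool(res.success),
                          iterations=int(res.nit), sample_size=int(counts.size),
                          n_free=2)
    return params, diag
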