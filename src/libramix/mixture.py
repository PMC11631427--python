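"""Two-component negative binomial mixture: fit, label, posterior.

The donor-cell UMI counts for one antigen are modeled as

    P(k) = omega * NB(k | n1, p1) + (1 - omega) * NB(k | n2, p2)

where the two components are a priori exchangeable.  After fitting, the
component with the higher median is labeled "Signal" (true antigen
binding) and the other "Noise" (ambient/dissociated barcodes and
non-specific capture); all reported quantities are derived from these
post-hoc labels, so results do not depend on slot order.

Two initialization strategies are provided:

* control-biased: the noise slot starts at a single-NB MLE of the
  negative-control (e.g. VRC01-expressing) cells' counts, which are pure
  technical noise by construction;
* percentile-based: the donor counts are split at the (1 - omega0)-th
  quantile and each part is fitted separately — used when no control
  cells were recovered.

Per-count signal probabilities follow from Bayes' theorem applied to the
fitted mixture:  P_noise(k) = w_N * NB_N(k) / P(k),  P_signal = 1 - P_noise,
evaluated in log space so extreme counts never produce 0/0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize
from scipy.special import expit, logit, logsumexp

from .errors import DegenerateDataError
from .nb import (
    _N_MAX,
    _N_MIN,
    _P_EPS,
    FitConfig,
    FitDiagnostics,
    NBParams,
    fit_nb_mle,
    information_criteria,
    nb_logpmf,
    nb_median,
    nb_moment_estimate,
    nb_pmf,
)

logger = logging.getLogger(__name__)

NOISE = "noise"
SIGNAL = "signal"

__all__ = [
    "MixtureParams",
    "PosteriorResult",
    "mixture_pmf",
    "mixture_logpmf",
    "mixture_nll",
    "init_from_control",
    "init_percentile",
    "fit_mixture",
    "assign_labels",
    "posterior",
    "classify",
]


@dataclass(frozen=True)
class MixtureParams:
    """Weight omega on comp1, two NB components, and optional post-hoc labels."""

    omega: float
    comp1: NBParams
    comp2: NBParams
    labels: tuple[str, str] | None = None  # (label of comp1, label of comp2)

    def __post_init__(self) -> None:
        if not (0.0 < self.omega < 1.0):
            raise ValueError(f"omega must lie in (0, 1), got {self.omega}")
        if self.labels is not None and sorted(self.labels) != [NOISE, SIGNAL]:
            raise ValueError(f"labels must be a permutation of (noise, signal), got {self.labels}")

    @property
    def is_labeled(self) -> bool:
        return self.labels is not None

    def _require_labels(self) -> None:
        if self.labels is None:
            raise ValueError("components are unlabeled; call assign_labels first")

    @property
    def noise(self) -> NBParams:
        self._require_labels()
        return self.comp1 if self.labels[0] == NOISE else self.comp2

    @property
    def signal(self) -> NBParams:
        self._require_labels()
        return self.comp1 if self.labels[0] == SIGNAL else self.comp2

    @property
    def noise_weight(self) -> float:
        self._require_labels()
        return self.omega if self.labels[0] == NOISE else 1.0 - self.omega

    @property
    def signal_weight(self) -> float:
        return 1.0 - self.noise_weight

    def to_dict(self) -> dict:
        d = {"omega": self.omega, "comp1": self.comp1.to_dict(),
             "comp2": self.comp2.to_dict()}
        if self.labels is not None:
            d["labels"] = list(self.labels)
        return d


@dataclass(frozen=True)
class PosteriorResult:
    """Per-cell signal/noise posteriors and threshold calls for one antigen."""

    k: np.ndarray
    p_signal: np.ndarray
    p_noise: np.ndarray
    calls: np.ndarray          # "signal" / "noise" strings
    threshold: float
    cell_ids: list[str] | None = None

    @property
    def mean_p_signal(self) -> float:
        return float(self.p_signal.mean())


def mixture_pmf(k, params: MixtureParams):
    """omega * pmf1(k) + (1 - omega) * pmf2(k)."""
    out = params.omega * nb_pmf(k, params.comp1) + (1.0 - params.omega) * nb_pmf(k, params.comp2)
    return out if np.ndim(out) else float(out)


def mixture_logpmf(k, params: MixtureParams):
    """Log mixture PMF via log-sum-exp (stable far into either tail)."""
    a = math.log(params.omega) + nb_logpmf(k, params.comp1)
    b = math.log1p(-params.omega) + nb_logpmf(k, params.comp2)
    out = np.logaddexp(a, b)
    return out if np.ndim(out) else float(out)


def mixture_nll(counts, params: MixtureParams) -> float:
    """Negative log-likelihood of counts under the mixture."""
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("empty counts")
    unique, weights = np.unique(counts, return_counts=True)
    return float(-(weights * mixture_logpmf(unique, params)).sum())


def _fit_part_or_fallback(part: np.ndarray, full: np.ndarray,
                          config: FitConfig | None, what: str) -> NBParams:
    part = np.asarray(part)
    if part.size >= 2 and np.unique(part).size >= 2:
        try:
            fitted, _ = fit_nb_mle(part, config=config)
            return fitted
        except DegenerateDataError:
            pass
    logger.warning(
        "%s partition degenerate (%d values); falling back to moment estimates "
        "of the full data", what, part.size)
    return nb_moment_estimate(full)


def init_percentile(donor_counts, omega0: float = 0.1,
                    config: FitConfig | None = None) -> MixtureParams:
    """Initialize the mixture by splitting counts at the (1 - omega0) quantile.

    The lower part seeds the lower-median (noise) slot, the upper part the
    higher-median (signal) slot, and the weight starts at ``omega0``.  Used
    on its own when no negative-control cells exist, and for the signal
    slot of :func:`init_from_control`.
    """
    donor_counts = np.asarray(donor_counts)
    if donor_counts.size == 0:
        raise ValueError("empty donor counts")
    if not (0.0 < omega0 < 1.0):
        raise ValueError("omega0 must lie in (0, 1)")
    cut = np.percentile(donor_counts, (1.0 - omega0) * 100.0)
    lower = donor_counts[donor_counts <= cut]
    upper = donor_counts[donor_counts > cut]
    comp_lo = _fit_part_or_fallback(lower, donor_counts, config, "lower")
    comp_hi = _fit_part_or_fallback(upper, donor_counts, config, "upper")
    return MixtureParams(omega=omega0, comp1=comp_lo, comp2=comp_hi)


def init_from_control(control_counts, donor_counts, omega0: float = 0.1,
                      config: FitConfig | None = None) -> MixtureParams:
    """Control-biased initialization: noise slot from the control-cell fit.

    Falls back to :func:`init_percentile` when the control counts are
    empty or degenerate.
    """
    control_counts = np.asarray(control_counts)
    perc = init_percentile(donor_counts, omega0, config)
    if control_counts.size < 2:
        logger.warning("no usable control counts; using percentile initialization")
        return perc
    try:
        noise_fit, _ = fit_nb_mle(control_counts, config=config)
    except DegenerateDataError:
        logger.warning("degenerate control counts; using percentile initialization")
        return perc
    return MixtureParams(omega=omega0, comp1=noise_fit, comp2=perc.comp2)


def fit_mixture(donor_counts, init: MixtureParams,
                config: FitConfig | None = None) -> tuple[MixtureParams, FitDiagnostics]:
    """Jointly minimize the mixture NLL over (omega, n1, p1, n2, p2).

    The search runs on transformed coordinates (logit omega, log n, logit p
    per component) with a derivative-free simplex.  All five parameters are
    free: the control fit only biases the start, it does not constrain the
    optimum.  Labels are left unassigned.
    """
    counts = np.asarray(donor_counts)
    if counts.size == 0 or np.unique(counts).size < 2:
        raise DegenerateDataError("mixture fit requires >= 2 distinct counts")
    config = config or FitConfig()
    unique, weights = np.unique(counts, return_counts=True)
    w = weights.astype(float)
    lgk = np.array([math.lgamma(k + 1) for k in unique])  # constant over the fit

    from scipy.special import gammaln

    def objective(x: np.ndarray) -> float:
        om = float(np.clip(expit(x[0]), 1e-9, 1 - 1e-9))
        n1 = float(np.clip(np.exp(x[1]), _N_MIN, _N_MAX))
        p1 = float(np.clip(expit(x[2]), _P_EPS, 1 - _P_EPS))
        n2 = float(np.clip(np.exp(x[3]), _N_MIN, _N_MAX))
        p2 = float(np.clip(expit(x[4]), _P_EPS, 1 - _P_EPS))
        l1 = gammaln(unique + n1) - gammaln(n1) - lgk + n1 * math.log(p1) + unique * math.log1p(-p1)
        l2 = gammaln(unique + n2) - gammaln(n2) - lgk + n2 * math.log(p2) + unique * math.log1p(-p2)
        ll = logsumexp(np.stack([math.log(om) + l1, math.log1p(-om) + l2]), axis=0)
        return float(-(w * ll).sum())

    x0 = np.array([
        logit(init.omega),
        math.log(init.comp1.n), logit(init.comp1.p),
        math.log(init.comp2.n), logit(init.comp2.p),
    ])
    res = optimize.minimize(
        objective, x0, method="Nelder-Mead",
        options={"fatol": config.tol, "xatol": 1e-6,
                 "maxiter": config.maxiter_mixture,
                 "maxfev": 4 * config.maxiter_mixture},
    )
    fitted = MixtureParams(
        omega=float(np.clip(expit(res.x[0]), 1e-9, 1 - 1e-9)),
        comp1=NBParams(float(np.clip(np.exp(res.x[1]), _N_MIN, _N_MAX)),
                       float(np.clip(expit(res.x[2]), _P_EPS, 1 - _P_EPS))),
        comp2=NBParams(float(np.clip(np.exp(res.x[3]), _N_MIN, _N_MAX)),
                       float(np.clip(expit(res.x[4]), _P_EPS, 1 - _P_EPS))),
    )
    nll = float(res.fun)
    aic, bic = information_criteria(nll, 5, counts.size)
    diag = FitDiagnostics(nll=nll, aic=aic, bic=bic, converged=bool(res.success),
                          iterations=int(res.nit), sample_size=int(counts.size),
                          n_free=5)
    return fitted, diag


def assign_labels(params: MixtureParams) -> MixtureParams:
    """Label the higher-median component Signal, the other Noise.

    Ties on the median are broken by the higher mean; a full tie labels
    comp2 Signal (deterministic slot-order rule).
    """
    m1, m2 = nb_median(params.comp1), nb_median(params.comp2)
    if m1 != m2:
        comp1_is_signal = m1 > m2
    elif params.comp1.mean != params.comp2.mean:
        comp1_is_signal = params.comp1.mean > params.comp2.mean
    else:
        comp1_is_signal = False
    labels = (SIGNAL, NOISE) if comp1_is_signal else (NOISE, SIGNAL)
    return replace(params, labels=labels)


def posterior(k, params: MixtureParams):
    """Bayes posterior (p_noise, p_signal) for UMI count(s) k.

    p_noise = w_N * NB_N(k) / mixture(k), computed in log space;
    p_signal is its exact complement so the pair always sums to 1.
    """
    params._require_labels()
    k = np.asarray(k)
    ln = math.log(params.noise_weight) + nb_logpmf(k, params.noise)
    ls = math.log(params.signal_weight) + nb_logpmf(k, params.signal)
    denom = np.logaddexp(ln, ls)
    p_noise = np.exp(ln - denom)
    p_signal = 1.0 - p_noise
    if p_noise.shape:
        return p_noise, p_signal
    return float(p_noise), float(p_signal)


def classify(counts, params: MixtureParams, threshold: float = 0.5,
             cell_ids: list[str] | None = None) -> PosteriorResult:
    """Threshold the signal posterior: call = signal iff p_signal >= threshold."""
    counts = np.atleast_1d(np.asarray(counts))
    p_noise, p_signal = posterior(counts, params)
    p_noise, p_signal = np.atleast_1d(p_noise), np.atleast_1d(p_signal)
    calls = np.where(p_signal >= threshold, SIGNAL, NOISE)
    return PosteriorResult(k=counts, p_signal=p_signal, p_noise=p_noise,
                           calls=calls, threshold=float(threshold),
                           cell_ids=list(cell_ids) if cell_ids is not None else None)
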