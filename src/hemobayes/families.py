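"""The three likelihood families used throughout the pipeline.

Every marginal model in the package is one of

* ``normal`` — Normal(mu, sigma);
* ``student_t`` — location–scale Student-t(mu, sigma, nu), nu > 1 so that
  the mean exists (the treatment-effect test is a statement about a mean);
* ``skew_normal`` — Azzalini skew-normal(xi, omega, alpha) with density
  ``2/omega * phi((y-xi)/omega) * Phi(alpha*(y-xi)/omega)``; alpha = 0
  recovers the normal exactly.

The module is a thin, validated facade over ``scipy.stats`` with a uniform
(family, params) calling convention, plus the closed-form moments the
effect analysis and the synthetic generator need.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError

NORMAL = "normal"
STUDENT_T = "student_t"
SKEW_NORMAL = "skew_normal"

#: Families in increasing order of structural complexity.  The order is
#: load-bearing: model selection breaks exact ties in favour of the
#: earlier (simpler) family.
FAMILIES = (NORMAL, STUDENT_T, SKEW_NORMAL)

#: Human-readable labels used in report tables.
FAMILY_LABELS = {NORMAL: "Normal", STUDENT_T: "Student t", SKEW_NORMAL: "Skew normal"}

_PARAM_NAMES = {
    NORMAL: ("mu", "sigma"),
    STUDENT_T: ("mu", "sigma", "nu"),
    SKEW_NORMAL: ("xi", "omega", "alpha"),
}


@dataclass(frozen=True)
class NormalParams:
    mu: float
    sigma: float

    def __post_init__(self):
        if not (self.sigma > 0):
            raise DomainError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class StudentTParams:
    mu: float
    sigma: float
    nu: float

    def __post_init__(self):
        if not (self.sigma > 0):
            raise DomainError(f"sigma must be positive, got {self.sigma}")
        if not (self.nu > 1):
            raise DomainError(f"nu must exceed 1 (finite mean), got {self.nu}")


@dataclass(frozen=True)
class SkewNormalParams:
    xi: float
    omega: float
    alpha: float

    def __post_init__(self):
        if not (self.omega > 0):
            raise DomainError(f"omega must be positive, got {self.omega}")


PARAM_CLASSES = {
    NORMAL: NormalParams,
    STUDENT_T: StudentTParams,
    SKEW_NORMAL: SkewNormalParams,
}


def param_names(family: str) -> tuple[str, ...]:
    _check_family(family)
    return _PARAM_NAMES[family]


def n_params(family: str) -> int:
    return len(param_names(family))


def make_params(family: str, values):
    """Build the validated params object for ``family`` from a sequence."""
    _check_family(family)
    return PARAM_CLASSES[family](*[float(v) for v in values])


def _check_family(family: str) -> None:
    if family not in FAMILIES:
        raise DomainError(f"unknown family {family!r}; expected one of {FAMILIES}")


def _frozen(family: str, params):
    """scipy frozen distribution for (family, params)."""
    if family == NORMAL:
        return stats.norm(loc=params.mu, scale=params.sigma)
    if family == STUDENT_T:
        return stats.t(df=params.nu, loc=params.mu, scale=params.sigma)
    if family == SKEW_NORMAL:
        return stats.skewnorm(a=params.alpha, loc=params.xi, scale=params.omega)
    _check_family(family)


def logpdf(family: str, params, y):
    """Log-density of ``family`` at ``y`` (scalar or array)."""
    return _frozen(family, params).logpdf(y)


def pdf(family: str, params, y):
    return _frozen(family, params).pdf(y)


def cdf(family: str, params, y):
    return _frozen(family, params).cdf(y)


def quantile(family: str, params, p):
    """Inverse CDF.  ``p`` strictly inside (0, 1)."""
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr <= 0) or np.any(p_arr >= 1):
        raise DomainError("quantile probability must lie strictly in (0, 1)")
    return _frozen(family, params).ppf(p)


def rng(family: str, params, n: int, seed) -> np.ndarray:
    """``n`` i.i.d. draws, reproducible under ``seed``.

    ``seed`` may be an int, SeedSequence or Generator.
    """
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    gen = np.random.default_rng(seed)
    return _frozen(family, params).rvs(size=n, random_state=gen)


def mean(family: str, params) -> float:
    """Closed-form mean.

    For the skew-normal this is ``xi + omega * delta * sqrt(2/pi)`` with
    ``delta = alpha / sqrt(1 + alpha^2)``.
    """
    if family == NORMAL or family == STUDENT_T:
        return params.mu
    if family == SKEW_NORMAL:
        delta = params.alpha / math.sqrt(1.0 + params.alpha**2)
        return params.xi + params.omega * delta * math.sqrt(2.0 / math.pi)
    _check_family(family)


def sd(family: str, params) -> float:
    """Closed-form standard deviation (infinite for Student-t with nu <= 2)."""
    if family == NORMAL:
        return params.sigma
    if family == STUDENT_T:
        if params.nu <= 2:
            return math.inf
        return params.sigma * math.sqrt(params.nu / (params.nu - 2.0))
    if family == SKEW_NORMAL:
        delta = params.alpha / math.sqrt(1.0 + params.alpha**2)
        return params.omega * math.sqrt(1.0 - 2.0 * delta**2 / math.pi)
    _check_family(family)


# ---------------------------------------------------------------------------
# Vectorised kernels used by the MCMC engine.  They accept a (S, k) matrix
# of parameter vectors (columns in param_names order) and return the
# (S, n) matrix of pointwise log-likelihoods.  Written directly in numpy /
# scipy.special so a sampler step costs microseconds, and kept numerically
# identical to ``logpdf`` (same formulas scipy uses).
# ---------------------------------------------------------------------------

from scipy.special import gammaln, log_ndtr  # noqa: E402

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def loglik_matrix(family: str, theta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pointwise log-likelihood matrix log p(y_j | theta_s), shape (S, n)."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    y = np.asarray(y, dtype=float)[None, :]
    if family == NORMAL:
        mu, sigma = theta[:, 0:1], theta[:, 1:2]
        z = (y - mu) / sigma
        return -0.5 * z**2 - np.log(sigma) - _LOG_SQRT_2PI
    if family == STUDENT_T:
        mu, sigma, nu = theta[:, 0:1], theta[:, 1:2], theta[:, 2:3]
        z = (y - mu) / sigma
        return (
            gammaln((nu + 1.0) / 2.0)
            - gammaln(nu / 2.0)
            - 0.5 * np.log(nu * math.pi)
            - np.log(sigma)
            - (nu + 1.0) / 2.0 * np.log1p(z**2 / nu)
        )
    if family == SKEW_NORMAL:
        xi, omega, alpha = theta[:, 0:1], theta[:, 1:2], theta[:, 2:3]
        z = (y - xi) / omega
        return (
            math.log(2.0)
            - 0.5 * z**2
            - np.log(omega)
            - _LOG_SQRT_2PI
            + log_ndtr(alpha * z)
        )
    _check_family(family)


def mean_of_draws(family: str, theta: np.ndarray) -> np.ndarray:
    """Distribution mean implied by each parameter draw, shape (S,)."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if family in (NORMAL, STUDENT_T):
        return theta[:, 0].copy()
    if family == SKEW_NORMAL:
        xi, omega, alpha = theta[:, 0], theta[:, 1], theta[:, 2]
        delta = alpha / np.sqrt(1.0 + alpha**2)
        return xi + omega * delta * math.sqrt(2.0 / math.pi)
    _check_family(family)


def sample_at_draws(family: str, theta: np.ndarray, gen: np.random.Generator) -> np.ndarray:
    """One draw of y per parameter vector (row of ``theta``)."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    m = theta.shape[0]
    if family == NORMAL:
        return theta[:, 0] + theta[:, 1] * gen.standard_normal(m)
    if family == STUDENT_T:
        return theta[:, 0] + theta[:, 1] * gen.standard_t(theta[:, 2])
    if family == SKEW_NORMAL:
        # Additive representation: Z = delta*|U0| + sqrt(1-delta^2)*U1.
        alpha = theta[:, 2]
        delta = alpha / np.sqrt(1.0 + alpha**2)
        u0 = np.abs(gen.standard_normal(m))
        u1 = gen.standard_normal(m)
        z = delta * u0 + np.sqrt(1.0 - delta**2) * u1
        return theta[:, 0] + theta[:, 1] * z
    _check_family(family)
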