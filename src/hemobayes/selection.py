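"""Model comparison by approximate leave-one-out cross-validation.

The expected log pointwise predictive density under leave-one-out
(elpd_loo) is estimated from the posterior sample by Pareto-smoothed
importance sampling (PSIS).  Observations whose Pareto shape diagnostic
exceeds 0.7 — where the importance-sampling estimate is unreliable —
are handled by an exact fallback: the model is refitted without that
observation and its predictive density evaluated directly.

The family with the highest elpd_loo among converged fits wins; exact
ties break toward the structurally simpler family (Normal < Student-t <
Skew-Normal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)
    import arviz as az

from . import families
from .engine import FitConfig, PosteriorDraws, fit_family
from .errors import SelectionError
from .errors import HemobayesError

#: Pareto shape threshold above which PSIS is considered unreliable for
#: an observation and an exact refit is used instead.
PARETO_K_THRESHOLD = 0.7


@dataclass
class LooResult:
    family: str
    elpd_loo: float
    se_elpd: float
    pointwise_elpd: np.ndarray  # length n
    pareto_k: np.ndarray  # length n
    n_refits: int


@dataclass
class SelectionResult:
    loo_results: dict[str, LooResult]
    selected: str
    #: family -> (elpd difference vs selected, SE of the difference)
    differences: dict[str, tuple[float, float]]


def _relative_efficiency(fit: PosteriorDraws) -> float:
    ess_vals = list(fit.ess.values())
    if not ess_vals:
        return 1.0
    return float(min(1.0, np.mean(ess_vals) / fit.S))


def loo(fit: PosteriorDraws, values=None, refit: bool = True) -> LooResult:
    """PSIS-LOO elpd for one fit, with exact-refit fallback.

    ``values`` defaults to the data vector stored on the fit; passing it
    explicitly only asserts the pointwise matrix matches its length.
    """
    y = fit.y if values is None else np.asarray(list(values), dtype=float)
    loglik = fit.pointwise_loglik  # (S, n)
    if loglik.shape[1] != y.size:
        raise SelectionError(
            f"pointwise log-likelihood has n={loglik.shape[1]} but data has n={y.size}"
        )
    if not np.any(np.isfinite(loglik)):
        raise HemobayesError("all importance weights non-finite")
    reff = _relative_efficiency(fit)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lw, k = az.psislw(-loglik.T, reff=reff)  # (n, S) normalized log-weights
    lw = np.asarray(lw)
    k = np.asarray(k, dtype=float)
    pointwise = logsumexp(lw + loglik.T, axis=1)

    n_refits = 0
    if refit:
        for i in np.flatnonzero(k > PARETO_K_THRESHOLD):
            y_minus = np.delete(y, i)
            sub = fit_family(
                y_minus, fit.family, fit.config.with_seed(fit.config.seed + 7919 * (i + 1))
            )
            ll_i = families.loglik_matrix(fit.family, sub.draws, y[i : i + 1])[:, 0]
            pointwise[i] = logsumexp(ll_i) - np.log(ll_i.size)
            n_refits += 1

    n = y.size
    se = float(np.sqrt(n * np.var(pointwise)))
    return LooResult(
        family=fit.family,
        elpd_loo=float(pointwise.sum()),
        se_elpd=se,
        pointwise_elpd=pointwise,
        pareto_k=k,
        n_refits=n_refits,
    )


def exact_loo(values, family: str, config: FitConfig) -> LooResult:
    """Brute-force exact LOO: one full refit per left-out observation.

    O(n) refits — a reference implementation for verifying the PSIS
    approximation on small samples, not for production use.
    """
    y = np.asarray(list(values), dtype=float)
    n = y.size
    pointwise = np.empty(n)
    for i in range(n):
        sub = fit_family(np.delete(y, i), family, config.with_seed(config.seed + 104729 * (i + 1)))
        ll_i = families.loglik_matrix(family, sub.draws, y[i : i + 1])[:, 0]
        pointwise[i] = logsumexp(ll_i) - np.log(ll_i.size)
    se = float(np.sqrt(n * np.var(pointwise)))
    return LooResult(
        family=family,
        elpd_loo=float(pointwise.sum()),
        se_elpd=se,
        pointwise_elpd=pointwise,
        pareto_k=np.full(n, np.nan),
        n_refits=n,
    )


def select_family(
    fits: dict[str, PosteriorDraws], values=None, refit: bool = True
) -> SelectionResult:
    """Pick the best family by elpd_loo among converged fits."""
    converged = {f: fit for f, fit in fits.items() if fit.converged}
    skipped = sorted(set(fits) - set(converged))
    if skipped:
        warnings.warn(
            f"excluding non-converged fits from selection: {skipped}", stacklevel=2
        )
    if len(converged) < 2:
        raise SelectionError(
            f"need at least 2 converged fits to select, got {len(converged)}"
        )
    results = {f: loo(fit, values, refit=refit) for f, fit in converged.items()}
    # max elpd; exact ties break toward the simpler family (FAMILIES order)
    ordered = [f for f in families.FAMILIES if f in results]
    best = max(ordered, key=lambda f: (results[f].elpd_loo, -ordered.index(f)))
    diffs = {}
    for f, res in results.items():
        d = res.pointwise_elpd - results[best].pointwise_elpd
        diffs[f] = (float(d.sum()), float(np.sqrt(d.size * np.var(d))))
    return SelectionResult(loo_results=results, selected=best, differences=diffs)


def fit_all_families(values, config: FitConfig) -> dict[str, PosteriorDraws]:
    """Fit Normal, Student-t and Skew-Normal to one data vector."""
    return {f: fit_family(values, f, config) for f in families.FAMILIES}
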