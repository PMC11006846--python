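"""Posterior-predictive reference intervals and density-overlay checks.

For each pretreatment variable the selected model's posterior predictive
distribution is sampled (one value per posterior draw, 5000 by default)
and its empirical 1% and 99% quantiles become the reference-interval
endpoints: values outside (Q01_pr, Q99_pr) in future measurements
deserve inspection for gross error or atypical physiology.  The overlay
utility reproduces the usual graphical posterior-predictive check: the
kernel density of the observed sample against densities of replicate
predictive samples of the same size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from . import families
from .engine import PosteriorDraws, posterior_predictive
from .errors import NotConvergedError

#: Number of posterior-predictive draws behind the interval endpoints.
DEFAULT_N_PREDICTIVE = 5000

#: Number of replicate samples in the graphical check.
DEFAULT_N_REPLICATES = 200

_GRID_POINTS = 512
_GRID_PAD = 0.05  # pooled range padded by 5% each side


@dataclass(frozen=True)
class ReferenceInterval:
    variable: str
    family: str
    q01_pr: float
    q99_pr: float
    observed_min: float
    observed_max: float
    n_predictive: int


@dataclass
class PpcOverlay:
    variable: str
    grid: np.ndarray  # (G,)
    data_density: np.ndarray  # (G,)
    replicate_densities: np.ndarray  # (R, G)


def _require_converged(fit: PosteriorDraws) -> None:
    if not fit.converged:
        bad_r = {k: round(v, 4) for k, v in fit.rhat.items()}
        bad_e = {k: round(v, 1) for k, v in fit.ess.items()}
        raise NotConvergedError(
            f"refusing non-converged {fit.family} fit (rhat={bad_r}, ess={bad_e})"
        )


def reference_interval(
    fit: PosteriorDraws,
    observed,
    variable: str = "",
    n_predictive: int | None = None,
    seed=0,
) -> ReferenceInterval:
    """1%/99% posterior-predictive endpoints plus the observed extremes.

    ``n_predictive`` defaults to one predictive value per posterior
    draw (5000 under the default sampler configuration).
    """
    _require_converged(fit)
    obs = np.asarray(list(observed), dtype=float)
    if obs.size == 0:
        raise ValueError("observed sample is empty")
    if n_predictive is None:
        n_predictive = min(DEFAULT_N_PREDICTIVE, fit.S)
    draws = posterior_predictive(fit, n_predictive, seed=seed)
    q01, q99 = np.quantile(draws, [0.01, 0.99])
    return ReferenceInterval(
        variable=variable,
        family=fit.family,
        q01_pr=float(q01),
        q99_pr=float(q99),
        observed_min=float(obs.min()),
        observed_max=float(obs.max()),
        n_predictive=int(n_predictive),
    )


def ppc_overlay(
    fit: PosteriorDraws,
    observed,
    variable: str = "",
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed=0,
) -> PpcOverlay:
    """Kernel-density overlay data for a posterior-predictive check.

    Each replicate is a predictive sample of size ``len(observed)``
    generated at a single posterior draw; all densities (Gaussian
    kernel, Silverman bandwidth) are evaluated on one common grid
    spanning the pooled range of observed and replicate values.
    """
    _require_converged(fit)
    obs = np.asarray(list(observed), dtype=float)
    if obs.size == 0:
        raise ValueError("observed sample is empty")
    gen = np.random.default_rng(seed)
    draw_idx = gen.choice(fit.S, size=n_replicates, replace=n_replicates > fit.S)
    replicates = [
        families.rng(
            fit.family,
            families.make_params(fit.family, fit.draws[s]),
            obs.size,
            gen,
        )
        for s in draw_idx
    ]
    pooled_lo = min(obs.min(), min(r.min() for r in replicates))
    pooled_hi = max(obs.max(), max(r.max() for r in replicates))
    pad = _GRID_PAD * (pooled_hi - pooled_lo)
    grid = np.linspace(pooled_lo - pad, pooled_hi + pad, _GRID_POINTS)
    data_density = gaussian_kde(obs, bw_method="silverman")(grid)
    rep_density = np.vstack(
        [gaussian_kde(r, bw_method="silverman")(grid) for r in replicates]
    )
    return PpcOverlay(
        variable=variable, grid=grid, data_density=data_density, replicate_densities=rep_density
    )
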