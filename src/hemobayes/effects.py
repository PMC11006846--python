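"""Paired-difference treatment-effect analysis.

For each variable with both basal and post-treatment measurements on
the same animals, form D = after - before per animal, screen the
differences with the 3x-IQR extreme-outlier fence, fit the Normal,
Student-t and Skew-Normal families to the kept differences, select by
LOO, and test H0: mu_D = 0 against the posterior of the *mean* of D
under the selected family (for the Skew-Normal the mean implied by a
draw is xi + omega * delta * sqrt(2/pi), not the location parameter).

The decision rule is a posterior tail probability: H0 is rejected when
P[mu_D > 0 | d] is greater than 0.99 or smaller than 0.01 (strict
inequalities).  With S posterior draws the estimated probability has
resolution 1/S; a count of 0 is reported as "< 1/S" and a count of S as
"> 1 - 1/S" (with S = 5000: "< 0.0002" and "> 0.9998").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import families
from .engine import FitConfig
from .errors import InsufficientDataError
from .outliers import screen_variable
from .panel import StudyTable, pair_records
from .selection import SelectionResult, fit_all_families, select_family

REJECT_H0 = "reject_H0"
RETAIN_H0 = "retain_H0"

#: Two-sided posterior tail-probability thresholds of the decision rule.
UPPER_THRESHOLD = 0.99
LOWER_THRESHOLD = 0.01

MIN_PAIRS = 5


@dataclass
class DifferenceSample:
    variable: str
    pairs: pd.DataFrame  # columns animal_id, d
    removed: pd.DataFrame  # same columns; fence-flagged pairs

    @property
    def d(self) -> np.ndarray:
        return self.pairs["d"].to_numpy(dtype=float)

    @property
    def n(self) -> int:
        return len(self.pairs)


@dataclass
class EffectResult:
    variable: str
    family: str
    q01_diff: float
    q99_diff: float
    p_mu_gt0: float
    p_label: str
    decision: str
    n_pairs: int
    selection: SelectionResult | None = None


def build_differences(table: StudyTable, variable: str) -> DifferenceSample:
    """Per-animal after-minus-before differences for one variable."""
    paired = pair_records(table, variable)
    if len(paired) < MIN_PAIRS:
        raise InsufficientDataError(
            f"{variable}: need at least {MIN_PAIRS} complete pairs, got {len(paired)}"
        )
    out = pd.DataFrame(
        {
            "animal_id": paired["animal_id"],
            "d": paired["after"].to_numpy() - paired["before"].to_numpy(),
        }
    )
    empty = out.iloc[0:0]
    return DifferenceSample(variable=variable, pairs=out, removed=empty.copy())


def screen_differences(sample: DifferenceSample) -> DifferenceSample:
    """Apply the extreme-outlier fence to the differences.

    A deterministic stand-in for ad-hoc visual (QQ-plot) removal of
    aberrant pairs: the same 3x-IQR fence used on the marginal strata,
    applied to d.
    """
    d = sample.d
    res = screen_variable(d, sample.variable, "diff")
    inside = (d >= res.l1) & (d <= res.l2)
    kept = sample.pairs.loc[inside].reset_index(drop=True)
    removed = pd.concat(
        [sample.removed, sample.pairs.loc[~inside]], ignore_index=True
    )
    return DifferenceSample(variable=sample.variable, pairs=kept, removed=removed)


def qq_plot_data(sample: DifferenceSample) -> tuple[np.ndarray, np.ndarray]:
    """Standard-normal QQ coordinates for the differences.

    Theoretical quantiles at plotting positions (j - 0.5)/n against the
    sorted differences.
    """
    d = np.sort(sample.d)
    n = d.size
    if n < 3:
        raise InsufficientDataError(f"need at least 3 pairs for a QQ plot, got {n}")
    positions = (np.arange(1, n + 1) - 0.5) / n
    return norm.ppf(positions), d


def format_tail_probability(count_gt0: int, S: int) -> str:
    """Report k/S at its sampling resolution, open-ended at 0 and S."""
    if count_gt0 == 0:
        return f"< {1.0 / S:g}"
    if count_gt0 == S:
        return f"> {1.0 - 1.0 / S:g}"
    return f"{count_gt0 / S:g}"


def effect_analysis(
    sample: DifferenceSample,
    config: FitConfig | None = None,
    refit: bool = True,
) -> EffectResult:
    """Fit, select and test the mean difference for one variable.

    ``q01_diff``/``q99_diff`` are the 1% and 99% empirical quantiles of
    the S posterior draws of the mean of D under the selected family
    (a 98% credible interval for mu_D).
    """
    config = config or FitConfig()
    d = sample.d
    if d.size < MIN_PAIRS:
        raise InsufficientDataError(
            f"{sample.variable}: need at least {MIN_PAIRS} pairs, got {d.size}"
        )
    fits = fit_all_families(d, config)
    selection = select_family(fits, d, refit=refit)
    best = fits[selection.selected]
    mu_draws = families.mean_of_draws(best.family, best.draws)
    q01, q99 = np.quantile(mu_draws, [0.01, 0.99])
    count_gt0 = int(np.count_nonzero(mu_draws > 0.0))
    S = mu_draws.size
    p = count_gt0 / S
    decision = REJECT_H0 if (p > UPPER_THRESHOLD or p < LOWER_THRESHOLD) else RETAIN_H0
    return EffectResult(
        variable=sample.variable,
        family=best.family,
        q01_diff=float(q01),
        q99_diff=float(q99),
        p_mu_gt0=p,
        p_label=format_tail_probability(count_gt0, S),
        decision=decision,
        n_pairs=int(d.size),
        selection=selection,
    )
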