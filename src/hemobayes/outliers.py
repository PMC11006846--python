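"""Extreme-outlier screening with 3x-IQR fences.

Values outside (l1, l2) with

    l1 = Q1 - 3*(Q3 - Q1)
    l2 = Q3 + 3*(Q3 - Q1)

are declared extreme outliers and removed, once, independently per
(variable, treatment) stratum, before any model fitting.  Values exactly
on a fence are kept ("outside" read literally).  Quartiles use the same
type-7 convention as the rest of the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError
from .panel import StudyTable, TREATMENTS

#: Fence multiplier for *extreme* outliers (1.5 would give Tukey's
#: ordinary "outer mild" fences).
EXTREME_MULTIPLIER = 3.0


@dataclass(frozen=True)
class FenceResult:
    variable: str
    treatment: str
    q1: float
    q3: float
    l1: float
    l2: float
    kept: np.ndarray
    removed: np.ndarray


def tukey_fences(q1: float, q3: float, multiplier: float = EXTREME_MULTIPLIER) -> tuple[float, float]:
    """Fence endpoints (l1, l2) from the quartiles."""
    if q1 > q3:
        raise DomainError(f"require q1 <= q3, got q1={q1}, q3={q3}")
    iqr = q3 - q1
    return q1 - multiplier * iqr, q3 + multiplier * iqr


def screen_variable(
    values,
    variable: str = "",
    treatment: str = "",
    multiplier: float = EXTREME_MULTIPLIER,
) -> FenceResult:
    """Partition one stratum's values by the extreme-outlier fences.

    Boundary values (exactly l1 or l2) are kept.  Input order is
    preserved within each partition.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 4:
        raise InsufficientDataError(f"need at least 4 values for quartile fences, got {x.size}")
    q1, q3 = np.quantile(x, [0.25, 0.75])
    l1, l2 = tukey_fences(float(q1), float(q3), multiplier)
    inside = (x >= l1) & (x <= l2)
    return FenceResult(
        variable=variable,
        treatment=treatment,
        q1=float(q1),
        q3=float(q3),
        l1=l1,
        l2=l2,
        kept=x[inside],
        removed=x[~inside],
    )


def screen_table(table: StudyTable) -> tuple[StudyTable, pd.DataFrame]:
    """One-pass screening of every (variable, treatment) stratum.

    Returns the screened table and an audit frame of removed records
    with the fences that excluded them.  Strata with fewer than 4
    observations are passed through unscreened.
    """
    keep_mask = np.ones(len(table.df), dtype=bool)
    audit_rows = []
    for variable in table.variables():
        for treatment in TREATMENTS:
            m = (table.df["variable"] == variable) & (table.df["treatment"] == treatment)
            idx = np.flatnonzero(m.to_numpy())
            if idx.size < 4:
                continue
            x = table.df.loc[m, "value"].to_numpy(dtype=float)
            res = screen_variable(x, variable, treatment)
            outside = (x < res.l1) | (x > res.l2)
            for j in idx[outside]:
                keep_mask[j] = False
                row = table.df.iloc[j]
                audit_rows.append(
                    {
                        "animal_id": row["animal_id"],
                        "treatment": treatment,
                        "variable": variable,
                        "value": row["value"],
                        "l1": res.l1,
                        "l2": res.l2,
                    }
                )
    screened = StudyTable(
        table.df.loc[keep_mask].reset_index(drop=True),
        provenance={**table.provenance, "outliers_removed": int((~keep_mask).sum())},
    )
    audit = pd.DataFrame(
        audit_rows, columns=["animal_id", "treatment", "variable", "value", "l1", "l2"]
    )
    return screened, audit
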