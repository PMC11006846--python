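"""Variable registry, measurement data model and summary statistics.

The measurement panel is the sixteen-analyte hemolymph blood-gas profile
reported by a point-of-care veterinary analyzer: acidity (pH), partial
pressures of CO2 and O2 (raw and temperature-corrected "(TC)" channels),
electrolytes, bicarbonate and derived acid-base quantities, plus
osmolarity.  Data travel through the pipeline as a long-format table of
(animal_id, treatment, variable, value) records, where treatment is
either "Bas" (basal, pre-treatment) or "CO2" (after hypercapnic
cold-water immersion).  A seventeenth, display-only variable log10pCO2
is derived from pCO2 and excluded from the modelling loop.

Quantiles everywhere in the package use linear interpolation between
order statistics ("type 7", the convention of ``numpy.quantile``'s
default), so summary tables are comparable with those produced by
mainstream statistical environments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, DomainError, ValidationError

TREATMENTS = ("Bas", "CO2")

#: Columns of the long-format study-table file, in order.
TABLE_COLUMNS = ("animal_id", "treatment", "variable", "value")

#: Columns of a summary table, mirroring the conventional report layout.
SUMMARY_COLUMNS = (
    "variable",
    "treatment",
    "Min",
    "Q.25",
    "Mean",
    "Q.50",
    "Sd",
    "Q.75",
    "Max",
    "n_obs",
)


@dataclass(frozen=True)
class VariableSpec:
    """Registry entry for one panel variable."""

    name: str
    units: str
    hard_bounds: Optional[tuple[float, float]] = None
    derived: bool = False

    def __post_init__(self):
        if self.hard_bounds is not None:
            lo, hi = self.hard_bounds
            if not lo < hi:
                raise ValidationError(f"hard_bounds must satisfy lo < hi, got {self.hard_bounds}")


def _spec(name, units, bounds, derived=False):
    return VariableSpec(name, units, bounds, derived)


#: The sixteen measured panel variables, in report order, plus the
#: derived log10pCO2 display variable.  Units for "A" (labelled
#: "Alkalosis" by the analyzer) and "Osm" (osmolarity) are not resolved
#: by the instrument documentation available to us and are stored as
#: explicit unknowns.
REGISTRY: dict[str, VariableSpec] = {
    s.name: s
    for s in [
        _spec("pH", "", (0.0, 14.0)),
        _spec("pCO2", "mmHg", (0.0, math.inf)),
        _spec("pO2", "mmHg", (0.0, math.inf)),
        _spec("Na_p", "mmol/L", (0.0, math.inf)),
        _spec("K_p", "mmol/L", (0.0, math.inf)),
        _spec("Cl_m", "mmol/L", (0.0, math.inf)),
        _spec("Ca_pp", "mmol/L", (0.0, math.inf)),
        _spec("TCO2", "mmol/L", (0.0, math.inf)),
        _spec("nCa", "mmol/L", (0.0, math.inf)),
        _spec("pH_TC", "", (0.0, 14.0)),
        _spec("pCO2_TC", "mmHg", (0.0, math.inf)),
        _spec("pO2_TC", "mmHg", (0.0, math.inf)),
        _spec("SBC", "mmol/L", (0.0, math.inf)),
        _spec("HCO3_m", "mmol/L", (0.0, math.inf)),
        _spec("A", "unresolved", (0.0, math.inf)),
        _spec("Osm", "unresolved", (0.0, math.inf)),
        _spec("log10pCO2", "log10(mmHg)", None, derived=True),
    ]
}

#: Names of the sixteen variables entering the modelling loop (the
#: derived log10pCO2 is display-only).
PANEL_VARIABLES = tuple(n for n, s in REGISTRY.items() if not s.derived)


@dataclass(frozen=True)
class MeasurementRecord:
    """One (animal, treatment, variable, value) observation."""

    animal_id: str
    treatment: str
    variable: str
    value: float


@dataclass
class StudyTable:
    """Long-format collection of measurement records plus provenance."""

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"study table missing columns: {missing}")
        self.df = self.df.loc[:, list(TABLE_COLUMNS)].reset_index(drop=True)

    @property
    def records(self) -> list[MeasurementRecord]:
        return [
            MeasurementRecord(str(r.animal_id), str(r.treatment), str(r.variable), float(r.value))
            for r in self.df.itertuples(index=False)
        ]

    def __len__(self) -> int:
        return len(self.df)

    def values(self, variable: str, treatment: str) -> np.ndarray:
        """All values for one (variable, treatment) stratum, input order."""
        m = (self.df["variable"] == variable) & (self.df["treatment"] == treatment)
        return self.df.loc[m, "value"].to_numpy(dtype=float)

    def variables(self) -> list[str]:
        """Variable names present, in registry order then any extras."""
        present = set(self.df["variable"])
        ordered = [n for n in REGISTRY if n in present]
        return ordered + sorted(present - set(ordered))


def _validate_frame(
    df: pd.DataFrame, registry: dict[str, VariableSpec]
) -> tuple[list[str], list[str]]:
    report: list[str] = []
    unknown = sorted(set(df["variable"].astype(str)) - set(registry))
    for name in unknown:
        report.append(f"unknown variable name {name!r}")
    bad_treat = sorted(set(df["treatment"].astype(str)) - set(TREATMENTS))
    for t in bad_treat:
        report.append(f"unknown treatment label {t!r} (expected one of {TREATMENTS})")
    values = pd.to_numeric(df["value"], errors="coerce")
    for idx in df.index[values.isna() | ~np.isfinite(values.fillna(np.nan))]:
        report.append(f"non-numeric or non-finite value in row {idx}: {df.loc[idx, 'value']!r}")
    dup = df.duplicated(subset=["animal_id", "treatment", "variable"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["animal_id", "treatment", "variable"]].drop_duplicates()
        for _, k in keys.iterrows():
            report.append(
                f"duplicate record for animal {k.animal_id!r}, "
                f"treatment {k.treatment!r}, variable {k.variable!r}"
            )
    # hard-bound screening: non-fatal flags (likely unit mix-ups)
    flags: list[str] = []
    for name, spec in registry.items():
        if spec.hard_bounds is None:
            continue
        lo, hi = spec.hard_bounds
        m = (df["variable"] == name) & values.notna()
        out = df.loc[m & ((values < lo) | (values > hi))]
        for idx, row in out.iterrows():
            flags.append(
                f"value {row['value']} for {name} outside hard bounds ({lo}, {hi}) in row {idx}"
            )
    return report, flags


def make_study_table(
    df: pd.DataFrame,
    registry: dict[str, VariableSpec] = REGISTRY,
    provenance: dict | None = None,
) -> StudyTable:
    """Validate a raw frame and wrap it as a :class:`StudyTable`."""
    if len(df) == 0:
        raise ValidationError("empty study table")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"study table missing columns: {missing}")
    report, flags = _validate_frame(df, registry)
    if report:
        raise ValidationError(f"{len(report)} validation problem(s)", report=report)
    out = df.copy()
    out["animal_id"] = out["animal_id"].astype(str)
    out["value"] = out["value"].astype(float)
    prov = dict(provenance or {})
    if flags:
        warnings.warn(f"{len(flags)} value(s) outside hard bounds", stacklevel=2)
        prov["bound_flags"] = flags
    return StudyTable(out, provenance=prov)


def read_study_table(path, registry: dict[str, VariableSpec] = REGISTRY) -> StudyTable:
    """Read a long-format CSV study table and validate it."""
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValidationError(f"empty input file: {path}")
    return make_study_table(df, registry, provenance={"source": str(path)})


def write_study_table(table: StudyTable, path) -> None:
    table.df.to_csv(path, index=False)


def derive_log10_pco2(table: StudyTable) -> StudyTable:
    """Append log10(pCO2) records as the display variable ``log10pCO2``.

    Original records are untouched; requires every pCO2 value > 0.
    """
    m = table.df["variable"] == "pCO2"
    sub = table.df.loc[m]
    if (sub["value"] <= 0).any():
        bad = sub.loc[sub["value"] <= 0, "value"].tolist()
        raise DomainError(f"pCO2 values must be positive to take log10, got {bad}")
    derived = sub.copy()
    derived["variable"] = "log10pCO2"
    derived["value"] = np.log10(sub["value"].to_numpy())
    df = pd.concat([table.df, derived], ignore_index=True)
    return StudyTable(df, provenance=dict(table.provenance))


def pair_records(table: StudyTable, variable: str) -> pd.DataFrame:
    """Complete before/after pairs for one variable.

    Returns a frame with columns (animal_id, before, after), one row per
    animal having BOTH a basal and a post-treatment value, sorted by
    animal id.  An empty frame signals "no complete pairs".
    """
    sub = table.df[table.df["variable"] == variable]
    wide = sub.pivot(index="animal_id", columns="treatment", values="value")
    for t in TREATMENTS:
        if t not in wide.columns:
            wide[t] = np.nan
    wide = wide.dropna(subset=list(TREATMENTS))
    out = pd.DataFrame(
        {
            "animal_id": wide.index.astype(str),
            "before": wide["Bas"].to_numpy(dtype=float),
            "after": wide["CO2"].to_numpy(dtype=float),
        }
    )
    # numeric-aware deterministic ordering: "2" before "10" when ids are numeric
    key = pd.to_numeric(out["animal_id"], errors="coerce")
    if key.notna().all():
        out = out.sort_values(by="animal_id", key=lambda s: pd.to_numeric(s))
    else:
        out = out.sort_values(by="animal_id")
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class SummaryStats:
    """Five-number summary plus mean, sd and count for one stratum."""

    variable: str
    treatment: str
    min: float
    q25: float
    mean: float
    q50: float
    sd: float
    q75: float
    max: float
    n_obs: int


def summarize(values: Iterable[float], variable: str = "", treatment: str = "") -> SummaryStats:
    """Summary statistics with type-7 quantiles and sample (n-1) sd."""
    x = np.asarray(list(values), dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise InsufficientDataError(f"need at least 2 finite values, got {x.size}")
    q25, q50, q75 = np.quantile(x, [0.25, 0.5, 0.75])
    return SummaryStats(
        variable=variable,
        treatment=treatment,
        min=float(x.min()),
        q25=float(q25),
        mean=float(x.mean()),
        q50=float(q50),
        sd=float(x.std(ddof=1)),
        q75=float(q75),
        max=float(x.max()),
        n_obs=int(x.size),
    )


def summary_table(table: StudyTable) -> pd.DataFrame:
    """Per-(variable, treatment) summary frame in report column order."""
    rows = []
    for variable in table.variables():
        for treatment in TREATMENTS:
            x = table.values(variable, treatment)
            if x.size < 2:
                continue
            s = summarize(x, variable, treatment)
            rows.append(
                {
                    "variable": s.variable,
                    "treatment": s.treatment,
                    "Min": s.min,
                    "Q.25": s.q25,
                    "Mean": s.mean,
                    "Q.50": s.q50,
                    "Sd": s.sd,
                    "Q.75": s.q75,
                    "Max": s.max,
                    "n_obs": s.n_obs,
                }
            )
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))
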