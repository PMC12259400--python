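"""Read, validate, link and encode individual-level and state-year tax tables.

The loaders consume plain delimited files (CSV/TSV, header row) and return
typed, validated pandas DataFrames together with a load report that counts
every row dropped per validation rule.  ``link_and_filter`` inner-joins
individuals to their state-year taxes, applies the eligibility filters
(minimum age, current-drinker restriction, complete cases) and produces the
numeric arrays every estimator consumes: outcome ``y``, exposure ``x``,
instrument matrix ``Z`` and reference-coded covariate matrix ``C``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schema
from .exceptions import DataError

__all__ = [
    "LoadReport",
    "AnalysisDataset",
    "load_individuals",
    "load_taxes",
    "validate_individuals",
    "validate_taxes",
    "adjust_to_base_year",
    "link_and_filter",
    "categorise_drinks",
    "encode_covariates",
]


# ---------------------------------------------------------------------------
# reports and containers


@dataclass
class LoadReport:
    """Row accounting for a load or filter step: n_input = n_retained + drops."""

    n_input: int = 0
    n_retained: int = 0
    drops: dict[str, int] = field(default_factory=dict)

    def add_drop(self, reason: str, count: int) -> None:
        if count:
            self.drops[reason] = self.drops.get(reason, 0) + int(count)

    @property
    def n_dropped(self) -> int:
        return sum(self.drops.values())

    def to_dict(self) -> dict:
        return {
            "n_input": int(self.n_input),
            "n_retained": int(self.n_retained),
            "drops": {k: int(v) for k, v in sorted(self.drops.items())},
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


@dataclass
class AnalysisDataset:
    """Analysis-ready arrays: outcome, exposure, instruments, covariates.

    ``C`` includes the intercept column and reference-coded categoricals in
    the order of :data:`taxiv.schema.DESIGN_COLUMNS`.  ``meta`` records the
    analysis-sample exposure mean/SD (the "per SD" contrast is defined on
    the filtered sample) and the filter report.
    """

    y: np.ndarray
    x: np.ndarray
    Z: np.ndarray
    C: np.ndarray
    z_names: list[str]
    c_names: list[str]
    state: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def x_sd(self) -> float:
        return float(self.meta["x_sd"])

    @property
    def x_mean(self) -> float:
        return float(self.meta["x_mean"])

    def subset(self, idx: np.ndarray) -> "AnalysisDataset":
        """Row subset (boolean mask or index array); recomputes exposure moments."""
        sub = AnalysisDataset(
            y=self.y[idx],
            x=self.x[idx],
            Z=self.Z[idx],
            C=self.C[idx],
            z_names=list(self.z_names),
            c_names=list(self.c_names),
            state=self.state[idx],
            meta=dict(self.meta),
        )
        sub.meta["x_mean"] = float(sub.x.mean())
        sub.meta["x_sd"] = float(sub.x.std(ddof=1))
        sub.meta["n"] = int(sub.y.shape[0])
        return sub

    def resample(self, idx: np.ndarray, keep_contrast: bool = True) -> "AnalysisDataset":
        """Bootstrap resample; optionally keeps the original exposure contrast."""
        sub = self.subset(idx)
        if keep_contrast:
            sub.meta["x_mean"] = self.meta["x_mean"]
            sub.meta["x_sd"] = self.meta["x_sd"]
        return sub

    def drop_covariate(self, name: str) -> "AnalysisDataset":
        """Remove one covariate design column (e.g. sex within a sex stratum)."""
        if name not in self.c_names:
            raise KeyError(name)
        keep = [i for i, c in enumerate(self.c_names) if c != name]
        out = AnalysisDataset(
            y=self.y, x=self.x, Z=self.Z, C=self.C[:, keep],
            z_names=list(self.z_names),
            c_names=[self.c_names[i] for i in keep],
            state=self.state, meta=dict(self.meta),
        )
        return out

    def with_outcome(self, y: np.ndarray) -> "AnalysisDataset":
        out = AnalysisDataset(
            y=np.asarray(y, dtype=float), x=self.x, Z=self.Z, C=self.C,
            z_names=list(self.z_names), c_names=list(self.c_names),
            state=self.state, meta=dict(self.meta),
        )
        return out


# ---------------------------------------------------------------------------
# loading and validation


def _read_delimited(path, delimiter=None) -> pd.DataFrame:
    if delimiter is None:
        return pd.read_csv(path, sep=None, engine="python")
    return pd.read_csv(path, sep=delimiter)


def _apply_column_map(df: pd.DataFrame, column_map: dict[str, str] | None) -> pd.DataFrame:
    """Rename source columns to canonical names; unknown targets are an error."""
    if not column_map:
        return df
    missing = [src for src in column_map.values() if src not in df.columns]
    if missing:
        raise DataError(
            "column map refers to columns absent from the file: " + ", ".join(sorted(missing))
        )
    return df.rename(columns={src: canon for canon, src in column_map.items()})


def validate_individuals(df: pd.DataFrame, years=None) -> tuple[pd.DataFrame, LoadReport]:
    """Type and validate an individual-level table; invalid rows are dropped
    one reason at a time (first matching rule wins) and counted."""
    report = LoadReport(n_input=len(df))
    missing = [c for c in schema.INDIVIDUAL_REQUIRED if c not in df.columns]
    if missing:
        raise DataError("missing mandatory column(s): " + ", ".join(missing))

    df = df.copy()
    df["drinks_per_day"] = pd.to_numeric(df["drinks_per_day"], errors="coerce")
    df["age"] = pd.to_numeric(df["age"], errors="coerce")
    df["year"] = pd.to_numeric(df["year"], errors="coerce")
    df["edentulous"] = pd.to_numeric(df["edentulous"], errors="coerce")

    rules = [
        ("unparseable numeric field",
         df[["drinks_per_day", "age", "year", "edentulous"]].isna().any(axis=1)),
        ("negative exposure", df["drinks_per_day"] < 0),
        ("outcome not binary", ~df["edentulous"].isin([0, 1])),
        ("unknown sex level", ~df["sex"].isin(schema.SEX_LEVELS)),
        ("unknown race/ethnicity level", ~df["race_ethnicity"].isin(schema.RACE_LEVELS)),
        ("unknown education level", ~df["education"].isin(schema.EDUCATION_LEVELS)),
        ("unknown smoking level", ~df["smoking"].isin(schema.SMOKING_LEVELS)),
    ]
    if years is not None:
        rules.append(("year outside study years", ~df["year"].isin(list(years))))

    bad = np.zeros(len(df), dtype=bool)
    for reason, mask in rules:
        new = np.asarray(mask) & ~bad
        report.add_drop(reason, int(new.sum()))
        bad |= new
    out = df.loc[~bad].reset_index(drop=True)
    out["year"] = out["year"].astype(int)
    out["edentulous"] = out["edentulous"].astype(int)
    report.n_retained = len(out)
    return out, report


def load_individuals(path, column_map=None, delimiter=None, years=None):
    """Load a delimited individual-level table.

    Parameters
    ----------
    column_map : dict, optional
        Mapping ``canonical_name -> source_column`` documenting how the
        extract's columns map onto the canonical schema.
    years : iterable of int, optional
        If given, rows outside these survey years are rejected.

    Returns
    -------
    (DataFrame, LoadReport)
    """
    df = _apply_column_map(_read_delimited(path, delimiter), column_map)
    return validate_individuals(df, years=years)


def validate_taxes(df: pd.DataFrame) -> tuple[pd.DataFrame, LoadReport]:
    report = LoadReport(n_input=len(df))
    required = ("state_code", "year") + schema.TAX_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError("missing mandatory column(s): " + ", ".join(missing))
    df = df.copy()
    for c in schema.TAX_COLUMNS + tuple(c for c in schema.TAX_OPTIONAL if c in df.columns):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df["year"] = pd.to_numeric(df["year"], errors="coerce")

    dup = df.duplicated(subset=["state_code", "year"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["state_code", "year"]].drop_duplicates()
        raise DataError(
            "duplicate (state, year) rows in tax table: "
            + "; ".join(f"({r.state_code}, {int(r.year)})" for r in keys.itertuples())
        )

    tax_cols = [c for c in schema.TAX_COLUMNS]
    rules = [
        ("unparseable numeric field", df[tax_cols + ["year"]].isna().any(axis=1)),
        ("negative tax", (df[tax_cols] < 0).any(axis=1)),
    ]
    bad = np.zeros(len(df), dtype=bool)
    for reason, mask in rules:
        new = np.asarray(mask) & ~bad
        report.add_drop(reason, int(new.sum()))
        bad |= new
    out = df.loc[~bad].reset_index(drop=True)
    out["year"] = out["year"].astype(int)
    report.n_retained = len(out)
    return out, report


def load_taxes(path, column_map=None, delimiter=None):
    """Load a state-year excise tax table (duplicate (state, year) is a hard error)."""
    df = _apply_column_map(_read_delimited(path, delimiter), column_map)
    return validate_taxes(df)


def adjust_to_base_year(taxes: pd.DataFrame, cpi_series, base_year: int,
                        already_real: bool = False) -> pd.DataFrame:
    """Express nominal taxes in base-year currency: tax * cpi(base)/cpi(year).

    ``cpi_series`` maps year -> price index.  When ``already_real`` is set the
    input is returned unchanged (pass-through for pre-deflated extracts).
    """
    if already_real:
        return taxes
    cpi = dict(pd.Series(cpi_series).items()) if not isinstance(cpi_series, dict) else cpi_series
    years_needed = set(int(y) for y in taxes["year"].unique()) | {int(base_year)}
    missing = sorted(y for y in years_needed if y not in cpi)
    if missing:
        raise DataError("CPI series missing year(s): " + ", ".join(map(str, missing)))
    out = taxes.copy()
    factor = taxes["year"].map(lambda y: cpi[int(base_year)] / cpi[int(y)])
    cols = [c for c in schema.TAX_COLUMNS + schema.TAX_OPTIONAL if c in out.columns]
    for c in cols:
        out[c] = out[c] * factor
    return out


# ---------------------------------------------------------------------------
# encoding and linkage


def encode_covariates(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Reference-coded covariate design matrix (intercept first).

    Reference levels: male, White, college graduate, never smoker.
    """
    n = len(df)
    cols = {
        "const": np.ones(n),
        "age": df["age"].to_numpy(dtype=float),
        "female": (df["sex"] == "female").to_numpy(dtype=float),
        "race_black": (df["race_ethnicity"] == "Black").to_numpy(dtype=float),
        "race_hispanic": (df["race_ethnicity"] == "Hispanic").to_numpy(dtype=float),
        "race_other": (df["race_ethnicity"] == "Other").to_numpy(dtype=float),
        "edu_no_certificate": (df["education"] == "no_certificate").to_numpy(dtype=float),
        "edu_elementary": (df["education"] == "elementary").to_numpy(dtype=float),
        "edu_some_high_school": (df["education"] == "some_high_school").to_numpy(dtype=float),
        "edu_high_school_graduate": (df["education"] == "high_school_graduate").to_numpy(dtype=float),
        "edu_some_college": (df["education"] == "some_college").to_numpy(dtype=float),
        "smoke_current": (df["smoking"] == "current").to_numpy(dtype=float),
        "smoke_former": (df["smoking"] == "former").to_numpy(dtype=float),
    }
    names = list(schema.DESIGN_COLUMNS)
    C = np.column_stack([cols[c] for c in names])
    return C, names


def link_and_filter(
    individuals: pd.DataFrame,
    taxes: pd.DataFrame,
    min_age: float | None = 30,
    max_age: float | None = None,
    require_positive_exposure: bool = True,
    instruments: tuple[str, ...] = schema.TAX_COLUMNS,
    outcome: str = "edentulous",
    extra_covariates: tuple[str, ...] = (),
) -> AnalysisDataset:
    """Inner-join individuals to state-year taxes and apply eligibility filters.

    Filters (each drop is counted in the report carried in ``meta``):
    age >= min_age (and <= max_age when given), exposure > 0 under the
    current-drinker restriction, and complete cases on all model variables.
    Any retained (state, year) missing from the tax table is a hard error.

    ``extra_covariates`` appends additional numeric columns from the tax
    table (e.g. the cigarette tax sensitivity adjustment) to ``C``.
    """
    report = LoadReport(n_input=len(individuals))
    df = individuals.copy()

    if min_age is not None:
        mask = df["age"] < min_age
        report.add_drop(f"age below {min_age}", int(mask.sum()))
        df = df.loc[~mask]
    if max_age is not None:
        mask = df["age"] > max_age
        report.add_drop(f"age above {max_age}", int(mask.sum()))
        df = df.loc[~mask]
    if require_positive_exposure:
        mask = df["drinks_per_day"] <= 0
        report.add_drop("not a current drinker (zero exposure)", int(mask.sum()))
        df = df.loc[~mask]

    model_cols = ["drinks_per_day", "age", "sex", "race_ethnicity",
                  "education", "smoking", outcome]
    missing_cols = [c for c in model_cols if c not in df.columns]
    if missing_cols:
        raise DataError("missing model column(s): " + ", ".join(missing_cols))
    mask = df[model_cols].isna().any(axis=1)
    report.add_drop("missing model variable", int(mask.sum()))
    df = df.loc[~mask]

    keys = df[["state_code", "year"]].drop_duplicates()
    tax_keys = set(zip(taxes["state_code"], taxes["year"]))
    absent = [k for k in zip(keys["state_code"], keys["year"]) if k not in tax_keys]
    if absent:
        raise DataError(
            "individual (state, year) absent from tax table: "
            + "; ".join(f"({s}, {y})" for s, y in sorted(absent)[:20])
        )

    tax_cols = list(dict.fromkeys(list(instruments) + list(extra_covariates)))
    merged = df.merge(taxes[["state_code", "year"] + tax_cols],
                      on=["state_code", "year"], how="inner", validate="many_to_one")
    mask = merged[tax_cols].isna().any(axis=1)
    report.add_drop("missing tax value", int(mask.sum()))
    merged = merged.loc[~mask].reset_index(drop=True)
    report.n_retained = len(merged)
    if report.n_retained == 0:
        raise DataError("no rows retained after linkage and filtering")

    C, c_names = encode_covariates(merged)
    for name in extra_covariates:
        C = np.column_stack([C, merged[name].to_numpy(dtype=float)])
        c_names = c_names + [name]
    # empty categorical cells (all-zero dummies) carry no information and
    # would make the design singular; drop them, keeping a record
    variable = [i for i, name in enumerate(c_names)
                if name == "const" or C[:, i].std() > 0]
    dropped_cols = [c_names[i] for i in range(len(c_names)) if i not in variable]
    if dropped_cols:
        C = C[:, variable]
        c_names = [c_names[i] for i in variable]
    Z = merged[list(instruments)].to_numpy(dtype=float)
    for j, zn in enumerate(instruments):
        if Z[:, j].std() == 0:
            raise DataError(f"instrument column {zn!r} has zero variance after linkage")

    x = merged["drinks_per_day"].to_numpy(dtype=float)
    y = merged[outcome].to_numpy(dtype=float)
    ds = AnalysisDataset(
        y=y, x=x, Z=Z, C=C,
        z_names=list(instruments), c_names=c_names,
        state=merged["state_code"].to_numpy(),
        meta={
            "n": int(len(merged)),
            "x_mean": float(x.mean()),
            "x_sd": float(x.std(ddof=1)),
            "outcome": outcome,
            "filter_report": report.to_dict(),
            "dropped_covariate_columns": dropped_cols,
        },
    )
    return ds


def categorise_drinks(x):
    """Exposure category for positive drinks/day: (0,2] / (2,5) / [5,inf).

    Accepts a scalar or array; raises on any non-positive value.
    """
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
        raise ValueError("drinks per day must be positive and finite")
    cats = np.where(arr <= 2, schema.DRINK_CATEGORIES[0],
                    np.where(arr < 5, schema.DRINK_CATEGORIES[1], schema.DRINK_CATEGORIES[2]))
    if np.isscalar(x) or np.asarray(x).ndim == 0:
        return str(cats[0])
    return cats
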