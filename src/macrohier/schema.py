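"""Cohort CSV I/O, predictor codings and analysis subsets.

Holds the machine-readable registry of the 26 candidate maternal predictors
(each with its coding, ordered categories, reference category and
missing-data policy), the treatment-coded design-matrix builder with the
'unknown' category for missing values, and construction of the two
case/control analysis subsets (macrosomia > 4000 g vs 2500-4000 g controls;
LGA > 90th percentile vs 10-90th percentile controls).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .cohort import COLUMNS, _NUMERIC_COLUMNS, CohortTable

__all__ = [
    "PredictorSpec",
    "DesignMatrix",
    "AnalysisSubset",
    "read_cohort_csv",
    "write_cohort_csv",
    "build_predictor_registry",
    "base_model_specs",
    "make_subset",
    "encode",
    "CONTRASTS",
    "IOM_GWG_RANGES",
]

UNKNOWN = "unknown"

#: 2009 Institute of Medicine total-GWG recommendation ranges (kg) by
#: pre-pregnancy BMI class.
IOM_GWG_RANGES = {
    "underweight": (12.5, 18.0),
    "normal": (11.5, 16.0),
    "overweight": (7.0, 11.5),
    "obese": (5.0, 9.0),
}

CONTRASTS = ("macrosomia_vs_2500_4000", "lga_vs_10_90")


class CohortParseError(ValueError):
    """Raised when a cohort CSV fails validation."""


@dataclass(frozen=True)
class PredictorSpec:
    """One predictor coding: how a cohort column maps into the regression.

    ``derive`` turns the cohort DataFrame into the predictor values (numeric
    for continuous codings, category labels otherwise); missing source values
    propagate to NaN and are handled per ``missing_policy``.
    """

    name: str
    coding: Literal["continuous", "categorical", "dichotomous"]
    derive: Callable[[pd.DataFrame], pd.Series]
    categories: tuple[str, ...] = ()
    reference: str | None = None
    missing_policy: Literal["unknown_category", "disallow"] = "disallow"
    unit: str = ""
    uses_bmi: bool = False  # drop BMI from the AOR adjuster set when tested

    def __post_init__(self) -> None:
        if self.coding == "continuous":
            if self.categories:
                raise ValueError(f"{self.name}: continuous spec may not have categories")
        else:
            if self.reference not in self.categories:
                raise ValueError(
                    f"{self.name}: reference {self.reference!r} not among categories "
                    f"{self.categories}")


@dataclass
class DesignMatrix:
    """Numeric design over an analysis subset: intercept column first."""

    X: np.ndarray
    columns: list[str]
    y: np.ndarray
    colmap: list[tuple[str, str | None]]  # column -> (predictor, category)
    row_index: np.ndarray  # positions of the subset rows in the cohort table


@dataclass
class AnalysisSubset:
    """Case/control record indices for one contrast."""

    contrast: str
    case_idx: np.ndarray
    control_idx: np.ndarray

    @property
    def index(self) -> np.ndarray:
        """Cases first, then controls."""
        return np.concatenate([self.case_idx, self.control_idx])

    @property
    def y(self) -> np.ndarray:
        return np.concatenate([
            np.ones(len(self.case_idx), dtype=int),
            np.zeros(len(self.control_idx), dtype=int),
        ])


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_cohort_csv(table: CohortTable, path) -> None:
    """Write a cohort as comma-separated UTF-8 CSV; empty string = missing."""
    table.df.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path) -> CohortTable:
    """Read and validate a cohort CSV (round-trip inverse of the writer)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown_cols = [c for c in df.columns if c not in COLUMNS]
    if unknown_cols:
        raise CohortParseError(f"unknown columns: {unknown_cols}")
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortParseError(f"missing columns: {missing_cols}")
    out = {}
    for col in COLUMNS:
        raw = df[col].replace("", np.nan)
        if col in _NUMERIC_COLUMNS:
            try:
                vals = pd.to_numeric(raw)
            except (ValueError, TypeError):
                bad = raw[pd.to_numeric(raw, errors="coerce").isna() & raw.notna()]
                row = int(bad.index[0]) + 2  # 1-based with header row
                raise CohortParseError(
                    f"non-numeric value {bad.iloc[0]!r} in column {col!r} "
                    f"(file row {row})") from None
            if col in ("parity", "gestational_age_weeks", "macrosomia"):
                vals = vals.astype("int64") if vals.notna().all() else vals
            out[col] = vals
        else:
            out[col] = raw
    df = pd.DataFrame(out)
    if len(df):
        neg = df.index[df["birthweight_g"] <= 0]
        if len(neg):
            raise CohortParseError(
                f"non-positive birthweight (file row {int(neg[0]) + 2})")
    table = CohortTable(df)
    table.validate()
    return table


# ---------------------------------------------------------------------------
# predictor registry
# ---------------------------------------------------------------------------

def _col(name):
    return lambda df: df[name]


def _dicho(source, label_yes, label_no, pred):
    def derive(df: pd.DataFrame) -> pd.Series:
        s = df[source]
        out = pd.Series(np.where(pred(s), label_yes, label_no), index=df.index, dtype=object)
        out[s.isna()] = np.nan
        return out
    return derive


def _bmi_category(df: pd.DataFrame) -> pd.Series:
    bins = pd.cut(df["prepreg_bmi"], [-np.inf, 18.5, 25.0, 30.0, np.inf],
                  right=False, labels=["underweight", "normal", "overweight", "obese"])
    return bins.astype(object)


def _gwg_class(df: pd.DataFrame) -> pd.Series:
    """below / within / above the BMI-class-specific 2009 IOM range."""
    bmi_class = _bmi_category(df)
    lo = bmi_class.map({k: v[0] for k, v in IOM_GWG_RANGES.items()})
    hi = bmi_class.map({k: v[1] for k, v in IOM_GWG_RANGES.items()})
    gwg = df["gwg_kg"]
    out = pd.Series(
        np.select([gwg > hi, gwg < lo], ["above", "below"], default="within"),
        index=df.index, dtype=object)
    out[gwg.isna() | df["prepreg_bmi"].isna()] = np.nan
    return out


def _gwg_above(df: pd.DataFrame) -> pd.Series:
    cls = _gwg_class(df)
    out = pd.Series(np.where(cls == "above", "above", "not_above"),
                    index=df.index, dtype=object)
    out[cls.isna()] = np.nan
    return out


def _parity_category(df: pd.DataFrame) -> pd.Series:
    p = df["parity"]
    out = pd.Series(
        np.select([p == 0, p == 1, p == 2], ["primiparity", "1", "2"], default="ge3"),
        index=df.index, dtype=object)
    out[p.isna()] = np.nan
    return out


def _interval(df: pd.DataFrame) -> pd.Series:
    return df["interpregnancy_interval"]


def build_predictor_registry(include_optional: bool = False) -> list[PredictorSpec]:
    """The 26 candidate predictor codings of the index tables.

    Each entry is one tested coding (a variable may appear under several
    codings, e.g. BMI as continuous, as 4 categories, and as the >=25 / >=30
    dichotomies).  ``include_optional`` appends codings defined by the study
    schema but not used in the index tables (age categories, GWG continuous
    and 3-category, 4-level GDM, 3-level smoking).
    """
    specs = [
        PredictorSpec("Pre-pregnancy weight (kg)", "continuous",
                      _col("prepreg_weight_kg"), unit="kg", uses_bmi=True),
        PredictorSpec("Pre-pregnancy BMI (kg/m2)", "continuous",
                      _col("prepreg_bmi"), unit="kg/m2", uses_bmi=True),
        PredictorSpec("BMI categories", "categorical", _bmi_category,
                      ("underweight", "normal", "overweight", "obese"),
                      reference="normal", unit="kg/m2", uses_bmi=True),
        PredictorSpec("GWG above the range", "dichotomous", _gwg_above,
                      ("not_above", "above"), reference="not_above", unit="kg"),
        PredictorSpec("BMI >= 25 kg/m2", "dichotomous",
                      _dicho("prepreg_bmi", "ge25", "lt25", lambda s: s >= 25),
                      ("lt25", "ge25"), reference="lt25", unit="kg/m2", uses_bmi=True),
        PredictorSpec("Maternal height (cm)", "continuous", _col("height_cm"), unit="cm"),
        PredictorSpec("Fetal sex: son", "dichotomous",
                      _dicho("fetal_sex", "son", "daughter", lambda s: s == "son"),
                      ("daughter", "son"), reference="daughter"),
        PredictorSpec("Maternal height > 170 cm", "dichotomous",
                      _dicho("height_cm", "gt170", "le170", lambda s: s > 170),
                      ("le170", "gt170"), reference="le170", unit="cm"),
        PredictorSpec("BMI >= 30 kg/m2", "dichotomous",
                      _dicho("prepreg_bmi", "ge30", "lt30", lambda s: s >= 30),
                      ("lt30", "ge30"), reference="lt30", unit="kg/m2", uses_bmi=True),
        PredictorSpec("Prior macrosomia", "dichotomous",
                      _dicho("prior_macrosomia", "yes", "no", lambda s: s == "yes"),
                      ("no", "yes"), reference="no"),
        PredictorSpec("Gestational age >= 38 weeks", "dichotomous",
                      _dicho("gestational_age_weeks", "ge38", "lt38", lambda s: s >= 38),
                      ("lt38", "ge38"), reference="lt38", unit="weeks"),
        PredictorSpec("Maternal height > 160 cm", "dichotomous",
                      _dicho("height_cm", "gt160", "le160", lambda s: s > 160),
                      ("le160", "gt160"), reference="le160", unit="cm"),
        PredictorSpec("Family: diabetes in the mother", "categorical",
                      _col("family_dm_mother"), ("none", "family_other", "parent"),
                      reference="none"),
        PredictorSpec("Interpregnancy interval", "categorical", _interval,
                      ("1y", "primigravida", "2y", "3_5y", "6_10y", "ge11y"),
                      reference="1y", missing_policy="unknown_category", unit="years"),
        PredictorSpec("Family: diabetes in the father", "categorical",
                      _col("family_dm_father"), ("none", "family_other", "parent"),
                      reference="none"),
        PredictorSpec("Ex-smoking", "dichotomous",
                      _dicho("smoking", "ex", "other", lambda s: s == "ex"),
                      ("other", "ex"), reference="other",
                      missing_policy="unknown_category"),
        PredictorSpec("GDM", "dichotomous",
                      _dicho("gdm", "gdm", "no_gdm", lambda s: s != "none"),
                      ("no_gdm", "gdm"), reference="no_gdm"),
        PredictorSpec("Prior diabetes", "dichotomous",
                      _dicho("prior_gdm", "yes", "no", lambda s: s == "yes"),
                      ("no", "yes"), reference="no"),
        PredictorSpec("Lower financial status", "dichotomous",
                      _dicho("financial_status", "lower", "higher", lambda s: s == "lower"),
                      ("higher", "lower"), reference="higher",
                      missing_policy="unknown_category"),
        PredictorSpec("Folic acid supplementation", "dichotomous",
                      _dicho("folic_acid", "yes", "no", lambda s: s == "yes"),
                      ("no", "yes"), reference="no",
                      missing_policy="unknown_category"),
        PredictorSpec("Education < 12 years", "dichotomous",
                      _dicho("education", "lt12", "ge12", lambda s: s == "lt12"),
                      ("ge12", "lt12"), reference="ge12",
                      missing_policy="unknown_category"),
        PredictorSpec("Marital status: married", "dichotomous",
                      _dicho("marital_status", "married", "other", lambda s: s == "married"),
                      ("other", "married"), reference="other",
                      missing_policy="unknown_category"),
        PredictorSpec("Prior cesarean section", "dichotomous",
                      _dicho("prior_cesarean", "yes", "no", lambda s: s == "yes"),
                      ("no", "yes"), reference="no"),
        PredictorSpec("Village", "dichotomous",
                      _dicho("residence", "village", "other", lambda s: s == "village"),
                      ("other", "village"), reference="other",
                      missing_policy="unknown_category"),
        PredictorSpec("Multivitamin supplementation", "dichotomous",
                      _dicho("multivitamin", "yes", "no", lambda s: s == "yes"),
                      ("no", "yes"), reference="no",
                      missing_policy="unknown_category"),
        PredictorSpec("Never smoking", "dichotomous",
                      _dicho("smoking", "never", "other", lambda s: s == "never"),
                      ("other", "never"), reference="other",
                      missing_policy="unknown_category"),
    ]
    if include_optional:
        specs += [
            PredictorSpec("Maternal age categories", "categorical",
                          lambda df: pd.cut(
                              df["maternal_age_years"], [18, 25, 30, 35, 40, np.inf],
                              right=False,
                              labels=["18_24", "25_29", "30_34", "35_39", "ge40"],
                          ).astype(object),
                          ("18_24", "25_29", "30_34", "35_39", "ge40"),
                          reference="18_24", unit="years"),
            PredictorSpec("GWG (kg)", "continuous", _col("gwg_kg"), unit="kg"),
            PredictorSpec("GWG categories", "categorical", _gwg_class,
                          ("within", "below", "above"), reference="within", unit="kg"),
            PredictorSpec("GDM categories", "categorical", _col("gdm"),
                          ("none", "gdm1", "gdm2"), reference="none"),
            PredictorSpec("Smoking", "categorical", _col("smoking"),
                          ("current", "ex", "never"), reference="current",
                          missing_policy="unknown_category"),
        ]
    return specs


def base_model_specs() -> list[PredictorSpec]:
    """The base prediction model: maternal age (continuous) + parity (0/1/2/>=3)."""
    return [
        PredictorSpec("Maternal age (years)", "continuous",
                      _col("maternal_age_years"), unit="years"),
        PredictorSpec("Parity", "categorical", _parity_category,
                      ("primiparity", "1", "2", "ge3"), reference="primiparity"),
    ]


def adjuster_specs(include_bmi: bool = True) -> list[PredictorSpec]:
    """Adjusters of the adjusted odds ratios: age, parity and (optionally) BMI."""
    specs = base_model_specs()
    if include_bmi:
        specs.append(PredictorSpec("Pre-pregnancy BMI (kg/m2)", "continuous",
                                   _col("prepreg_bmi"), unit="kg/m2", uses_bmi=True))
    return specs


# ---------------------------------------------------------------------------
# subsets and encoding
# ---------------------------------------------------------------------------

def make_subset(table: CohortTable, contrast: str) -> AnalysisSubset:
    """Select the case/control records of one contrast; all others drop out."""
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {CONTRASTS}")
    df = table.df
    if contrast == "macrosomia_vs_2500_4000":
        band = df["weight_band"]
        cases = np.flatnonzero(band == "gt4000")
        controls = np.flatnonzero(band == "2500_4000")
    else:
        band = df["lga_band"]
        cases = np.flatnonzero(band == "gt90")
        controls = np.flatnonzero(band == "10_90")
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError(
            f"contrast {contrast!r}: needs at least one case and one control "
            f"(got {len(cases)} cases, {len(controls)} controls)")
    return AnalysisSubset(contrast, cases, controls)


def encode(subset: AnalysisSubset, specs: PredictorSpec | Sequence[PredictorSpec],
           table: CohortTable) -> DesignMatrix:
    """Build the treatment-coded design matrix for one or more predictors.

    Continuous codings contribute one column; categorical/dichotomous codings
    contribute one dummy per observed non-reference category (in spec order),
    plus a final 'unknown' dummy when missing values are present and the
    spec's policy allows them.  The intercept column comes first.
    """
    if isinstance(specs, PredictorSpec):
        specs = [specs]
    rows = subset.index
    df = table.df.iloc[rows]
    cols: list[np.ndarray] = [np.ones(len(rows))]
    names: list[str] = ["intercept"]
    colmap: list[tuple[str, str | None]] = [("intercept", None)]
    for spec in specs:
        values = spec.derive(df)
        miss = pd.isna(values)
        if miss.any() and spec.missing_policy == "disallow":
            bad = list(np.flatnonzero(miss.to_numpy())[:10])
            raise ValueError(
                f"{spec.name}: missing values not allowed "
                f"(subset rows {bad}{'...' if miss.sum() > 10 else ''})")
        if spec.coding == "continuous":
            cols.append(values.to_numpy(dtype=float))
            names.append(spec.name)
            colmap.append((spec.name, None))
            continue
        observed = set(values[~miss].unique())
        unexpected = observed - set(spec.categories)
        if unexpected:
            raise ValueError(f"{spec.name}: unexpected categories {sorted(unexpected)}")
        for cat in spec.categories:
            if cat == spec.reference or cat not in observed:
                continue
            cols.append((values == cat).to_numpy(dtype=float))
            names.append(f"{spec.name}: {cat}")
            colmap.append((spec.name, cat))
        if miss.any():
            cols.append(miss.to_numpy(dtype=float))
            names.append(f"{spec.name}: {UNKNOWN}")
            colmap.append((spec.name, UNKNOWN))
    X = np.column_stack(cols)
    return DesignMatrix(X=X, columns=names, y=subset.y, colmap=colmap, row_index=rows)
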