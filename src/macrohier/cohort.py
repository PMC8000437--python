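"""Synthetic pregnancy-cohort generator.

Generates participant-level cohorts with the statistical structure assumed by
the macrosomia-prediction analysis: maternal covariates with realistic
marginals (age, height, pre-pregnancy BMI/weight, gestational weight gain,
parity, obstetric history, socio-demographics), a Gaussian linear birthweight
model over those covariates, and outcome bands derived deterministically from
the simulated birthweight (macrosomia > 4000 g; large-for-gestational-age via
a sex- and week-specific reference growth grid).

The default configuration is calibrated so that a cohort of n = 912 reproduces
the marginals of the emulated study population: macrosomia prevalence 10.6 %,
controls 2500-4000 g ~82.8 %, BMI >= 25 in 29.7 %, obesity 10.8 %, excessive
gestational weight gain ~36.8 %, GDM 16 %, maternal age median ~35 years,
BMI median ~22.8 kg/m2.  Because birthweight has an explicit generating
model, the generator provides a ground truth against which predictor-ranking
recovery can be tested.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneratorConfig",
    "CovariateParams",
    "BirthweightModel",
    "CohortTable",
    "ReferenceGrowthGrid",
    "default_config",
    "dominant_weight_config",
    "generate_cohort",
    "inject_missingness",
    "assign_lga_band",
    "derive_outcomes",
    "COLUMNS",
    "MISSABLE_VARIABLES",
]

# Completed gestational weeks supported by the generator and the default grid.
GA_MIN, GA_MAX = 25, 42

# Centering constants of the birthweight linear model (units of each covariate).
_CENTERS = {
    "prepreg_weight_kg": 66.5,
    "gwg_kg": 13.0,
    "height_cm": 166.7,
    "gestational_age_weeks": 39.0,
    "maternal_age_years": 34.8,
}

# z-scores of the 10th/90th percentiles of a normal reference distribution.
_Z90 = float(stats.norm.ppf(0.90))

#: Column order of a cohort table (also the CSV data dictionary order).
COLUMNS = [
    "maternal_age_years",
    "height_cm",
    "prepreg_weight_kg",
    "prepreg_bmi",
    "gwg_kg",
    "parity",
    "fetal_sex",
    "gestational_age_weeks",
    "gdm",
    "prior_macrosomia",
    "prior_gdm",
    "prior_cesarean",
    "family_dm_mother",
    "family_dm_father",
    "smoking",
    "education",
    "financial_status",
    "residence",
    "marital_status",
    "folic_acid",
    "multivitamin",
    "interpregnancy_interval",
    "birthweight_g",
    "macrosomia",
    "weight_band",
    "lga_band",
]

_NUMERIC_COLUMNS = {
    "maternal_age_years",
    "height_cm",
    "prepreg_weight_kg",
    "prepreg_bmi",
    "gwg_kg",
    "parity",
    "gestational_age_weeks",
    "birthweight_g",
    "macrosomia",
}

#: Variables that may legitimately carry missing values (they have an
#: 'unknown' category in the predictor codings); outcomes and the base-model
#: variables (age, parity) are never allowed to go missing.
MISSABLE_VARIABLES = (
    "interpregnancy_interval",
    "education",
    "financial_status",
    "residence",
    "marital_status",
    "folic_acid",
    "multivitamin",
    "smoking",
)

# Default missingness applies only to the five variables whose codings define
# an explicit missing-data category.
_DEFAULT_MISSING = {
    "interpregnancy_interval": 0.05,
    "education": 0.05,
    "financial_status": 0.05,
    "residence": 0.05,
    "marital_status": 0.05,
}


class ConfigError(ValueError):
    """Raised when a generator configuration field is invalid."""


def _check_probvec(name: str, p, length: int | None = None) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if length is not None and p.shape != (length,):
        raise ConfigError(f"{name}: expected {length} probabilities, got shape {p.shape}")
    if np.any(p < 0) or np.any(p > 1):
        raise ConfigError(f"{name}: probabilities must lie in [0, 1]")
    if abs(p.sum() - 1.0) > 1e-12:
        raise ConfigError(f"{name}: probabilities must sum to 1 (got {p.sum()!r})")
    return p


def _check_prob(name: str, p: float) -> float:
    if not 0.0 <= p <= 1.0:
        raise ConfigError(f"{name}: probability must lie in [0, 1] (got {p!r})")
    return float(p)


@dataclass
class CovariateParams:
    """Distribution parameters of the maternal covariates.

    BMI is drawn from a 3-component normal mixture (normal-weight bulk,
    overweight, obese components); pre-pregnancy weight is derived as
    BMI * height(m)^2 so that weight, height and BMI are mutually consistent.
    Gestational weight gain has a left-skewed reflected-gamma residual whose
    location depends on the BMI class (heavier women gain less).  Gestational
    age mixes a term normal with a preterm gamma tail.  All other covariates
    are drawn independently from their categorical marginals.
    """

    age_mean: float = 35.0
    age_sd: float = 4.7
    age_bounds: tuple[float, float] = (18.0, 48.0)
    height_mean: float = 166.7
    height_sd: float = 6.1
    height_bounds: tuple[float, float] = (145.0, 195.0)
    bmi_weights: tuple[float, ...] = (0.750, 0.132, 0.118)
    bmi_means: tuple[float, ...] = (21.9, 27.5, 32.5)
    bmi_sds: tuple[float, ...] = (2.2, 2.0, 3.0)
    bmi_bounds: tuple[float, float] = (15.0, 55.0)
    # class medians keyed to BMI class (underweight, normal, overweight, obese)
    gwg_class_medians: tuple[float, ...] = (15.0, 14.15, 12.7, 10.5)
    gwg_scale: float = 5.6
    gwg_shape: float = 1.0
    gwg_bounds: tuple[float, float] = (-5.0, 35.0)
    term_ga_mean: float = 39.35
    term_ga_sd: float = 1.0
    preterm_prob: float = 0.072
    preterm_offset: float = 36.5
    preterm_shape: float = 1.5
    preterm_scale: float = 2.3
    son_prob: float = 0.52
    parity_probs: tuple[float, ...] = (0.42, 0.36, 0.16, 0.06)  # 0,1,2,>=3
    gdm_probs: tuple[float, ...] = (0.84, 0.137, 0.023)  # none, diet, insulin
    prior_macrosomia_prob: float = 0.052  # conditional on parous (~3% marginal)
    prior_gdm_prob: float = 0.07  # conditional on parous
    prior_cesarean_prob: float = 0.31  # conditional on parous
    family_dm_mother_probs: tuple[float, ...] = (0.074, 0.10, 0.826)
    family_dm_father_probs: tuple[float, ...] = (0.122, 0.08, 0.798)
    smoking_probs: tuple[float, ...] = (0.82, 0.12, 0.06)  # never, ex, current
    education_lt12_prob: float = 0.12
    financial_lower_prob: float = 0.25
    residence_probs: tuple[float, ...] = (0.30, 0.30, 0.40)  # village, small, large
    marital_probs: tuple[float, ...] = (0.85, 0.04, 0.11)  # married, divorced, unmarried
    folic_acid_prob: float = 0.85
    multivitamin_prob: float = 0.585
    interval_probs: tuple[float, ...] = (0.14, 0.26, 0.34, 0.17, 0.09)  # 1y..>=11y | parous

    def validate(self) -> None:
        _check_probvec("bmi_weights", self.bmi_weights, 3)
        _check_probvec("parity_probs", self.parity_probs, 4)
        _check_probvec("gdm_probs", self.gdm_probs, 3)
        _check_probvec("family_dm_mother_probs", self.family_dm_mother_probs, 3)
        _check_probvec("family_dm_father_probs", self.family_dm_father_probs, 3)
        _check_probvec("smoking_probs", self.smoking_probs, 3)
        _check_probvec("residence_probs", self.residence_probs, 3)
        _check_probvec("marital_probs", self.marital_probs, 3)
        _check_probvec("interval_probs", self.interval_probs, 5)
        for nm in ("son_prob", "prior_macrosomia_prob", "prior_gdm_prob",
                   "prior_cesarean_prob", "education_lt12_prob",
                   "financial_lower_prob", "folic_acid_prob",
                   "multivitamin_prob", "preterm_prob"):
            _check_prob(nm, getattr(self, nm))
        for nm in ("age_sd", "height_sd", "gwg_scale", "gwg_shape",
                   "term_ga_sd", "preterm_shape", "preterm_scale"):
            if getattr(self, nm) <= 0:
                raise ConfigError(f"{nm}: must be positive")
        if any(s <= 0 for s in self.bmi_sds):
            raise ConfigError("bmi_sds: must be positive")


@dataclass
class BirthweightModel:
    """Gaussian linear model for birthweight (grams).

    ``coef`` maps feature names to gram-per-unit coefficients.  Continuous
    covariates enter centered at the constants in ``_CENTERS``; the
    ``preterm_hinge`` feature is max(37 - gestational_age, 0), giving the
    fetal growth curve its steeper pre-term slope.
    """

    intercept: float
    coef: dict[str, float] = field(default_factory=dict)
    residual_sd: float = 310.0

    def validate(self) -> None:
        if self.residual_sd <= 0:
            raise ConfigError("residual_sd: must be positive")
        unknown = set(self.coef) - set(_BW_FEATURES)
        if unknown:
            raise ConfigError(f"birthweight coef: unknown features {sorted(unknown)}")


_BW_FEATURES = (
    "prepreg_weight_kg", "gwg_kg", "height_cm", "son", "gestational_age_weeks",
    "preterm_hinge", "gdm1", "gdm2", "prior_macrosomia", "maternal_age_years",
    "parity1", "parity2", "parity3",
)

_DEFAULT_BW_COEF = {
    "prepreg_weight_kg": 10.0,
    "gwg_kg": 11.0,
    "height_cm": 3.0,
    "son": 110.0,
    "gestational_age_weeks": 130.0,
    "preterm_hinge": -360.0,
    "gdm1": 60.0,
    "gdm2": 120.0,
    "prior_macrosomia": 220.0,
    "maternal_age_years": 3.0,
    "parity1": 60.0,
    "parity2": 80.0,
    "parity3": 90.0,
}


@dataclass
class GeneratorConfig:
    """Full configuration of one synthetic cohort draw."""

    n_participants: int = 912
    seed: int = 0
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    birthweight_model: BirthweightModel = field(
        default_factory=lambda: BirthweightModel(intercept=3400.0, coef=dict(_DEFAULT_BW_COEF))
    )
    missingness_rates: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MISSING))
    macrosomia_target: float = 0.106

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ConfigError("n_participants: must be >= 0")
        self.covariate_params.validate()
        self.birthweight_model.validate()
        for var, rate in self.missingness_rates.items():
            if var not in MISSABLE_VARIABLES:
                raise ConfigError(
                    f"missingness_rates: {var!r} may not be set missing "
                    f"(allowed: {MISSABLE_VARIABLES})")
            _check_prob(f"missingness_rates[{var}]", rate)
        _check_prob("macrosomia_target", self.macrosomia_target)


# ---------------------------------------------------------------------------
# covariate simulation
# ---------------------------------------------------------------------------

def _draw_raw(params: CovariateParams, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Draw the covariate block as raw numeric arrays (no labels)."""
    p = params
    age = np.clip(rng.normal(p.age_mean, p.age_sd, n), *p.age_bounds)
    height = np.clip(rng.normal(p.height_mean, p.height_sd, n), *p.height_bounds)

    comp = rng.choice(3, n, p=np.asarray(p.bmi_weights))
    bmi = np.clip(
        rng.normal(np.asarray(p.bmi_means)[comp], np.asarray(p.bmi_sds)[comp]),
        *p.bmi_bounds,
    )
    weight = bmi * (height / 100.0) ** 2
    bmi_class = np.digitize(bmi, [18.5, 25.0, 30.0])  # 0 uw, 1 nw, 2 ow, 3 ob

    # left-skewed standardized reflected gamma: mean 0, sd 1
    k = p.gwg_shape
    g = rng.gamma(k, 1.0, n)
    z = -(g - k) / np.sqrt(k)
    z_med = -(stats.gamma.ppf(0.5, k) - k) / np.sqrt(k)
    loc = np.asarray(p.gwg_class_medians)[bmi_class] - p.gwg_scale * z_med
    gwg = np.clip(loc + p.gwg_scale * z, *p.gwg_bounds)

    term = np.round(rng.normal(p.term_ga_mean, p.term_ga_sd, n))
    preterm = np.minimum(np.round(p.preterm_offset - rng.gamma(p.preterm_shape, p.preterm_scale, n)), 36)
    ga = np.clip(np.where(rng.random(n) < p.preterm_prob, preterm, term), GA_MIN, GA_MAX).astype(int)

    son = rng.random(n) < p.son_prob
    parity_cat = rng.choice(4, n, p=np.asarray(p.parity_probs))
    # category >=3 holds an actual delivery count of 3 or more
    extra = rng.choice([3, 4, 5], n, p=[0.7, 0.2, 0.1])
    parity = np.where(parity_cat == 3, extra, parity_cat)
    parous = parity > 0

    gdm_idx = rng.choice(3, n, p=np.asarray(p.gdm_probs))
    prior_mac = parous & (rng.random(n) < p.prior_macrosomia_prob)
    prior_gdm = parous & (rng.random(n) < p.prior_gdm_prob)
    prior_ces = parous & (rng.random(n) < p.prior_cesarean_prob)

    fam_m = rng.choice(3, n, p=np.asarray(p.family_dm_mother_probs))
    fam_f = rng.choice(3, n, p=np.asarray(p.family_dm_father_probs))
    smoking = rng.choice(3, n, p=np.asarray(p.smoking_probs))
    edu = rng.random(n) < p.education_lt12_prob
    fin = rng.random(n) < p.financial_lower_prob
    res = rng.choice(3, n, p=np.asarray(p.residence_probs))
    mar = rng.choice(3, n, p=np.asarray(p.marital_probs))
    folic = rng.random(n) < p.folic_acid_prob
    multi = rng.random(n) < p.multivitamin_prob

    iv_idx = rng.choice(5, n, p=np.asarray(p.interval_probs))

    return {
        "age": age, "height": height, "bmi": weight / (height / 100.0) ** 2,
        "weight": weight, "gwg": gwg, "ga": ga, "son": son,
        "parity": parity.astype(int), "gdm_idx": gdm_idx,
        "prior_mac": prior_mac, "prior_gdm": prior_gdm, "prior_ces": prior_ces,
        "fam_m": fam_m, "fam_f": fam_f, "smoking": smoking, "edu": edu,
        "fin": fin, "res": res, "mar": mar, "folic": folic, "multi": multi,
        "iv_idx": iv_idx,
    }


def _draw_covariates(params: CovariateParams, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the maternal covariate block as a labelled DataFrame."""
    r = _draw_raw(params, n, rng)
    iv_labels = np.array(["1y", "2y", "3_5y", "6_10y", "ge11y"])
    fam_labels = np.array(["parent", "family_other", "none"])
    return pd.DataFrame({
        "maternal_age_years": r["age"],
        "height_cm": r["height"],
        "prepreg_weight_kg": r["weight"],
        "prepreg_bmi": r["bmi"],
        "gwg_kg": r["gwg"],
        "parity": r["parity"],
        "fetal_sex": np.where(r["son"], "son", "daughter"),
        "gestational_age_weeks": r["ga"],
        "gdm": np.array(["none", "gdm1", "gdm2"])[r["gdm_idx"]],
        "prior_macrosomia": np.where(r["prior_mac"], "yes", "no"),
        "prior_gdm": np.where(r["prior_gdm"], "yes", "no"),
        "prior_cesarean": np.where(r["prior_ces"], "yes", "no"),
        "family_dm_mother": fam_labels[r["fam_m"]],
        "family_dm_father": fam_labels[r["fam_f"]],
        "smoking": np.array(["never", "ex", "current"])[r["smoking"]],
        "education": np.where(r["edu"], "lt12", "ge12"),
        "financial_status": np.where(r["fin"], "lower", "higher"),
        "residence": np.array(["village", "small_town", "large_city"])[r["res"]],
        "marital_status": np.array(["married", "divorced", "unmarried"])[r["mar"]],
        "folic_acid": np.where(r["folic"], "yes", "no"),
        "multivitamin": np.where(r["multi"], "yes", "no"),
        "interpregnancy_interval": np.where(
            r["parity"] > 0, iv_labels[r["iv_idx"]], "primigravida"),
    })


def _bw_design(data) -> dict[str, np.ndarray]:
    """Centered feature columns of the birthweight model.

    Accepts either a labelled cohort DataFrame or the raw draw dict.
    """
    if isinstance(data, pd.DataFrame):
        ga = data["gestational_age_weeks"].to_numpy(dtype=float)
        parity = np.minimum(data["parity"].to_numpy(dtype=int), 3)
        weight = data["prepreg_weight_kg"].to_numpy(dtype=float)
        gwg = data["gwg_kg"].to_numpy(dtype=float)
        height = data["height_cm"].to_numpy(dtype=float)
        age = data["maternal_age_years"].to_numpy(dtype=float)
        son = (data["fetal_sex"].to_numpy() == "son").astype(float)
        gdm1 = (data["gdm"].to_numpy() == "gdm1").astype(float)
        gdm2 = (data["gdm"].to_numpy() == "gdm2").astype(float)
        prior_mac = (data["prior_macrosomia"].to_numpy() == "yes").astype(float)
    else:
        ga = data["ga"].astype(float)
        parity = np.minimum(data["parity"], 3)
        weight, gwg, height, age = data["weight"], data["gwg"], data["height"], data["age"]
        son = data["son"].astype(float)
        gdm1 = (data["gdm_idx"] == 1).astype(float)
        gdm2 = (data["gdm_idx"] == 2).astype(float)
        prior_mac = data["prior_mac"].astype(float)
    return {
        "prepreg_weight_kg": weight - _CENTERS["prepreg_weight_kg"],
        "gwg_kg": gwg - _CENTERS["gwg_kg"],
        "height_cm": height - _CENTERS["height_cm"],
        "son": son,
        "gestational_age_weeks": ga - _CENTERS["gestational_age_weeks"],
        "preterm_hinge": np.maximum(37.0 - ga, 0.0),
        "gdm1": gdm1,
        "gdm2": gdm2,
        "prior_macrosomia": prior_mac,
        "maternal_age_years": age - _CENTERS["maternal_age_years"],
        "parity1": (parity == 1).astype(float),
        "parity2": (parity == 2).astype(float),
        "parity3": (parity == 3).astype(float),
    }


def _linear_predictor(data, model: BirthweightModel) -> np.ndarray:
    feats = _bw_design(data)
    lp = np.full(len(feats["son"]), model.intercept, dtype=float)
    for name, beta in model.coef.items():
        lp += beta * feats[name]
    return lp


# ---------------------------------------------------------------------------
# reference growth grid
# ---------------------------------------------------------------------------

@dataclass
class ReferenceGrowthGrid:
    """Sex- and gestational-week-specific reference birthweight distribution.

    Holds, for each (fetal sex, completed week), the mean and SD of a normal
    reference distribution; the 10th/90th percentiles derived from it define
    the small/large-for-gestational-age bands.  The built-in default grid is
    synthetic: it is derived from the cohort generator's own birthweight
    model, not from any published national percentile reference.
    """

    table: pd.DataFrame  # columns: fetal_sex, week, mean_g, sd_g

    def __post_init__(self) -> None:
        t = self.table
        required = {"fetal_sex", "week", "mean_g", "sd_g"}
        if not required.issubset(t.columns):
            raise ConfigError(f"grid table needs columns {sorted(required)}")
        if (t["sd_g"] <= 0).any():
            raise ConfigError("grid: sd_g must be positive")
        for sex, sub in t.groupby("fetal_sex"):
            m = sub.sort_values("week")["mean_g"].to_numpy()
            if np.any(np.diff(m) <= 0):
                raise ConfigError(f"grid: mean_g must increase with week for sex {sex!r}")
        self._lookup = {
            (r.fetal_sex, int(r.week)): (float(r.mean_g), float(r.sd_g))
            for r in t.itertuples()
        }

    def percentile(self, sex: str, week: int, q: float) -> float:
        try:
            mean, sd = self._lookup[(sex, int(week))]
        except KeyError:
            raise ValueError(
                f"gestational week {week} (sex {sex!r}) outside the reference grid") from None
        return mean + float(stats.norm.ppf(q)) * sd

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReferenceGrowthGrid":
        return cls(pd.read_csv(path))


def assign_lga_band(birthweight_g, sex, gest_week, grid: ReferenceGrowthGrid):
    """Classify birthweight(s) against the 10th/90th reference percentiles.

    Returns ``"lt10"``, ``"10_90"`` or ``"gt90"`` (vectorized over array
    inputs).  Weeks outside the grid raise ``ValueError``.
    """
    bw = np.atleast_1d(np.asarray(birthweight_g, dtype=float))
    sexes = np.atleast_1d(np.asarray(sex))
    weeks = np.atleast_1d(np.asarray(gest_week, dtype=int))
    p10 = np.array([grid.percentile(s, w, 0.10) for s, w in zip(sexes, weeks)])
    p90 = np.array([grid.percentile(s, w, 0.90) for s, w in zip(sexes, weeks)])
    band = np.where(bw > p90, "gt90", np.where(bw < p10, "lt10", "10_90"))
    if np.isscalar(birthweight_g) or np.ndim(birthweight_g) == 0:
        return str(band[0])
    return band


# ---------------------------------------------------------------------------
# calibration of the default configuration
# ---------------------------------------------------------------------------

_CALIBRATION_SEED = 202_103
_CALIBRATION_N = 1_500_000


@functools.lru_cache(maxsize=8)
def _calibrate(params_key: tuple, coef_key: tuple, residual_sd: float,
               target: float) -> tuple[float, float, float]:
    """Root-find the birthweight intercept against the macrosomia target.

    Draws a large fixed-seed covariate sample, computes the no-intercept
    linear predictor plus residual noise R, and sets
    intercept = 4000 - quantile_{1-target}(R), so that
    P(birthweight > 4000) = target up to Monte-Carlo error.  Also returns the
    mean and SD of the non-(sex, gestational-age) part of the model, used to
    build the default reference growth grid.  Deterministic and cached.
    """
    params = CovariateParams(**dict(params_key))
    coef = dict(coef_key)
    rng = np.random.default_rng(_CALIBRATION_SEED)
    raw = _draw_raw(params, _CALIBRATION_N, rng)
    model = BirthweightModel(intercept=0.0, coef=coef, residual_sd=residual_sd)
    lp = _linear_predictor(raw, model)
    eps = rng.normal(0.0, residual_sd, _CALIBRATION_N)
    r = lp + eps
    intercept = 4000.0 - float(np.quantile(r, 1.0 - target))
    # residual structure with the sex and gestational-age terms removed
    feats = _bw_design(raw)
    sex_ga = (coef.get("son", 0.0) * feats["son"]
              + coef.get("gestational_age_weeks", 0.0) * feats["gestational_age_weeks"]
              + coef.get("preterm_hinge", 0.0) * feats["preterm_hinge"])
    others = r - sex_ga
    return intercept, float(others.mean()), float(others.std())


def _params_key(params: CovariateParams) -> tuple:
    return tuple(sorted(
        (k, tuple(v) if isinstance(v, (tuple, list)) else float(v))
        for k, v in vars(params).items()
    ))


def default_grid(config: GeneratorConfig) -> ReferenceGrowthGrid:
    """Synthetic reference grid derived from the configured birthweight model.

    For each (sex, completed week) the reference mean is the model's expected
    birthweight conditional on sex and week (marginalizing the remaining
    covariates), and the SD is the pooled conditional SD.  By construction
    roughly 10 % of generated newborns fall above the 90th percentile.
    """
    coef = config.birthweight_model.coef
    _, m_others, s_others = _calibrate(
        _params_key(config.covariate_params),
        tuple(sorted(coef.items())),
        config.birthweight_model.residual_sd,
        config.macrosomia_target,
    )
    rows = []
    for sex, son in (("daughter", 0.0), ("son", 1.0)):
        for week in range(GA_MIN, GA_MAX + 1):
            mean = (config.birthweight_model.intercept + m_others
                    + coef.get("son", 0.0) * son
                    + coef.get("gestational_age_weeks", 0.0) * (week - _CENTERS["gestational_age_weeks"])
                    + coef.get("preterm_hinge", 0.0) * max(37.0 - week, 0.0))
            rows.append({"fetal_sex": sex, "week": week, "mean_g": mean, "sd_g": s_others})
    return ReferenceGrowthGrid(pd.DataFrame(rows))


def default_config() -> GeneratorConfig:
    """Default generator configuration calibrated to the emulated population.

    The birthweight intercept is solved at call time (cached) so that the
    configured macrosomia prevalence equals the 10.6 % target; all other
    parameters are the fixed defaults documented in :class:`CovariateParams`
    and :data:`_DEFAULT_BW_COEF`.
    """
    params = CovariateParams()
    coef = dict(_DEFAULT_BW_COEF)
    residual_sd = 310.0
    target = 0.106
    intercept, _, _ = _calibrate(
        _params_key(params), tuple(sorted(coef.items())), residual_sd, target)
    cfg = GeneratorConfig(
        n_participants=912,
        seed=0,
        covariate_params=params,
        birthweight_model=BirthweightModel(intercept=intercept, coef=coef, residual_sd=residual_sd),
        missingness_rates=dict(_DEFAULT_MISSING),
        macrosomia_target=target,
    )
    cfg.validate()
    return cfg


def dominant_weight_config() -> GeneratorConfig:
    """Configuration with pre-pregnancy weight decisively dominant.

    Used by the hierarchy-recovery experiment: the weight coefficient is
    raised to 20 g/kg while the competing gestational-weight-gain and height
    terms are shrunk and the residual SD tightened, so that pre-pregnancy
    weight is unambiguously the strongest single predictor of macrosomia in
    the generating model.  The macrosomia prevalence stays calibrated at the
    default target.
    """
    coef = dict(_DEFAULT_BW_COEF)
    coef.update({"prepreg_weight_kg": 20.0, "gwg_kg": 4.0, "height_cm": 0.0})
    residual_sd = 250.0
    params = CovariateParams()
    target = 0.106
    intercept, _, _ = _calibrate(
        _params_key(params), tuple(sorted(coef.items())), residual_sd, target)
    cfg = GeneratorConfig(
        n_participants=912, seed=0, covariate_params=params,
        birthweight_model=BirthweightModel(intercept=intercept, coef=coef,
                                           residual_sd=residual_sd),
        missingness_rates=dict(_DEFAULT_MISSING), macrosomia_target=target)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# cohort table
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Participant-level cohort: one row per pregnancy.

    Wraps a DataFrame with the columns in :data:`COLUMNS`; missing values are
    NaN.  Outcome bands (``weight_band``, ``lga_band``) partition the cohort.
    """

    df: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.df)

    def validate(self) -> None:
        missing_cols = [c for c in COLUMNS if c not in self.df.columns]
        if missing_cols:
            raise ValueError(f"cohort table missing columns: {missing_cols}")
        if self.n == 0:
            return
        bw = self.df["birthweight_g"]
        if (bw <= 0).any():
            raise ValueError("birthweight must be positive")
        ga = self.df["gestational_age_weeks"]
        if ((ga < GA_MIN) | (ga > 43)).any():
            raise ValueError(f"gestational age must lie in [{GA_MIN}, 43] weeks")
        both = self.df[["prepreg_weight_kg", "height_cm", "prepreg_bmi"]].dropna()
        expected = both["prepreg_weight_kg"] / (both["height_cm"] / 100.0) ** 2
        if not np.allclose(expected, both["prepreg_bmi"], atol=1e-9):
            raise ValueError("BMI does not equal weight / height(m)^2")

    def equals(self, other: "CohortTable") -> bool:
        try:
            pd.testing.assert_frame_equal(
                self.df.reset_index(drop=True), other.df.reset_index(drop=True),
                check_dtype=False)
            return True
        except AssertionError:
            return False


def derive_outcomes(df: pd.DataFrame, grid: ReferenceGrowthGrid) -> pd.DataFrame:
    """(Re)compute macrosomia, weight band and LGA band from birthweight."""
    df = df.copy()
    bw = df["birthweight_g"].to_numpy(dtype=float)
    df["macrosomia"] = (bw > 4000.0).astype(int)
    df["weight_band"] = np.where(
        bw > 4000.0, "gt4000", np.where(bw < 2500.0, "lt2500", "2500_4000"))
    df["lga_band"] = assign_lga_band(
        bw, df["fetal_sex"].to_numpy(), df["gestational_age_weeks"].to_numpy(), grid)
    return df


def generate_cohort(config: GeneratorConfig,
                    grid: ReferenceGrowthGrid | None = None) -> CohortTable:
    """Simulate one cohort under ``config`` (deterministic given the seed).

    Birthweight is drawn from the configured Gaussian linear model over the
    covariates; macrosomia and the weight/LGA bands are deterministic
    thresholds of it.  Missingness is then injected at the configured rates.
    """
    config.validate()
    if grid is None:
        grid = default_grid(config)
    n = config.n_participants
    rng = np.random.default_rng(config.seed)
    if n == 0:
        df = pd.DataFrame({c: pd.Series(dtype=float if c in _NUMERIC_COLUMNS else object)
                           for c in COLUMNS})
        return CohortTable(df)
    df = _draw_covariates(config.covariate_params, n, rng)
    lp = _linear_predictor(df, config.birthweight_model)
    bw = lp + rng.normal(0.0, config.birthweight_model.residual_sd, n)
    df["birthweight_g"] = np.maximum(bw, 300.0)  # floor: viable recruited birth
    df = derive_outcomes(df, grid)[COLUMNS]
    table = CohortTable(df)
    if any(r > 0 for r in config.missingness_rates.values()):
        miss_seed = int(rng.integers(0, 2**31 - 1))
        table = inject_missingness(table, config.missingness_rates, miss_seed)
    table.validate()
    return table


def inject_missingness(table: CohortTable, rates: dict[str, float], seed: int) -> CohortTable:
    """Independently blank targeted cells at the given per-variable rates.

    Only variables whose codings carry an 'unknown' category (plus the
    self-reported supplement/smoking fields) may be blanked; outcomes and the
    base-model variables (maternal age, parity) never go missing.
    """
    for var, rate in rates.items():
        if var not in MISSABLE_VARIABLES:
            raise ValueError(
                f"{var!r} may not be set missing (allowed: {MISSABLE_VARIABLES})")
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missingness rate for {var!r} outside [0, 1]: {rate}")
    df = table.df.copy()
    rng = np.random.default_rng(seed)
    for var in MISSABLE_VARIABLES:  # fixed order for determinism
        rate = rates.get(var, 0.0)
        if rate > 0 and len(df):
            mask = rng.random(len(df)) < rate
            df.loc[mask, var] = np.nan
    return CohortTable(df)
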