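"""Synthetic participant-level cohorts with known mediation ground truth.

The generator emulates a baseline examination table of a large adult
population cohort: five childhood-trauma screener (CTS) items, smoking
history (initiation / quit ages), a four-point weight history (weight
versus peers at age 10, weights at 18/30/50, measured baseline weight and
height), self-reported diagnoses with ages at first diagnosis, and the
adjustment covariates (baseline age, sex, study center, education years,
birth year).

The causal structure is the one the downstream analysis assumes:

* exposures (abuse, neglect) are correlated Bernoulli draws;
* each binary mediator status follows a logistic model
  ``logit P(M=1) = g0 + g1*A + gC'c``;
* each disease indicator follows a log-linear risk
  ``P(Y=1) = exp(l0 + l1*A + l2*M + l3*A*M + lC'c)`` (a Bernoulli draw
  with that mean -- the Poisson likelihood is an estimation device, not a
  data model);
* histories are generated *backwards* from the mediator status: an ever
  smoker receives an initiation age strictly before every diagnosis age
  (and before baseline), so the time-sequenced derivation recovers the
  generative mediator exactly under the default configuration.  A config
  switch injects initiation-after-diagnosis records to exercise the
  timing filter.

``true_mediation_effects`` integrates the generative models over the
binary mediator in closed form, giving the exact estimands implied by a
configuration -- the ground truth for parameter-recovery experiments.

Covariates enter the generative models through centred transforms
(``age_c`` = (age-47)/10, ``female`` indicator, ``education_c`` =
(years-15.7)/3); all covariate coefficients default to zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import truncnorm

from . import mediation_engine as me

COVARIATE_TERMS = ("age_c", "female", "education_c")
MEDIATOR_NAMES = ("ever_smoking", "early_overweight")
DISEASES = ("cancer", "mi", "stroke", "diabetes", "copd", "anxiety", "depression")

#: cancer-site vocabulary used for the first-tumour report
CANCER_SITES = (
    "oral_cavity", "pharynx", "esophagus", "stomach", "pancreas", "intestines",
    "larynx", "lung", "kidney", "urinary_tract", "urinary_bladder", "leukemia",
    "liver", "breast", "cervix", "skin", "thyroid", "brain",
    "non_hodgkin_lymphoma", "gall_bladder", "prostate", "uterus", "ovaries",
    "testis",
)


class ConfigurationError(ValueError):
    """Raised when a cohort is requested from an invalid configuration."""


class CovariateModel(BaseModel):
    age_range: tuple[int, int] = (19, 75)
    female_fraction: float = 0.4944
    n_centers: int = 18
    education_mean: float = 15.7
    education_sd: float = 2.8
    education_range: tuple[int, int] = (8, 20)


class MediatorModel(BaseModel):
    """Logistic mediator-status model: logit p = intercept + exposure_coef*A + cov'c."""

    intercept: float
    exposure_coef: float
    covariate_coefs: dict[str, float] = Field(default_factory=dict)


class DiseaseModel(BaseModel):
    """Log-linear disease-risk model driven by one mediator."""

    mediator: Literal["ever_smoking", "early_overweight"]
    intercept: float
    exposure_coef: float
    mediator_coef: float
    interaction_coef: float = 0.0
    covariate_coefs: dict[str, float] = Field(default_factory=dict)


class TimingModel(BaseModel):
    smoking_init_mean: float = 17.9
    smoking_init_sd: float = 3.0
    smoking_init_min: int = 10
    quit_probability: float = 0.55
    overweight_age10_share: float = 0.455  # share of early overweight qualifying at age 10 only
    late_overweight_given_early: float = 0.70
    late_overweight_given_not: float = 0.179
    dx_age_mean: float = 48.0
    dx_age_sd: float = 10.0
    dx_age_min: int = 19
    init_after_dx_fraction: float = 0.0  # injects records violating the time sequence


class MissingnessModel(BaseModel):
    """Per-field-group missing-completely-at-random rates."""

    cts: float = 0.0
    smoking: float = 0.0
    weight: float = 0.0
    disease: float = 0.0
    dx_age: float = 0.0
    education: float = 0.0


class CohortConfig(BaseModel):
    n_participants: int = 10_000
    seed: int = 0
    abuse_prevalence: float = 0.1632
    neglect_prevalence: float = 0.1493
    exposure_correlation: float = 0.227  # phi coefficient of the two exposures
    driving_exposure: Literal["abuse", "neglect"] = "abuse"
    baseline_year: int = 2014
    covariates: CovariateModel = Field(default_factory=CovariateModel)
    mediators: dict[str, MediatorModel] = Field(default_factory=dict)
    diseases: dict[str, DiseaseModel] = Field(default_factory=dict)
    timing: TimingModel = Field(default_factory=TimingModel)
    missingness: MissingnessModel = Field(default_factory=MissingnessModel)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.model_dump_json(indent=2))

    @classmethod
    def from_json(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.model_validate_json(fh.read())


# ----------------------------------------------------------------------
# validation
# ----------------------------------------------------------------------

def _covariate_support(cov: CovariateModel) -> dict[str, tuple[float, float]]:
    lo_a, hi_a = cov.age_range
    lo_e, hi_e = cov.education_range
    return {
        "age_c": ((lo_a - 47.0) / 10.0, (hi_a - 47.0) / 10.0),
        "female": (0.0, 1.0),
        "education_c": ((lo_e - 15.7) / 3.0, (hi_e - 15.7) / 3.0),
    }


def _joint_exposure(config: CohortConfig) -> float:
    """P(abuse & neglect) implied by the phi-coefficient knob."""
    pa, pn = config.abuse_prevalence, config.neglect_prevalence
    return config.exposure_correlation * np.sqrt(
        pa * (1 - pa) * pn * (1 - pn)) + pa * pn


def validate_config(config: CohortConfig) -> list[str]:
    """Return all invariant violations (empty list == valid). Never raises."""
    v: list[str] = []
    if config.n_participants < 0:
        v.append(f"n_participants must be >= 0, got {config.n_participants}")
    for name, p in [
        ("abuse_prevalence", config.abuse_prevalence),
        ("neglect_prevalence", config.neglect_prevalence),
        ("covariates.female_fraction", config.covariates.female_fraction),
        ("timing.quit_probability", config.timing.quit_probability),
        ("timing.overweight_age10_share", config.timing.overweight_age10_share),
        ("timing.late_overweight_given_early", config.timing.late_overweight_given_early),
        ("timing.late_overweight_given_not", config.timing.late_overweight_given_not),
        ("timing.init_after_dx_fraction", config.timing.init_after_dx_fraction),
        ("missingness.cts", config.missingness.cts),
        ("missingness.smoking", config.missingness.smoking),
        ("missingness.weight", config.missingness.weight),
        ("missingness.disease", config.missingness.disease),
        ("missingness.dx_age", config.missingness.dx_age),
        ("missingness.education", config.missingness.education),
    ]:
        if not 0.0 <= p <= 1.0:
            v.append(f"{name} must be a probability in [0, 1], got {p}")
    pa, pn = config.abuse_prevalence, config.neglect_prevalence
    if 0 <= pa <= 1 and 0 <= pn <= 1:
        p11 = _joint_exposure(config)
        lo = max(0.0, pa + pn - 1.0)
        hi = min(pa, pn)
        if not lo - 1e-12 <= p11 <= hi + 1e-12:
            v.append(
                f"exposure_correlation {config.exposure_correlation} implies joint "
                f"prevalence {p11:.4f} outside the feasible range [{lo:.4f}, {hi:.4f}]")
    if config.covariates.n_centers < 1:
        v.append(f"covariates.n_centers must be >= 1, got {config.covariates.n_centers}")
    support = _covariate_support(config.covariates)
    for dname, dm in config.diseases.items():
        if dm.mediator not in config.mediators:
            v.append(f"disease {dname!r} references unknown mediator {dm.mediator!r}")
            continue
        l1, l2, l3 = dm.exposure_coef, dm.mediator_coef, dm.interaction_coef
        lp = dm.intercept + max(0.0, l1, l2, l1 + l2 + l3)
        for term, coef in dm.covariate_coefs.items():
            lo, hi = support.get(term, (0.0, 0.0))
            lp += max(coef * lo, coef * hi)
        if lp > 1e-12:
            v.append(f"disease {dname!r}: risk exceeds 1 (sup log-risk = {lp:.4f} > 0)")
    t = config.timing
    if not 10 <= t.dx_age_min <= 75:
        v.append(f"timing.dx_age_min must lie in [10, 75], got {t.dx_age_min}")
    if not 10 <= t.smoking_init_min <= 75:
        v.append(f"timing.smoking_init_min must lie in [10, 75], got {t.smoking_init_min}")
    if t.smoking_init_sd <= 0 or t.dx_age_sd <= 0:
        v.append("timing standard deviations must be positive")
    lo_a, hi_a = config.covariates.age_range
    if not (18 <= lo_a <= hi_a <= 100):
        v.append(f"covariates.age_range must satisfy 18 <= lo <= hi <= 100, got {config.covariates.age_range}")
    return v


# ----------------------------------------------------------------------
# generation
# ----------------------------------------------------------------------

#: the cohort CSV dialect: column -> (description, units / allowed codes).
#: Missing values are empty fields.
COLUMN_DICTIONARY: dict[str, tuple[str, str]] = {
    "participant_id": ("running identifier", "integer >= 1"),
    "baseline_age": ("age at the baseline examination", "years"),
    "sex": ("sex", "M | F"),
    "center": ("study-center identifier", "C01..Cxx"),
    "education_years": ("years of education", "years, 8-20"),
    "birth_year": ("calendar year of birth", "baseline year - baseline age"),
    "cts_1": ("trauma screener: emotional abuse", "1 (never) .. 5 (very often)"),
    "cts_2": ("trauma screener: physical abuse", "1..5"),
    "cts_3": ("trauma screener: sexual abuse", "1..5"),
    "cts_4": ("trauma screener: emotional neglect (positively phrased)", "1..5"),
    "cts_5": ("trauma screener: physical neglect (positively phrased)", "1..5"),
    "ever_smoked": ("ever smoked regularly", "0 | 1"),
    "smoking_init_age": ("age at smoking initiation (smokers only)", "years"),
    "smoking_quit_age": ("age at last smoking cessation, if quit", "years"),
    "weight_at_10": ("weight compared to peers at age 10", "lower | regular | higher"),
    "weight_kg_18": ("reported weight at age 18", "kg"),
    "weight_kg_30": ("reported weight at age 30 (empty if younger)", "kg"),
    "weight_kg_50": ("reported weight at age 50 (empty if younger)", "kg"),
    "baseline_weight_kg": ("measured baseline weight", "kg"),
    "baseline_height_m": ("measured baseline height", "m"),
    "cancer_site": ("site of the first tumour (cancer cases only)",
                    "controlled vocabulary, see CANCER_SITES"),
    **{f"diagnosed_{d}": (f"ever diagnosed with {d}", "0 | 1") for d in DISEASES},
    **{f"age_at_dx_{d}": (f"age at first {d} diagnosis (cases only)", "years")
       for d in DISEASES},
    "_gen_ever_smoking": ("generator ground truth: ever-smoking mediator status", "0 | 1"),
    "_gen_early_overweight": ("generator ground truth: early-overweight status", "0 | 1"),
}

COHORT_COLUMNS = tuple(COLUMN_DICTIONARY)


def _trunc_int(rng, mean, sd, lo, hi):
    """Row-wise truncated-normal draw rounded down to integers in [lo, hi]."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    a = (lo - mean) / sd
    b = (hi + 1.0 - mean) / sd
    u = rng.random(lo.shape[0] if lo.ndim else 1)
    x = truncnorm.ppf(u, a, b, loc=mean, scale=sd)
    return np.clip(np.floor(x), lo, hi).astype(float)


def _cts_items(rng, abuse, neglect):
    n = abuse.size
    items = np.empty((n, 5), dtype=float)
    # benign defaults: abuse items below cut-off, neglect items above
    items[:, 0] = rng.choice([1, 2], n, p=[0.7, 0.3])
    items[:, 1] = rng.choice([1, 2], n, p=[0.8, 0.2])
    items[:, 2] = 1
    items[:, 3] = rng.choice([3, 4, 5], n, p=[0.2, 0.35, 0.45])
    items[:, 4] = rng.choice([3, 4, 5], n, p=[0.2, 0.35, 0.45])
    # abused participants: elevate one abuse subscale (emotional/physical/sexual)
    kind = rng.choice(3, n, p=[0.45, 0.30, 0.25])
    em = abuse & (kind == 0)
    ph = abuse & (kind == 1)
    sx = abuse & (kind == 2)
    items[em, 0] = rng.choice([3, 4, 5], int(em.sum()), p=[0.6, 0.3, 0.1])
    items[ph, 1] = rng.choice([3, 4, 5], int(ph.sum()), p=[0.6, 0.3, 0.1])
    items[sx, 2] = rng.choice([2, 3, 4, 5], int(sx.sum()), p=[0.5, 0.3, 0.15, 0.05])
    # neglected participants: lower one (positively phrased) neglect item
    which = rng.random(n) < 0.5
    emn = neglect & which
    phn = neglect & ~which
    items[emn, 3] = rng.choice([1, 2], int(emn.sum()), p=[0.45, 0.55])
    items[phn, 4] = rng.choice([1, 2], int(phn.sum()), p=[0.45, 0.55])
    return items


def generate_cohort(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a cohort table; identical (config, seed) pairs are bit-identical."""
    violations = validate_config(config)
    if violations:
        raise ConfigurationError(violations[0])
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.n_participants
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=object) for c in COHORT_COLUMNS})

    cov = config.covariates
    age = rng.integers(cov.age_range[0], cov.age_range[1] + 1, n).astype(float)
    female = rng.random(n) < cov.female_fraction
    center = np.array([f"C{k:02d}" for k in rng.integers(1, cov.n_centers + 1, n)])
    edu = np.clip(np.rint(rng.normal(cov.education_mean, cov.education_sd, n)),
                  cov.education_range[0], cov.education_range[1])
    birth_year = config.baseline_year - age

    # exposures with configured phi correlation
    pa, pn = config.abuse_prevalence, config.neglect_prevalence
    p11 = _joint_exposure(config)
    abuse = rng.random(n) < pa
    pn_cond = np.where(abuse, p11 / pa if pa > 0 else 0.0,
                       (pn - p11) / (1 - pa) if pa < 1 else 0.0)
    neglect = rng.random(n) < pn_cond
    items = _cts_items(rng, abuse, neglect)

    a_drive = (abuse if config.driving_exposure == "abuse" else neglect).astype(float)
    cvals = {
        "age_c": (age - 47.0) / 10.0,
        "female": female.astype(float),
        "education_c": (edu - 15.7) / 3.0,
    }

    def cov_lp(coefs: dict[str, float]) -> np.ndarray:
        lp = np.zeros(n)
        for term, coef in coefs.items():
            lp += coef * cvals[term]
        return lp

    med_status: dict[str, np.ndarray] = {}
    for mname in MEDIATOR_NAMES:
        if mname in config.mediators:
            mm = config.mediators[mname]
            lp = mm.intercept + mm.exposure_coef * a_drive + cov_lp(mm.covariate_coefs)
            med_status[mname] = rng.random(n) < expit(lp)
        else:
            med_status[mname] = rng.random(n) < (0.528 if mname == "ever_smoking" else 0.171)
    smoker = med_status["ever_smoking"]
    early_ow = med_status["early_overweight"]

    diagnosed: dict[str, np.ndarray] = {}
    for dname in DISEASES:
        if dname in config.diseases:
            dm = config.diseases[dname]
            m = med_status[dm.mediator].astype(float)
            lp = (dm.intercept + dm.exposure_coef * a_drive + dm.mediator_coef * m
                  + dm.interaction_coef * a_drive * m + cov_lp(dm.covariate_coefs))
            diagnosed[dname] = rng.random(n) < np.exp(lp)
        else:
            diagnosed[dname] = np.zeros(n, dtype=bool)

    t = config.timing
    dx_age: dict[str, np.ndarray] = {}
    min_dx = np.full(n, np.inf)
    for dname in DISEASES:
        case = diagnosed[dname]
        ages = np.full(n, np.nan)
        if case.any():
            lo = np.full(int(case.sum()), float(t.dx_age_min))
            hi = np.maximum(age[case], lo)  # diagnosis no later than baseline
            ages[case] = _trunc_int(rng, t.dx_age_mean, t.dx_age_sd, lo, hi)
        dx_age[dname] = ages
        min_dx = np.fmin(min_dx, np.where(case, ages, np.inf))
    ref_age = np.minimum(min_dx, age)  # history horizon: earliest diagnosis, else baseline

    # smoking history, generated backwards from the mediator status
    init_age = np.full(n, np.nan)
    quit_age = np.full(n, np.nan)
    if smoker.any():
        ub = ref_age[smoker] - 1.0
        init_age[smoker] = _trunc_int(rng, t.smoking_init_mean, t.smoking_init_sd,
                                      np.full(int(smoker.sum()), float(t.smoking_init_min)),
                                      np.maximum(ub, float(t.smoking_init_min)))
        if t.init_after_dx_fraction > 0:
            cand = smoker & np.isfinite(min_dx)
            inject = cand & (rng.random(n) < t.init_after_dx_fraction)
            if inject.any():
                lo = min_dx[inject]
                hi = np.maximum(age[inject], lo)
                init_age[inject] = _trunc_int(rng, t.dx_age_mean + 2.0, 5.0, lo, hi)
        quits = smoker & (rng.random(n) < t.quit_probability)
        if quits.any():
            lo = init_age[quits] + 1.0
            hi = np.maximum(age[quits], lo)
            quit_age[quits] = np.floor(lo + rng.random(int(quits.sum())) * (hi - lo + 1.0))
            quit_age[quits] = np.minimum(quit_age[quits], hi)

    # weight history, generated backwards from the overweight status
    height = np.where(female, rng.normal(1.65, 0.065, n), rng.normal(1.78, 0.07, n))
    height = np.clip(height, 1.45, 2.05)
    via_10 = early_ow & (rng.random(n) < t.overweight_age10_share)
    via_18 = early_ow & ~via_10
    weight_at_10 = np.where(rng.random(n) < 0.15, "lower", "regular").astype(object)
    weight_at_10[via_10] = "higher"
    bmi18 = rng.uniform(19.0, 24.9, n)
    bmi18[via_18] = rng.uniform(25.0, 32.0, int(via_18.sum()))
    p_late = np.where(early_ow, t.late_overweight_given_early, t.late_overweight_given_not)
    late_ow = rng.random(n) < p_late
    bmi30 = np.where(late_ow, rng.uniform(25.0, 33.0, n), rng.uniform(19.0, 24.9, n))
    bmi50 = np.where(late_ow, bmi30 + rng.uniform(0.0, 3.0, n),
                     rng.uniform(19.0, 24.9, n))
    w18 = bmi18 * height**2
    w30 = np.where(age >= 30, bmi30 * height**2, np.nan)
    w50 = np.where(age >= 50, bmi50 * height**2, np.nan)
    last_bmi = np.where(age >= 50, bmi50, np.where(age >= 30, bmi30, bmi18))
    baseline_weight = (last_bmi + rng.uniform(-1.0, 2.0, n)) * height**2

    # first-tumour site for cancer cases
    site = np.full(n, None, dtype=object)
    cancer = diagnosed["cancer"]
    if cancer.any():
        site_vocab = np.array(["breast", "intestines", "prostate", "lung", "skin",
                               "stomach", "kidney", "thyroid", "leukemia", "cervix",
                               "testis"], dtype=object)
        site_p = np.array([0.24, 0.15, 0.12, 0.12, 0.14, 0.05, 0.05, 0.04, 0.04,
                           0.03, 0.02])
        site[cancer] = rng.choice(site_vocab, int(cancer.sum()), p=site_p)

    df = pd.DataFrame({
        "participant_id": np.arange(1, n + 1),
        "baseline_age": age,
        "sex": np.where(female, "F", "M"),
        "center": center,
        "education_years": edu,
        "birth_year": birth_year,
        **{f"cts_{i + 1}": items[:, i] for i in range(5)},
        "ever_smoked": smoker.astype(float),
        "smoking_init_age": init_age,
        "smoking_quit_age": quit_age,
        "weight_at_10": weight_at_10,
        "weight_kg_18": w18,
        "weight_kg_30": w30,
        "weight_kg_50": w50,
        "baseline_weight_kg": baseline_weight,
        "baseline_height_m": height,
        "cancer_site": site,
        **{f"diagnosed_{d}": diagnosed[d].astype(float) for d in DISEASES},
        **{f"age_at_dx_{d}": dx_age[d] for d in DISEASES},
        "_gen_ever_smoking": smoker.astype(float),
        "_gen_early_overweight": early_ow.astype(float),
    })[list(COHORT_COLUMNS)]

    # MCAR missingness by field group
    miss = config.missingness
    groups = {
        "cts": ([f"cts_{i}" for i in range(1, 6)], miss.cts),
        "smoking": (["ever_smoked", "smoking_init_age", "smoking_quit_age"], miss.smoking),
        "weight": (["weight_at_10", "weight_kg_18", "weight_kg_30", "weight_kg_50"], miss.weight),
        "education": (["education_years"], miss.education),
    }
    for cols, rate in groups.values():
        if rate > 0:
            mask = rng.random(n) < rate
            df.loc[mask, cols] = np.nan
    if miss.disease > 0:
        for d in DISEASES:
            mask = rng.random(n) < miss.disease
            df.loc[mask, [f"diagnosed_{d}", f"age_at_dx_{d}"]] = np.nan
    if miss.dx_age > 0:
        for d in DISEASES:
            mask = (rng.random(n) < miss.dx_age) & (df[f"diagnosed_{d}"] == 1)
            df.loc[mask, f"age_at_dx_{d}"] = np.nan
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sex": str, "center": str, "weight_at_10": object,
                                  "cancer_site": object})
    return df


# ----------------------------------------------------------------------
# ground truth
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class MediationTruth:
    """Exact estimands implied by a generative configuration at covariates c."""

    rr_te: float
    rr_pde: float
    rr_tie: float
    pm: float
    err_cde: float
    err_intref: float
    err_pie: float
    err_intmed: float

    def check_identities(self, tol: float = 1e-12) -> None:
        assert abs(self.rr_te - self.rr_pde * self.rr_tie) <= tol * max(1.0, abs(self.rr_te))
        s = self.err_cde + self.err_intref + self.err_pie + self.err_intmed
        assert abs(s - (self.rr_te - 1.0)) <= tol * max(1.0, abs(self.rr_te - 1.0))


def _packed_models(config: CohortConfig, disease: str) -> tuple[np.ndarray, np.ndarray]:
    if disease not in config.diseases:
        raise KeyError(f"unknown disease {disease!r}; configured: {sorted(config.diseases)}")
    dm = config.diseases[disease]
    mm = config.mediators[dm.mediator]
    theta = np.array([dm.intercept, dm.exposure_coef, dm.mediator_coef, dm.interaction_coef]
                     + [dm.covariate_coefs.get(t, 0.0) for t in COVARIATE_TERMS])
    beta = np.array([mm.intercept, mm.exposure_coef]
                    + [mm.covariate_coefs.get(t, 0.0) for t in COVARIATE_TERMS])
    return theta, beta


def true_mediation_effects(config: CohortConfig, disease: str,
                           c: Sequence[float] | None = None) -> MediationTruth:
    """Closed-form estimands implied by (gamma, lambda) at covariate value c.

    ``c`` is over ``COVARIATE_TERMS`` (centred age, female indicator,
    centred education); default zeros = a 47-year-old man with 15.7
    education years.  Deterministic: no seed involved.
    """
    violations = validate_config(config)
    if violations:
        raise ConfigurationError(violations[0])
    theta, beta = _packed_models(config, disease)
    c_arr = np.zeros(len(COVARIATE_TERMS)) if c is None else np.asarray(c, dtype=float)
    est = me._estimands(theta, beta, c_arr)
    return MediationTruth(**{k: float(est[k]) for k in me.ESTIMANDS})


# ----------------------------------------------------------------------
# calibration helpers and ready-made configurations
# ----------------------------------------------------------------------

def mediator_from_margin(margin: float, rr: float, exposure_prev: float) -> MediatorModel:
    """Logistic mediator coefficients hitting a marginal prevalence and a
    conditional risk ratio (unexposed vs exposed), covariate-free."""
    p0 = margin / (1.0 + exposure_prev * (rr - 1.0))
    p1 = p0 * rr
    if not (0 < p0 < 1 and 0 < p1 < 1):
        raise ValueError(f"margin {margin} with RR {rr} not attainable")
    return MediatorModel(intercept=float(logit(p0)), exposure_coef=float(logit(p1) - logit(p0)))


def solve_disease(mediator_name: str, mediator: MediatorModel, exposure_prev: float,
                  prevalence: float, total_rr: float, pm: float,
                  interaction_coef: float = 0.05) -> DiseaseModel:
    """Find (l0, l1, l2) so the covariate-free generative model has the
    requested marginal prevalence, total-effect RR and proportion mediated."""
    p0 = expit(mediator.intercept)
    p1 = expit(mediator.intercept + mediator.exposure_coef)
    l3 = interaction_coef

    def estimands(l2):
        k1 = np.exp(l2 + l3)   # exp(theta2 + theta3)
        k0 = np.exp(l2)
        rr_tie = ((1 - p1) + p1 * k1) / ((1 - p0) + p0 * k1)
        rr_pde_over_el1 = ((1 - p0) + p0 * k1) / ((1 - p0) + p0 * k0)
        rr_pde = total_rr / rr_tie
        l1 = np.log(rr_pde / rr_pde_over_el1)
        pm_val = rr_pde * (rr_tie - 1.0) / (total_rr - 1.0)
        return l1, pm_val

    l2 = brentq(lambda x: estimands(x)[1] - pm, -4.0, 4.0, xtol=1e-12)
    l1 = estimands(l2)[0]
    # intercept from the marginal prevalence over (A, M)
    mean_exp = ((1 - exposure_prev) * ((1 - p0) + p0 * np.exp(l2))
                + exposure_prev * np.exp(l1) * ((1 - p1) + p1 * np.exp(l2 + l3)))
    l0 = float(np.log(prevalence) - np.log(mean_exp))
    return DiseaseModel(mediator=mediator_name, intercept=l0, exposure_coef=float(l1),
                        mediator_coef=float(l2), interaction_coef=float(l3))


#: per-disease calibration targets: (mediator, marginal prevalence,
#: total-effect RR for the driving exposure, proportion mediated)
DISEASE_TARGETS: dict[str, tuple[str, float, float, float]] = {
    "cancer": ("ever_smoking", 0.0388, 1.16, 0.1390),
    "mi": ("ever_smoking", 0.0133, 1.26, 0.3688),
    "stroke": ("ever_smoking", 0.0122, 1.47, 0.06),
    "diabetes": ("early_overweight", 0.0397, 1.33, 0.1369),
    "copd": ("ever_smoking", 0.0283, 1.72, 0.12),
    "anxiety": ("ever_smoking", 0.0698, 2.18, 0.0561),
    "depression": ("ever_smoking", 0.1337, 2.26, 0.0266),
}


def calibrated_config(n_participants: int = 100_000, seed: int = 0) -> CohortConfig:
    """The default study conditions: margins and effects of the emulated
    population cohort (abuse 16.32%, neglect 14.93%, ever smoking 52.80%
    with exposure RR 1.23, early overweight 17.09% with RR 1.24, disease
    prevalences 1.2-13.4% with their reported total effects)."""
    pa = 0.1632
    mediators = {
        "ever_smoking": mediator_from_margin(0.5280, 1.23, pa),
        "early_overweight": mediator_from_margin(0.1709, 1.24, pa),
    }
    diseases = {
        d: solve_disease(m, mediators[m], pa, prev, rr, pm)
        for d, (m, prev, rr, pm) in DISEASE_TARGETS.items()
    }
    return CohortConfig(n_participants=n_participants, seed=seed,
                        mediators=mediators, diseases=diseases)


def pm_benchmark_config(true_pm: float, n_participants: int = 20_000,
                        seed: int = 0, prevalence: float = 0.10,
                        total_rr: float = 1.45,
                        interaction_coef: float = 0.05) -> tuple[CohortConfig, MediationTruth]:
    """Single-disease configuration whose exact proportion mediated equals
    ``true_pm`` (solved in closed form), for parameter-recovery studies."""
    pa = 0.1632
    mediators = {"ever_smoking": mediator_from_margin(0.5280, 1.23, pa)}
    disease = solve_disease("ever_smoking", mediators["ever_smoking"], pa,
                            prevalence, total_rr, true_pm, interaction_coef)
    config = CohortConfig(n_participants=n_participants, seed=seed,
                          mediators=mediators, diseases={"depression": disease})
    truth = true_mediation_effects(config, "depression")
    return config, truth
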