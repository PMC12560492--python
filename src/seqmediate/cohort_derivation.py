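"""Variable construction and time-sequencing rules.

This module turns a raw participant table into the disease-specific
analysis rectangles the regressions consume:

* CTS exposure scoring with the published cut-offs (abuse: emotional or
  physical item >= 3, or sexual item >= 2; neglect: emotional or physical
  neglect item <= 2 -- the neglect items are positively phrased, so *low*
  ratings indicate neglect);
* classification of a first-tumour site into smoking-related and
  obesity-related cancer (breast counts as smoking-related in women only);
* disease-specific mediator flags that respect the time sequence: a
  mediator counts only if its event (smoking initiation, overweight
  milestone) happened strictly before the reference age -- the age at
  first diagnosis for affected participants, the baseline age otherwise;
* complete-case assembly with an exclusion ledger that attributes every
  dropped row to exactly one first-matching reason.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DISEASES = ("cancer", "mi", "stroke", "diabetes", "copd", "anxiety", "depression")
#: analysis outcomes: the seven reported diseases plus the two cancer subtypes
OUTCOMES = DISEASES + ("cancer_smoking_related", "cancer_obesity_related")
EXPOSURES = ("abuse", "neglect")

EXCLUDED = "excluded"

SMOKING_RELATED_SITES = frozenset({
    "oral_cavity", "pharynx", "esophagus", "stomach", "pancreas", "intestines",
    "larynx", "lung", "kidney", "urinary_tract", "urinary_bladder", "leukemia",
    "liver", "breast", "cervix",
})
OBESITY_RELATED_SITES = frozenset({
    "oral_cavity", "pharynx", "esophagus", "stomach", "pancreas", "intestines",
    "larynx", "skin", "kidney", "urinary_tract", "thyroid", "brain",
    "non_hodgkin_lymphoma", "liver", "gall_bladder", "breast", "prostate",
    "uterus", "ovaries",
})
KNOWN_SITES = SMOKING_RELATED_SITES | OBESITY_RELATED_SITES | {"testis"}


class MediatorVariant(str, Enum):
    ever_smoking = "ever_smoking"
    current_smoking = "current_smoking"
    early_overweight = "early_overweight"
    early_overweight_18plus = "early_overweight_18plus"
    late_overweight = "late_overweight"

    @property
    def is_smoking(self) -> bool:
        return self in (MediatorVariant.ever_smoking, MediatorVariant.current_smoking)


#: exclusion reasons in deterministic first-match order
EXCLUSION_ORDER = (
    "missing_cts", "missing_smoking", "missing_weight_history",
    "missing_disease_history", "missing_education",
    "missing_diagnosis_age", "diagnosed_before_18",
    "quit_before_diagnosis", "unaffected",
)


@dataclass
class ExclusionLedger:
    """Counts of removed rows keyed by (single, first-matching) reason."""

    n_input: int
    n_retained: int
    counts: dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        if self.n_input != self.n_retained + sum(self.counts.values()):
            raise AssertionError(
                f"ledger does not reconcile: {self.n_input} != "
                f"{self.n_retained} + {sum(self.counts.values())}")

    def to_json(self, path=None) -> str:
        payload = json.dumps({"n_input": self.n_input, "n_retained": self.n_retained,
                              "excluded": self.counts}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


@dataclass
class AnalysisTable:
    """Complete-case rectangle for one outcome x exposure x mediator cell."""

    df: pd.DataFrame
    ledger: ExclusionLedger
    outcome: str
    exposure: str
    variant: MediatorVariant
    outcome_kind: str

    def __len__(self) -> int:
        return len(self.df)


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x)) or pd.isna(x)


# ----------------------------------------------------------------------
# scalar rules (the canonical definitions; vectorized twins below)
# ----------------------------------------------------------------------

def score_cts(items: Sequence[float]) -> tuple[int, int]:
    """(abuse, neglect) flags from the five CTS items.

    Order: emotional abuse, physical abuse, sexual abuse, emotional
    neglect, physical neglect, each rated 1 (never) .. 5 (very often).
    """
    if len(items) != 5:
        raise ValueError("score_cts expects exactly 5 items")
    vals = [float(x) for x in items]
    if any(_is_missing(v) or not 1 <= v <= 5 for v in vals):
        raise ValueError(f"CTS items missing or out of range: {items}")
    e_ab, p_ab, s_ab, e_ne, p_ne = vals
    abuse = int(e_ab >= 3 or p_ab >= 3 or s_ab >= 2)
    neglect = int(e_ne <= 2 or p_ne <= 2)
    return abuse, neglect


def classify_cancer(site: str | None, sex: str) -> tuple[int, int]:
    """(smoking_related, obesity_related) flags for a first-tumour site.

    Breast cancer counts as smoking-related only for women; the
    obesity-related list carries breast without qualification.  Unknown
    sites classify as (0, 0) with a logged warning.
    """
    if _is_missing(site):
        logger.warning("cancer case without a site report; classified (0, 0)")
        return 0, 0
    site = str(site)
    if site not in KNOWN_SITES:
        logger.warning("unknown cancer site %r; classified (0, 0)", site)
        return 0, 0
    smoking = site in SMOKING_RELATED_SITES and not (site == "breast" and sex != "F")
    obesity = site in OBESITY_RELATED_SITES
    return int(smoking), int(obesity)


def _reference_age(record: Mapping, disease: str) -> float:
    """Age at first diagnosis for cases, baseline age otherwise."""
    base = "cancer" if disease.startswith("cancer") else disease
    diagnosed = record.get(f"diagnosed_{base}")
    if not _is_missing(diagnosed) and float(diagnosed) == 1.0:
        dx = record.get(f"age_at_dx_{base}")
        if not _is_missing(dx):
            return float(dx)
    return float(record["baseline_age"])


def derive_smoking_mediator(record: Mapping, disease: str, variant: MediatorVariant):
    """0/1 smoking-before-diagnosis flag, or ``"excluded"``.

    Never smokers are 0.  ``ever_smoking``: 1 iff initiation strictly
    before the reference age.  ``current_smoking``: smokers who quit
    before the reference age are excluded (never vs current comparison);
    initiation at or after the reference age codes 0.
    """
    variant = MediatorVariant(variant)
    if not variant.is_smoking:
        raise ValueError(f"{variant} is not a smoking variant")
    ever = record.get("ever_smoked")
    if _is_missing(ever):
        return EXCLUDED
    if float(ever) == 0.0:
        return 0
    init = record.get("smoking_init_age")
    if _is_missing(init):
        return EXCLUDED  # ever smoker without initiation age
    ref = _reference_age(record, disease)
    if float(init) >= ref:
        return 0  # initiation after (or at) diagnosis cannot mediate
    if variant is MediatorVariant.current_smoking:
        quit = record.get("smoking_quit_age")
        if not _is_missing(quit) and float(quit) < ref:
            return EXCLUDED
    return 1


def derive_overweight_mediator(record: Mapping, disease: str, variant: MediatorVariant):
    """0/1 overweight-before-diagnosis flag, or ``"excluded"``.

    Milestones are the assessment ages themselves: higher weight versus
    peers at 10, BMI >= 25 at 18 (early); BMI >= 25 at 30 or 50 (late).
    A milestone counts only if its age is strictly before the reference
    age.  BMI at 18/30/50 uses the measured baseline height.
    """
    variant = MediatorVariant(variant)
    if variant.is_smoking:
        raise ValueError(f"{variant} is not an overweight variant")
    ref = _reference_age(record, disease)
    h = float(record["baseline_height_m"])
    if h <= 0:
        raise ValueError("baseline height must be positive")

    def bmi(col):
        w = record.get(col)
        return None if _is_missing(w) else float(w) / h**2

    w10 = record.get("weight_at_10")
    b18, b30, b50 = bmi("weight_kg_18"), bmi("weight_kg_30"), bmi("weight_kg_50")
    milestones: list[tuple[float, bool]] = []
    if variant in (MediatorVariant.early_overweight, MediatorVariant.early_overweight_18plus):
        fields = []
        if variant is MediatorVariant.early_overweight:
            fields.append(w10)
            milestones.append((10.0, (not _is_missing(w10)) and str(w10) == "higher"))
        fields.append(b18)
        milestones.append((18.0, b18 is not None and b18 >= 25.0))
        if all(f is None or _is_missing(f) for f in fields):
            return EXCLUDED
    else:  # late_overweight
        expected = [b for b, age_req in ((b30, 30), (b50, 50))
                    if float(record["baseline_age"]) >= age_req]
        if expected and all(b is None for b in expected):
            return EXCLUDED
        milestones.append((30.0, b30 is not None and b30 >= 25.0))
        milestones.append((50.0, b50 is not None and b50 >= 25.0))
    return int(any(met and age < ref for age, met in milestones))


# ----------------------------------------------------------------------
# vectorized assembly
# ----------------------------------------------------------------------

def _score_cts_frame(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    items = df[[f"cts_{i}" for i in range(1, 6)]].to_numpy(dtype=float)
    valid = np.all(np.isfinite(items) & (items >= 1) & (items <= 5), axis=1)
    abuse = (items[:, 0] >= 3) | (items[:, 1] >= 3) | (items[:, 2] >= 2)
    neglect = (items[:, 3] <= 2) | (items[:, 4] <= 2)
    return abuse, neglect, valid


def _classify_cancer_frame(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, int]:
    site = df["cancer_site"].astype(object).to_numpy()
    sex = df["sex"].astype(str).to_numpy()
    cancer = df["diagnosed_cancer"].to_numpy(dtype=float) == 1.0
    known = np.array([(not _is_missing(s)) and str(s) in KNOWN_SITES for s in site])
    in_sm = np.array([(not _is_missing(s)) and str(s) in SMOKING_RELATED_SITES for s in site])
    in_ob = np.array([(not _is_missing(s)) and str(s) in OBESITY_RELATED_SITES for s in site])
    is_breast = np.array([str(s) == "breast" for s in site])
    smoking = cancer & in_sm & ~(is_breast & (sex != "F"))
    obesity = cancer & in_ob
    n_unknown = int(np.sum(cancer & ~known))
    if n_unknown:
        logger.warning("%d cancer cases with unknown/missing site classified (0, 0)", n_unknown)
    return smoking, obesity, n_unknown


def build_analysis_table(
    cohort: pd.DataFrame,
    outcome: str,
    exposure: str,
    variant: MediatorVariant | str = MediatorVariant.ever_smoking,
    outcome_kind: str = "presence",
) -> AnalysisTable:
    """Complete-case (a, m, y, c) rectangle plus its exclusion ledger.

    Exclusion reasons are attributed in a fixed order -- missing CTS,
    missing smoking information, missing weight history, missing disease
    history, missing education, then the diagnosis-age rules and the
    variant-specific current-smoking rule -- one reason per row.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if outcome not in OUTCOMES:
        raise KeyError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    if exposure not in EXPOSURES:
        raise KeyError(f"unknown exposure {exposure!r}")
    if outcome_kind not in ("presence", "age_at_dx"):
        raise ValueError(f"unknown outcome_kind {outcome_kind!r}")
    variant = MediatorVariant(variant)
    base = "cancer" if outcome.startswith("cancer") else outcome

    df = cohort.reset_index(drop=True)
    n = len(df)
    reasons = np.full(n, "", dtype=object)

    def mark(mask: np.ndarray, reason: str) -> None:
        reasons[(reasons == "") & np.asarray(mask, dtype=bool)] = reason

    abuse, neglect, cts_ok = _score_cts_frame(df)
    mark(~cts_ok, "missing_cts")

    ever = df["ever_smoked"].to_numpy(dtype=float)
    init = df["smoking_init_age"].to_numpy(dtype=float)
    smoking_missing = np.isnan(ever) | ((ever == 1.0) & np.isnan(init))
    mark(smoking_missing, "missing_smoking")

    w10 = df["weight_at_10"].astype(object).to_numpy()
    w10_missing = np.array([_is_missing(x) for x in w10])
    w18 = df["weight_kg_18"].to_numpy(dtype=float)
    mark(w10_missing & np.isnan(w18), "missing_weight_history")

    diag = df[f"diagnosed_{base}"].to_numpy(dtype=float)
    mark(np.isnan(diag), "missing_disease_history")

    edu = df["education_years"].to_numpy(dtype=float)
    mark(np.isnan(edu), "missing_education")

    dx = df[f"age_at_dx_{base}"].to_numpy(dtype=float)
    case = diag == 1.0
    mark(case & np.isnan(dx), "missing_diagnosis_age")
    mark(case & (dx < 18.0), "diagnosed_before_18")

    # reference age: diagnosis age for cases, baseline age for everyone else
    baseline_age = df["baseline_age"].to_numpy(dtype=float)
    ref = np.where(case & ~np.isnan(dx), dx, baseline_age)

    if variant.is_smoking:
        smoked_before = (ever == 1.0) & ~np.isnan(init) & (init < ref)
        m = smoked_before.astype(float)
        if variant is MediatorVariant.current_smoking:
            quit = df["smoking_quit_age"].to_numpy(dtype=float)
            mark(smoked_before & ~np.isnan(quit) & (quit < ref), "quit_before_diagnosis")
    else:
        height = df["baseline_height_m"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            b18 = w18 / height**2
            b30 = df["weight_kg_30"].to_numpy(dtype=float) / height**2
            b50 = df["weight_kg_50"].to_numpy(dtype=float) / height**2
        hit10 = np.array([(not _is_missing(x)) and str(x) == "higher" for x in w10]) & (10.0 < ref)
        hit18 = ~np.isnan(b18) & (b18 >= 25.0) & (18.0 < ref)
        hit30 = ~np.isnan(b30) & (b30 >= 25.0) & (30.0 < ref)
        hit50 = ~np.isnan(b50) & (b50 >= 25.0) & (50.0 < ref)
        if variant is MediatorVariant.early_overweight:
            m = (hit10 | hit18).astype(float)
        elif variant is MediatorVariant.early_overweight_18plus:
            m = hit18.astype(float)
        else:
            m = (hit30 | hit50).astype(float)

    # outcome
    if outcome == "cancer_smoking_related":
        y_sm, _, _ = _classify_cancer_frame(df)
        y = y_sm.astype(float)
    elif outcome == "cancer_obesity_related":
        _, y_ob, _ = _classify_cancer_frame(df)
        y = y_ob.astype(float)
    else:
        y = (diag == 1.0).astype(float)

    if outcome_kind == "age_at_dx":
        mark(y != 1.0, "unaffected")
        y = dx

    keep = reasons == ""
    out = pd.DataFrame({
        "a": (abuse if exposure == "abuse" else neglect).astype(float)[keep],
        "m": m[keep],
        "y": y[keep],
        "baseline_age": baseline_age[keep],
        "sex_female": (df["sex"].astype(str).to_numpy() == "F").astype(float)[keep],
        "center": df["center"].astype(str).to_numpy()[keep],
        "education_years": edu[keep],
        "sex": df["sex"].astype(str).to_numpy()[keep],
        "birth_cohort": np.where(df["birth_year"].to_numpy(dtype=float) <= 1970,
                                 "older", "younger")[keep],
    }).reset_index(drop=True)

    counts = {r: int(np.sum(reasons == r)) for r in EXCLUSION_ORDER if np.sum(reasons == r)}
    ledger = ExclusionLedger(n_input=n, n_retained=len(out), counts=counts)
    ledger.check()
    return AnalysisTable(out, ledger, outcome, exposure, variant, outcome_kind)
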