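"""Orchestration of the full mediation study.

For every disease x exposure x mediator-variant x stratum cell the
pipeline builds the time-sequenced analysis table, fits the three path
regressions (A: exposure -> mediator, B: mediator -> outcome, C:
exposure -> outcome), screens them against the substantive-effect
thresholds (RR < 0.9 or RR > 1.1, |beta| > 1 year), and runs the two-way
and four-way mediation decompositions conditioned at the stratum's
covariate means.  Cells that cannot be estimated (too few cases, a
degenerate mediator, non-convergence) are recorded as such rather than
aborting the run; the whole grid is deterministic given the input cohort.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .cohort_derivation import (EXPOSURES, OUTCOMES, AnalysisTable, MediatorVariant,
                                build_analysis_table)
from .glm_core import ConvergenceError, DesignSpec, RankDeficientError, fit_glm, term_rr
from .mediation_engine import (Effect, MediationSpec, fit_mediation_models,
                               four_way_decomposition, mediate_linear_outcome,
                               two_way_decomposition)

STRATA = ("whole", "men", "women", "older", "younger")

PRIMARY_VARIANTS = (MediatorVariant.ever_smoking, MediatorVariant.early_overweight)
SENSITIVITY_VARIANTS = (MediatorVariant.current_smoking, MediatorVariant.early_overweight_18plus)


class Thresholds(BaseModel):
    rr_low: float = 0.9
    rr_high: float = 1.1
    beta_abs: float = 1.0


class StudyConfig(BaseModel):
    outcomes: tuple[str, ...] = OUTCOMES
    exposures: tuple[str, ...] = EXPOSURES
    mediator_variants: tuple[str, ...] = tuple(v.value for v in PRIMARY_VARIANTS)
    include_sensitivity: bool = False
    strata: tuple[str, ...] = STRATA
    covariates: tuple[str, ...] = ("baseline_age", "sex_female", "center", "education_years")
    thresholds: Thresholds = Field(default_factory=Thresholds)
    ci_level: float = 0.95
    min_cases: int = 10
    inference: str = "delta"
    age_at_dx_mediation: bool = False  # the age-at-diagnosis outcome is screened only
    seed: int = 0

    def variants(self) -> list[MediatorVariant]:
        out = [MediatorVariant(v) for v in self.mediator_variants]
        if self.include_sensitivity:
            out += [v for v in SENSITIVITY_VARIANTS if v not in out]
        return out


class NotEstimable(RuntimeError):
    pass


@dataclass
class PathEstimates:
    """Path A/B/C effects with CIs; RRs for presence outcomes, linear
    betas (paths B/C) for age-at-diagnosis outcomes."""

    path_a: Effect | None
    path_b: Effect | None
    path_c: Effect | None
    outcome_kind: str
    n: int
    n_cases: int
    notes: list[str]


def _rr_effect(fit, term: str, level: float) -> Effect:
    rr, lo, hi = term_rr(fit, term, level)
    i = fit.index(term)
    return Effect(rr, lo, hi, float(np.sqrt(fit.cov_robust[i, i])))


def _beta_effect(fit, term: str, level: float) -> Effect:
    from scipy.stats import norm
    b = fit.coef(term)
    se = fit.se(term, robust=False)  # classical SEs reported for linear fits
    z = norm.ppf(0.5 + level / 2.0)
    return Effect(b, b - z * se, b + z * se, se)


def run_path_models(table: AnalysisTable, covariates: Sequence[str] = (),
                    level: float = 0.95, min_cases: int = 10) -> PathEstimates:
    """Fit the three path regressions for one analysis table."""
    df = table.df
    n = len(df)
    notes: list[str] = []
    kind = table.outcome_kind
    n_cases = int(df["y"].sum()) if kind == "presence" else n
    a_var = df["a"].nunique() > 1
    m_var = df["m"].nunique() > 1

    path_a = path_b = path_c = None
    if n == 0:
        return PathEstimates(None, None, None, kind, 0, 0, ["empty table"])
    try:
        if a_var and m_var and 0 < df["m"].sum() < n:
            fa = fit_glm(df, DesignSpec("m", ("a", *covariates), "log_poisson"))
            path_a = _rr_effect(fa, "a", level)
        else:
            notes.append("path A not estimable: degenerate exposure or mediator")
    except (ConvergenceError, RankDeficientError, ValueError) as exc:
        notes.append(f"path A failed: {exc}")

    if kind == "presence":
        if n_cases < min_cases or n_cases == n:
            notes.append(f"paths B/C not estimable: {n_cases} cases")
            return PathEstimates(path_a, None, None, kind, n, n_cases, notes)
        fam, eff = "log_poisson", _rr_effect
    else:
        fam, eff = "linear", _beta_effect
    try:
        if m_var:
            fb = fit_glm(df, DesignSpec("y", ("m", *covariates), fam))
            path_b = eff(fb, "m", level)
        else:
            notes.append("path B not estimable: constant mediator")
    except (ConvergenceError, RankDeficientError, ValueError) as exc:
        notes.append(f"path B failed: {exc}")
    try:
        if a_var:
            fc = fit_glm(df, DesignSpec("y", ("a", *covariates), fam))
            path_c = eff(fc, "a", level)
        else:
            notes.append("path C not estimable: constant exposure")
    except (ConvergenceError, RankDeficientError, ValueError) as exc:
        notes.append(f"path C failed: {exc}")
    return PathEstimates(path_a, path_b, path_c, kind, n, n_cases, notes)


def screen_substantive(paths: PathEstimates, thresholds: Thresholds | None = None) -> dict:
    """Substantive-effect flags per path and the all-paths interpretation gate.

    A risk ratio is substantive iff RR < rr_low or RR > rr_high (strict);
    a linear coefficient iff |beta| > beta_abs.
    """
    t = thresholds or Thresholds()

    def flag(effect: Effect | None, is_rr: bool) -> bool | None:
        if effect is None:
            return None
        if is_rr:
            return bool(effect.estimate < t.rr_low or effect.estimate > t.rr_high)
        return bool(abs(effect.estimate) > t.beta_abs)

    rr_kind = paths.outcome_kind == "presence"
    flags = {
        "a": flag(paths.path_a, True),
        "b": flag(paths.path_b, rr_kind),
        "c": flag(paths.path_c, rr_kind),
    }
    flags["gate"] = bool(flags["a"] and flags["b"] and flags["c"])
    return flags


def _stratum_frame(cohort: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if stratum == "whole":
        return cohort
    if stratum == "men":
        return cohort[cohort["sex"].astype(str) == "M"]
    if stratum == "women":
        return cohort[cohort["sex"].astype(str) == "F"]
    if stratum == "older":
        return cohort[cohort["birth_year"].astype(float) <= 1970]
    if stratum == "younger":
        return cohort[cohort["birth_year"].astype(float) > 1970]
    raise KeyError(f"unknown stratum {stratum!r}")


def _covariates_for(stratum: str, covariates: Sequence[str]) -> tuple[str, ...]:
    # sex is dropped inside sex strata; birth-cohort strata keep baseline age
    if stratum in ("men", "women"):
        return tuple(c for c in covariates if c != "sex_female")
    return tuple(covariates)


def covariate_means(df: pd.DataFrame, covariates: Sequence[str]) -> tuple[float, ...]:
    """Means of the expanded covariate design columns (the conditioning c)."""
    from .glm_core import build_design
    if not covariates:
        return ()
    X, names = build_design(df, tuple(covariates))
    return tuple(float(v) for v in X[:, 1:].mean(axis=0))


def _cell_result(table: AnalysisTable, covariates: tuple[str, ...],
                 config: StudyConfig) -> dict:
    row: dict = {}
    paths = run_path_models(table, covariates, config.ci_level, config.min_cases)
    flags = screen_substantive(paths, config.thresholds)
    for name, eff in (("path_a", paths.path_a), ("path_b", paths.path_b),
                      ("path_c", paths.path_c)):
        if eff is None:
            row.update({f"{name}_est": np.nan, f"{name}_lo": np.nan, f"{name}_hi": np.nan})
        else:
            row.update({f"{name}_est": eff.estimate, f"{name}_lo": eff.lower,
                        f"{name}_hi": eff.upper})
    row.update({"substantive_a": flags["a"], "substantive_b": flags["b"],
                "substantive_c": flags["c"], "gate": flags["gate"],
                "n": paths.n, "n_cases": paths.n_cases})

    if paths.n_cases < config.min_cases or paths.n_cases == paths.n:
        row["status"] = f"not_estimable: {paths.n_cases} cases of {paths.n}"
        return row
    if table.df["a"].nunique() < 2 or table.df["m"].nunique() < 2:
        row["status"] = "not_estimable: degenerate exposure or mediator"
        return row
    try:
        pair = fit_mediation_models(table.df, "y", "a", "m", covariates)
        c = covariate_means(table.df, covariates)
        spec = MediationSpec(c=c, level=config.ci_level, inference=config.inference,
                             boot_seed=config.seed)
        two = two_way_decomposition(pair, spec)
        four = four_way_decomposition(pair, spec)
    except (ConvergenceError, RankDeficientError, ValueError, RuntimeError) as exc:
        row["status"] = f"error: {exc}"
        return row
    for name, eff in (("rr_te", two.rr_te), ("rr_pde", two.rr_pde), ("rr_tie", two.rr_tie)):
        row.update({f"{name}_est": eff.estimate, f"{name}_lo": eff.lower,
                    f"{name}_hi": eff.upper})
    row.update({"pm_pct": two.pm.estimate * 100.0, "pm_lo_pct": two.pm.lower * 100.0,
                "pm_hi_pct": two.pm.upper * 100.0, "pm_defined": two.pm_defined})
    for name, eff in (("err_cde", four.err_cde), ("err_intref", four.err_intref),
                      ("err_pie", four.err_pie), ("err_intmed", four.err_intmed)):
        row.update({f"{name}_est": eff.estimate, f"{name}_lo": eff.lower,
                    f"{name}_hi": eff.upper})
    row["status"] = "ok"
    return row


def run_full_study(cohort: pd.DataFrame, config: StudyConfig | None = None) -> pd.DataFrame:
    """One row per outcome x exposure x mediator variant x stratum.

    Smoking variants are paired with every outcome; overweight variants
    likewise, so each outcome appears under both mediator families.
    Per-cell failures are recorded in the row's ``status``.
    """
    config = config or StudyConfig()
    rows: list[dict] = []
    for outcome in config.outcomes:
        for exposure in config.exposures:
            for variant in config.variants():
                for stratum in config.strata:
                    meta = {"outcome": outcome, "exposure": exposure,
                            "mediator": variant.value, "stratum": stratum}
                    sub = _stratum_frame(cohort, stratum)
                    covs = _covariates_for(stratum, config.covariates)
                    try:
                        table = build_analysis_table(sub, outcome, exposure, variant)
                        row = _cell_result(table, covs, config)
                        row["n_excluded"] = sum(table.ledger.counts.values())
                    except Exception as exc:  # defensive: a cell never kills the run
                        row = {"status": f"error: {exc}", "n": len(sub)}
                    rows.append({**meta, **row})
    df = pd.DataFrame(rows)
    # gate correctness is a structural invariant of every run
    is_true = lambda col: df[col].map(lambda v: v is True)
    bad = df[(df.get("gate") == True)  # noqa: E712
             & ~(is_true("substantive_a") & is_true("substantive_b")
                 & is_true("substantive_c"))]
    if len(bad):
        raise AssertionError("interpretation gate set without all three path flags")
    return df


def _fmt(x, pattern="{:.2f}"):
    return "" if x is None or (isinstance(x, float) and np.isnan(x)) else pattern.format(x)


def export_report(results: pd.DataFrame, destination, config: StudyConfig | None = None,
                  seed: int | None = None) -> dict[str, Path]:
    """Write the results CSV (deterministic bytes) and a JSON run manifest.

    Adds display columns in the journal-table style: risk ratios to two
    decimals, proportion mediated as a percentage with its CI.
    """
    if results is None or len(results) == 0:
        raise ValueError("cannot export an empty results table")
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    df = results.copy()
    for name, label in (("path_c", "total_effect"), ("rr_pde", "pde"), ("rr_tie", "tie")):
        if f"{name}_est" in df:
            df[f"{label}_display"] = [
                f"{_fmt(e)} [{_fmt(l)}; {_fmt(h)}]" if _fmt(e) else ""
                for e, l, h in zip(df[f"{name}_est"], df[f"{name}_lo"], df[f"{name}_hi"])]
    if "pm_pct" in df:
        df["pm_display"] = [
            f"{_fmt(e)}% [{_fmt(l)}; {_fmt(h)}]" if _fmt(e) else ""
            for e, l, h in zip(df["pm_pct"], df["pm_lo_pct"], df["pm_hi_pct"])]
    csv_path = dest / "report.csv"
    df.to_csv(csv_path, index=False, float_format="%.10g")
    manifest = {
        "package": "seqmediate",
        "version": __version__,
        "seed": seed,
        "config": json.loads(config.model_dump_json()) if config is not None else None,
        "n_rows": int(len(df)),
        "n_ok": int((df["status"] == "ok").sum()),
        "python": platform.python_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    manifest_path = dest / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {"report": csv_path, "manifest": manifest_path}
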