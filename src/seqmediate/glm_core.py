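"""Regression engine for the path and mediation models.

Three families are supported, all fitted by iteratively reweighted least
squares (IRLS):

``log_poisson``
    Log-link GLM with a Poisson working variance ("modified Poisson
    regression").  On a binary outcome the exponentiated coefficients are
    risk ratios, and the HC0 sandwich covariance gives valid standard
    errors even though the Poisson variance is misspecified for 0/1 data.
``logistic``
    Ordinary logistic regression (used for binary mediators).
``linear``
    Ordinary least squares (used for age-at-diagnosis outcomes), with both
    the classical and the HC0 covariance.

Categorical columns (``object``/``category``/string dtypes) are expanded
into reference-coded indicators; the first level in sorted order is the
reference.  Interaction terms are written ``"a:m"`` and must multiply
numeric (or already-binary) columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

FAMILIES = ("log_poisson", "logistic", "linear")

_SCORE_TOL = 1e-8
_MAX_ITER = 100


class RankDeficientError(ValueError):
    """The design matrix is not of full column rank."""


class ConvergenceError(RuntimeError):
    """IRLS failed to reach the score tolerance (e.g. separation)."""

    def __init__(self, message: str, trace: Sequence[float] = ()):
        super().__init__(message)
        self.trace = list(trace)


@dataclass(frozen=True)
class DesignSpec:
    """Response + term list + family for one regression.

    ``terms`` never includes the intercept; it is always prepended.
    """

    response: str
    terms: tuple[str, ...]
    family: str

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")


def build_design(df: pd.DataFrame, terms: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Expand a term list into a dense design matrix with an intercept.

    Returns ``(X, column_names)``.  Raises on missing values: the caller is
    expected to pass a complete-case table.
    """
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["Intercept"]

    def numeric(col: str) -> np.ndarray:
        s = df[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == "string":
            raise ValueError(f"term {col!r} inside an interaction must be numeric")
        v = s.to_numpy(dtype=float)
        if np.isnan(v).any():
            raise ValueError(f"column {col!r} contains missing values")
        return v

    for term in terms:
        if ":" in term:
            parts = term.split(":")
            v = np.ones(n)
            for p in parts:
                v = v * numeric(p)
            cols.append(v)
            names.append(term)
            continue
        s = df[term]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == "string":
            if s.isna().any():
                raise ValueError(f"column {term!r} contains missing values")
            levels = sorted(map(str, pd.unique(s.astype(str))))
            for lev in levels[1:]:  # first (sorted) level is the reference
                cols.append((s.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{term}[{lev}]")
        else:
            cols.append(numeric(term))
            names.append(term)
    return np.column_stack(cols), names


@dataclass
class GLMFit:
    """A fitted regression with model-based and sandwich covariances."""

    params: np.ndarray
    names: list[str]
    cov_model: np.ndarray
    cov_robust: np.ndarray
    family: str
    n: int
    iterations: int
    converged: bool
    max_fitted: float
    response: str = ""
    terms: tuple[str, ...] = ()

    def index(self, term: str) -> int:
        try:
            return self.names.index(term)
        except ValueError as exc:
            raise KeyError(f"term {term!r} not in fit ({self.names})") from exc

    def coef(self, term: str) -> float:
        return float(self.params[self.index(term)])

    def se(self, term: str, robust: bool = True) -> float:
        i = self.index(term)
        cov = self.cov_robust if robust else self.cov_model
        return float(np.sqrt(cov[i, i]))

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "n": self.n,
            "iterations": self.iterations,
            "converged": self.converged,
            "terms": list(self.names),
            "coef": self.params.tolist(),
            "se_model": np.sqrt(np.diag(self.cov_model)).tolist(),
            "se_robust": np.sqrt(np.diag(self.cov_robust)).tolist(),
            "cov_robust": self.cov_robust.tolist(),
            "max_fitted": self.max_fitted,
        }

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "se_model": np.sqrt(np.diag(self.cov_model)),
                "se_robust": np.sqrt(np.diag(self.cov_robust)),
            },
            index=self.names,
        )


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    # QR with column pivoting is overkill here; diagonal of plain R exposes
    # the near-dependent columns well enough to name them.
    r = np.linalg.qr(X, mode="r")
    d = np.abs(np.diag(r))
    scale = d.max() if d.size else 0.0
    bad = [names[i] for i in range(len(d)) if d[i] < 1e-10 * max(scale, 1.0)]
    if bad:
        raise RankDeficientError(f"design matrix is rank deficient; collinear terms: {bad}")


def _neg_loglik(family: str, y: np.ndarray, eta: np.ndarray) -> float:
    if family == "log_poisson":
        return float(np.sum(np.exp(eta)) - y @ eta)
    # logistic
    return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)


def fit_glm(
    data: pd.DataFrame,
    spec: DesignSpec,
    *,
    hc1: bool = False,
    tol: float = _SCORE_TOL,
    max_iter: int = _MAX_ITER,
) -> GLMFit:
    """Fit one regression by IRLS (or OLS for the linear family).

    ``hc1`` applies the n/(n-p) small-sample factor to the sandwich; the
    default is plain HC0.
    """
    df = getattr(data, "df", data)  # accept AnalysisTable or DataFrame
    X, names = build_design(df, spec.terms)
    y = df[spec.response].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError(f"response {spec.response!r} contains missing values")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n={n} rows cannot identify {p} parameters")
    _check_rank(X, names)

    if spec.family == "linear":
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        xtx_inv = np.linalg.inv(X.T @ X)
        sigma2 = float(resid @ resid) / (n - p)
        cov_model = sigma2 * xtx_inv
        meat = (X.T * resid**2) @ X
        cov_robust = xtx_inv @ meat @ xtx_inv
        if hc1:
            cov_robust *= n / (n - p)
        return GLMFit(beta, names, cov_model, cov_robust, "linear", n, 0, True,
                      float(np.max(X @ beta)), spec.response, tuple(spec.terms))

    binary = bool(np.isin(y, (0.0, 1.0)).all())
    mean_y = float(np.mean(y))
    beta = np.zeros(p)
    if spec.family == "log_poisson":
        if mean_y <= 0:
            raise ValueError("log-link fit requires a response with positive mean")
        beta[0] = np.log(mean_y)
        inv_link = np.exp
        var_fn = lambda mu: mu
    else:  # logistic
        if binary and (mean_y <= 0 or mean_y >= 1):
            raise ValueError("logistic fit requires both outcome levels present")
        m0 = min(max(mean_y, 1e-6), 1 - 1e-6)
        beta[0] = np.log(m0 / (1 - m0))
        inv_link = lambda eta: 1.0 / (1.0 + np.exp(-eta))
        var_fn = lambda mu: mu * (1.0 - mu)

    eta = X @ beta
    nll = _neg_loglik(spec.family, y, eta)
    trace: list[float] = []
    converged = False
    it = 0
    # the score is a sum over rows, so its numerical floor grows with n;
    # the induced coefficient error stays ~ tol_n / O(n), far below tol
    tol_n = tol * max(1.0, n / 1000.0)
    for it in range(1, max_iter + 1):
        mu = inv_link(eta)
        score = X.T @ (y - mu)
        trace.append(float(np.max(np.abs(score))))
        if trace[-1] < tol_n:
            converged = True
            break
        w = np.maximum(var_fn(mu), 1e-12)
        z = eta + (y - mu) / w
        xtw = X.T * w
        try:
            step = np.linalg.solve(xtw @ X, xtw @ z) - beta
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"weighted normal equations singular at iteration {it}", trace) from exc
        # step-halving on working-likelihood increase; the tolerance scales
        # with |nll| because its float resolution does too
        lam = 1.0
        nll_floor = 1e-10 * max(1.0, abs(nll))
        for _ in range(30):
            cand = beta + lam * step
            eta_c = X @ cand
            nll_c = _neg_loglik(spec.family, y, eta_c)
            if nll_c <= nll + nll_floor:
                beta, eta, nll = cand, eta_c, nll_c
                break
            lam /= 2.0
        else:
            # no improving step: at the numerical floor of the likelihood this
            # is the optimum; otherwise report non-convergence
            if trace[-1] < 1e-6 * max(1.0, abs(nll)):
                converged = True
                break
            raise ConvergenceError(
                f"step-halving stalled at iteration {it}; max|score| trace: {trace[-5:]}", trace)
    if not converged:
        mu = inv_link(eta)
        score = X.T @ (y - mu)
        if float(np.max(np.abs(score))) < tol_n:
            converged = True
        else:
            raise ConvergenceError(
                f"IRLS did not converge in {max_iter} iterations "
                f"(possible separation); max|score| trace tail: {trace[-5:]}", trace)

    if spec.family == "logistic" and float(np.max(np.abs(eta))) > 15.0:
        # saturated fitted probabilities: the score vanishes numerically even
        # though the MLE diverges
        raise ConvergenceError(
            "logistic fit appears separated (|linear predictor| > 15); "
            "coefficients diverge", trace)
    mu = inv_link(eta)
    w = np.maximum(var_fn(mu), 1e-12)
    xtwx = (X.T * w) @ X
    bread = np.linalg.inv(xtwx)
    resid = y - mu
    meat = (X.T * resid**2) @ X
    cov_robust = bread @ meat @ bread
    if hc1:
        cov_robust *= n / (n - p)
    cov_model = bread  # dispersion fixed at 1 for both working families
    max_fitted = float(np.max(mu))
    if spec.family == "log_poisson" and binary and max_fitted > 1.0:
        warnings.warn(
            f"log-link fit produced {int(np.sum(mu > 1.0))} fitted risks > 1 "
            f"(max {max_fitted:.3f})", RuntimeWarning, stacklevel=2)
    return GLMFit(beta, names, cov_model, cov_robust, spec.family, n, it, True,
                  max_fitted, spec.response, tuple(spec.terms))


def term_rr(fit: GLMFit, term: str, level: float = 0.95) -> tuple[float, float, float]:
    """Risk ratio and Wald CI for one coefficient of a log-link fit."""
    if fit.family != "log_poisson":
        raise ValueError(f"risk ratios are defined for log_poisson fits, not {fit.family!r}")
    i = fit.index(term)
    b = float(fit.params[i])
    se = float(np.sqrt(fit.cov_robust[i, i]))
    z = norm.ppf(0.5 + level / 2.0)
    return float(np.exp(b)), float(np.exp(b - z * se)), float(np.exp(b + z * se))


def fit_diagnostics(fit: GLMFit, data: pd.DataFrame) -> dict:
    """Fit-quality report: score norm, design conditioning, leverage."""
    df = getattr(data, "df", data)
    X, _ = build_design(df, fit.terms)
    y = df[fit.response].to_numpy(dtype=float)
    if fit.family == "linear":
        mu = X @ fit.params
        w = np.ones(len(y))
    elif fit.family == "log_poisson":
        mu = np.exp(X @ fit.params)
        w = np.maximum(mu, 1e-12)
    else:
        mu = 1.0 / (1.0 + np.exp(-(X @ fit.params)))
        w = np.maximum(mu * (1 - mu), 1e-12)
    score = X.T @ (y - mu)
    xw = X * np.sqrt(w)[:, None]
    sv = np.linalg.svd(xw, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else float("inf")
    bread = np.linalg.inv((X.T * w) @ X)
    lev = np.einsum("ij,jk,ik->i", xw, bread, xw)
    return {
        "max_abs_score": float(np.max(np.abs(score))),
        "condition_number": cond,
        "ill_conditioned": cond > 1e8,
        "leverage_min": float(lev.min()),
        "leverage_mean": float(lev.mean()),
        "leverage_max": float(lev.max()),
        "n": fit.n,
        "converged": fit.converged,
    }
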