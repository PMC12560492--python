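"""RR-scale causal mediation with exposure-mediator interaction.

Given a log-link (modified Poisson) outcome model

    log E[Y | A=a, M=m, C=c] = th0 + th1*a + th2*m + th3*a*m + thC'c

and a logistic mediator model

    logit P(M=1 | A=a, C=c) = b0 + b1*a + bC'c,

the counterfactual mean at covariate value c is obtained by exact
integration over the binary mediator (no rare-outcome approximation):

    Q(a, a') = exp(th0 + th1*a + thC'c) * [(1 - p(a')) + p(a') * exp(th2 + th3*a)]

with p(x) = expit(b0 + b1*x + bC'c).  The two-way decomposition reports

    RR_PDE = Q(1,0)/Q(0,0),  RR_TIE = Q(1,1)/Q(1,0),  RR_TE = Q(1,1)/Q(0,0),
    PM = RR_PDE * (RR_TIE - 1) / (RR_TE - 1),

and the four-way decomposition splits the excess relative risk
RR_TE - 1 additively into a controlled direct effect, a reference
interaction, a pure indirect effect and a mediated interaction, with
ERR_CDE + ERR_INTref = RR_PDE - 1 (the direct block) and
ERR_PIE + ERR_INTmed = RR_PDE * (RR_TIE - 1) (the indirect block).

Interval estimation is by the multivariate delta method with central
finite-difference gradients over the stacked coefficient vector (outcome
sandwich covariance, mediator model-based covariance, block-diagonal), or
by a row-resampling bootstrap that refits both models and therefore also
captures the cross-model covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .glm_core import DesignSpec, GLMFit, fit_glm

ESTIMANDS = (
    "rr_te", "rr_pde", "rr_tie", "pm",
    "err_cde", "err_intref", "err_pie", "err_intmed",
)


class Effect(NamedTuple):
    estimate: float
    lower: float
    upper: float
    se: float


@dataclass(frozen=True)
class MediationSpec:
    """Exposure contrast, conditioning covariates and inference choices."""

    a: float = 1.0
    a_star: float = 0.0
    m_star: float = 0.0
    c: tuple[float, ...] = ()
    level: float = 0.95
    inference: str = "delta"  # "delta" | "bootstrap"
    n_boot: int = 500
    boot_seed: int = 0

    def __post_init__(self):
        if self.a == self.a_star:
            raise ValueError("exposure levels a and a* must differ")
        if self.inference not in ("delta", "bootstrap"):
            raise ValueError(f"unknown inference {self.inference!r}")


@dataclass
class MediationModelPair:
    """An outcome fit and a mediator fit sharing the same covariate terms.

    The outcome fit must contain terms ``Intercept, exposure, mediator,
    exposure:mediator`` plus covariate columns; the mediator fit contains
    ``Intercept, exposure`` plus the same covariate columns in the same
    order.  ``data``/design specs are optional and only needed for
    bootstrap inference.
    """

    outcome: GLMFit
    mediator: GLMFit
    exposure: str
    mediator_name: str
    data: pd.DataFrame | None = None
    outcome_spec: DesignSpec | None = None
    mediator_spec: DesignSpec | None = None
    covariate_names: list[str] = field(init=False)

    def __post_init__(self):
        if not (self.outcome.converged and self.mediator.converged):
            raise ValueError("both fits must have converged")
        inter = f"{self.exposure}:{self.mediator_name}"
        inter_alt = f"{self.mediator_name}:{self.exposure}"
        names = self.outcome.names
        self._inter = inter if inter in names else inter_alt
        core_out = ("Intercept", self.exposure, self.mediator_name, self._inter)
        cov_out = [t for t in names if t not in core_out]
        cov_med = [t for t in self.mediator.names if t not in ("Intercept", self.exposure)]
        if cov_out != cov_med:
            raise ValueError(
                f"covariate terms differ between outcome {cov_out} and mediator {cov_med}")
        self.covariate_names = cov_out

    # --- packed coefficient vectors in canonical order -----------------
    def _perm(self, fit: GLMFit, order: Sequence[str]) -> np.ndarray:
        return np.array([fit.index(t) for t in order], dtype=int)

    def theta(self) -> np.ndarray:
        order = ["Intercept", self.exposure, self.mediator_name, self._inter] + self.covariate_names
        return self.outcome.params[self._perm(self.outcome, order)]

    def beta(self) -> np.ndarray:
        order = ["Intercept", self.exposure] + self.covariate_names
        return self.mediator.params[self._perm(self.mediator, order)]

    def joint_cov(self) -> np.ndarray:
        """Block-diagonal covariance of (theta, beta).

        Sandwich block for the outcome fit (modified Poisson), model-based
        block for the logistic/linear mediator-outcome pair, matching
        separate-fit estimation.
        """
        po = self._perm(self.outcome, ["Intercept", self.exposure, self.mediator_name,
                                       self._inter] + self.covariate_names)
        pm_ = self._perm(self.mediator, ["Intercept", self.exposure] + self.covariate_names)
        co = self.outcome.cov_robust[np.ix_(po, po)]
        cm = self.mediator.cov_model[np.ix_(pm_, pm_)]
        k = co.shape[0] + cm.shape[0]
        out = np.zeros((k, k))
        out[: co.shape[0], : co.shape[0]] = co
        out[co.shape[0]:, co.shape[0]:] = cm
        return out

    def resolve_c(self, spec: MediationSpec) -> np.ndarray:
        c = np.asarray(spec.c, dtype=float)
        if c.size == 0 and self.covariate_names:
            raise ValueError(
                f"spec.c must supply {len(self.covariate_names)} covariate values "
                f"for {self.covariate_names}")
        if c.size != len(self.covariate_names):
            raise ValueError(
                f"spec.c has length {c.size}, expected {len(self.covariate_names)}")
        return c


def fit_mediation_models(
    df: pd.DataFrame,
    outcome: str,
    exposure: str,
    mediator: str,
    covariates: Sequence[str] = (),
    outcome_family: str = "log_poisson",
) -> MediationModelPair:
    """Fit the outcome and mediator regressions used by the decompositions."""
    o_spec = DesignSpec(outcome, (exposure, mediator, f"{exposure}:{mediator}", *covariates),
                        outcome_family)
    m_spec = DesignSpec(mediator, (exposure, *covariates), "logistic")
    return MediationModelPair(
        fit_glm(df, o_spec), fit_glm(df, m_spec), exposure, mediator,
        data=df, outcome_spec=o_spec, mediator_spec=m_spec)


# ----------------------------------------------------------------------
# closed forms on packed coefficient vectors
# ----------------------------------------------------------------------

def _p_med(beta: np.ndarray, x: float, c: np.ndarray) -> float:
    return float(expit(beta[0] + beta[1] * x + (beta[2:] @ c if c.size else 0.0)))


def _risk(theta: np.ndarray, a: float, m: float, c: np.ndarray) -> float:
    lp = theta[0] + theta[1] * a + theta[2] * m + theta[3] * a * m
    if c.size:
        lp += theta[4:] @ c
    return float(np.exp(lp))


def _q(theta: np.ndarray, beta: np.ndarray, a: float, a_prime: float, c: np.ndarray) -> float:
    p = _p_med(beta, a_prime, c)
    base = theta[0] + theta[1] * a + (theta[4:] @ c if c.size else 0.0)
    return float(np.exp(base) * ((1.0 - p) + p * np.exp(theta[2] + theta[3] * a)))


def _estimands(theta: np.ndarray, beta: np.ndarray, c: np.ndarray,
               a: float = 1.0, a_star: float = 0.0) -> dict[str, float]:
    """All point estimands for the exposure contrast a vs a_star at c."""
    q11 = _q(theta, beta, a, a, c)
    q10 = _q(theta, beta, a, a_star, c)
    q00 = _q(theta, beta, a_star, a_star, c)
    rr_te = q11 / q00
    rr_pde = q10 / q00
    rr_tie = q11 / q10
    pm = rr_pde * (rr_tie - 1.0) / (rr_te - 1.0) if rr_te != 1.0 else np.nan
    p1 = _p_med(beta, a, c)
    p0 = _p_med(beta, a_star, c)
    r = lambda aa, mm: _risk(theta, aa, mm, c)
    d = q00
    err_cde = (r(a, 0.0) - r(a_star, 0.0)) / d
    err_intref = (q10 - q00) / d - err_cde
    err_pie = (r(a_star, 1.0) - r(a_star, 0.0)) * (p1 - p0) / d
    err_intmed = (q11 - q10) / d - err_pie
    return {
        "rr_te": rr_te, "rr_pde": rr_pde, "rr_tie": rr_tie, "pm": pm,
        "err_cde": err_cde, "err_intref": err_intref,
        "err_pie": err_pie, "err_intmed": err_intmed,
    }


def counterfactual_mean(models: MediationModelPair, a: float, a_prime: float,
                        spec: MediationSpec) -> float:
    """Q(a, a'; c): mean of Y(a, M(a')) under the fitted models."""
    if models.outcome.family != "log_poisson":
        raise ValueError("counterfactual risks require a log-link outcome fit")
    return _q(models.theta(), models.beta(), a, a_prime, models.resolve_c(spec))


# ----------------------------------------------------------------------
# delta-method machinery
# ----------------------------------------------------------------------

def _fd_grad(f: Callable[[np.ndarray], float], x0: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    g = np.empty_like(x0)
    for i in range(x0.size):
        h = rel_step * max(1.0, abs(x0[i]))
        xp = x0.copy(); xp[i] += h
        xm = x0.copy(); xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2.0 * h)
    return g


def _check_psd(sigma: np.ndarray) -> None:
    if not np.all(np.isfinite(sigma)):
        raise ValueError("joint covariance contains non-finite entries")
    eig = np.linalg.eigvalsh((sigma + sigma.T) / 2.0)
    if eig.min() < -1e-8 * max(1.0, abs(eig.max())):
        raise ValueError("joint covariance is not positive semidefinite")


def delta_ci(effect: Callable[[np.ndarray], float], models: MediationModelPair,
             level: float = 0.95, scale: str = "identity") -> Effect:
    """Delta-method CI for an effect written as a function of (theta, beta).

    ``scale="log"`` builds the normal interval on the log of the effect
    (appropriate for risk ratios); ``"identity"`` builds it directly
    (proportions mediated and excess-RR components, whose intervals may
    legitimately cross 0 or exceed 100%).
    """
    x0 = np.concatenate([models.theta(), models.beta()])
    sigma = models.joint_cov()
    _check_psd(sigma)
    est = float(effect(x0))
    z = norm.ppf(0.5 + level / 2.0)
    if scale == "log":
        f = lambda v: float(np.log(effect(v)))
        g = _fd_grad(f, x0)
        se_log = float(np.sqrt(max(g @ sigma @ g, 0.0)))
        return Effect(est, est * np.exp(-z * se_log), est * np.exp(z * se_log), se_log)
    g = _fd_grad(lambda v: float(effect(v)), x0)
    se = float(np.sqrt(max(g @ sigma @ g, 0.0)))
    return Effect(est, est - z * se, est + z * se, se)


# ----------------------------------------------------------------------
# decompositions
# ----------------------------------------------------------------------

@dataclass
class TwoWayResult:
    rr_te: Effect
    rr_pde: Effect
    rr_tie: Effect
    pm: Effect
    pm_defined: bool
    c: tuple[float, ...]
    inference: str

    def to_dict(self) -> dict:
        d = {}
        for k in ("rr_te", "rr_pde", "rr_tie", "pm"):
            e = getattr(self, k)
            d[k] = {"estimate": e.estimate, "lower": e.lower, "upper": e.upper, "se": e.se}
        d["pm_defined"] = self.pm_defined
        return d


@dataclass
class FourWayResult:
    err_cde: Effect
    err_intref: Effect
    err_pie: Effect
    err_intmed: Effect
    prop_cde: Effect
    prop_intref: Effect
    prop_pie: Effect
    prop_intmed: Effect
    rr_te: float
    c: tuple[float, ...]
    inference: str

    def to_dict(self) -> dict:
        d = {}
        for k in ("err_cde", "err_intref", "err_pie", "err_intmed",
                  "prop_cde", "prop_intref", "prop_pie", "prop_intmed"):
            e = getattr(self, k)
            d[k] = {"estimate": e.estimate, "lower": e.lower, "upper": e.upper, "se": e.se}
        d["rr_te"] = self.rr_te
        return d


def _split(models: MediationModelPair, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    k = models.theta().size
    return v[:k], v[k:]


def _effect_fn(models: MediationModelPair, name: str, c: np.ndarray,
               a: float, a_star: float) -> Callable[[np.ndarray], float]:
    def f(v: np.ndarray) -> float:
        th, be = _split(models, v)
        return _estimands(th, be, c, a, a_star)[name]
    return f


def _bootstrap(models: MediationModelPair, spec: MediationSpec,
               names: Sequence[str]) -> dict[str, Effect]:
    if models.data is None or models.outcome_spec is None:
        raise ValueError("bootstrap inference needs the model pair built by fit_mediation_models")
    rng = np.random.default_rng(spec.boot_seed)
    c = models.resolve_c(spec)
    n = len(models.data)
    draws = {k: [] for k in names}
    done = 0
    attempts = 0
    while done < spec.n_boot and attempts < 4 * spec.n_boot:
        attempts += 1
        idx = rng.integers(0, n, n)
        sample = models.data.iloc[idx]
        try:
            of = fit_glm(sample, models.outcome_spec)
            mf = fit_glm(sample, models.mediator_spec)
            pair = MediationModelPair(of, mf, models.exposure, models.mediator_name)
            est = _estimands(pair.theta(), pair.beta(), c, spec.a, spec.a_star)
        except Exception:
            continue  # degenerate resample (e.g. empty cell); redraw
        for k in names:
            draws[k].append(est[k])
        done += 1
    if done < max(10, spec.n_boot // 2):
        raise RuntimeError(f"bootstrap failed: only {done}/{spec.n_boot} successful resamples")
    alpha = 1.0 - spec.level
    th, be = models.theta(), models.beta()
    point = _estimands(th, be, c, spec.a, spec.a_star)
    out = {}
    for k in names:
        arr = np.array(draws[k])
        lo, hi = np.quantile(arr, [alpha / 2.0, 1.0 - alpha / 2.0])
        out[k] = Effect(point[k], float(lo), float(hi), float(arr.std(ddof=1)))
    return out


def two_way_decomposition(models: MediationModelPair, spec: MediationSpec) -> TwoWayResult:
    """PDE/TIE/TE risk ratios and the proportion mediated, with CIs."""
    if models.outcome.family != "log_poisson":
        raise ValueError("two_way_decomposition requires a log-link outcome model "
                         "(use mediate_linear_outcome for linear outcomes)")
    c = models.resolve_c(spec)
    point = _estimands(models.theta(), models.beta(), c, spec.a, spec.a_star)
    pm_defined = abs(point["rr_te"] - 1.0) > 1e-12
    if spec.inference == "bootstrap":
        eff = _bootstrap(models, spec, ("rr_te", "rr_pde", "rr_tie", "pm"))
    else:
        eff = {}
        for k in ("rr_te", "rr_pde", "rr_tie"):
            eff[k] = delta_ci(_effect_fn(models, k, c, spec.a, spec.a_star),
                              models, spec.level, scale="log")
        if pm_defined:
            eff["pm"] = delta_ci(_effect_fn(models, "pm", c, spec.a, spec.a_star),
                                 models, spec.level, scale="identity")
        else:
            eff["pm"] = Effect(np.nan, np.nan, np.nan, np.nan)
    if not pm_defined:
        eff["pm"] = Effect(np.nan, np.nan, np.nan, np.nan)
    return TwoWayResult(eff["rr_te"], eff["rr_pde"], eff["rr_tie"], eff["pm"],
                        pm_defined, tuple(c), spec.inference)


def four_way_decomposition(models: MediationModelPair, spec: MediationSpec) -> FourWayResult:
    """CDE / INT_ref / PIE / INT_med on the excess-relative-risk scale."""
    if models.outcome.family != "log_poisson":
        raise ValueError("four_way_decomposition requires a log-link outcome model")
    c = models.resolve_c(spec)
    point = _estimands(models.theta(), models.beta(), c, spec.a, spec.a_star)
    comp = ("err_cde", "err_intref", "err_pie", "err_intmed")
    te_defined = abs(point["rr_te"] - 1.0) > 1e-12

    def prop_fn(name):
        def f(v):
            th, be = _split(models, v)
            e = _estimands(th, be, c, spec.a, spec.a_star)
            return e[name] / (e["rr_te"] - 1.0)
        return f

    if spec.inference == "bootstrap":
        eff = _bootstrap(models, spec, comp)
        props = {k: Effect(point[k] / (point["rr_te"] - 1.0) if te_defined else np.nan,
                           np.nan, np.nan, np.nan) for k in comp}
    else:
        eff = {k: delta_ci(_effect_fn(models, k, c, spec.a, spec.a_star),
                           models, spec.level, scale="identity") for k in comp}
        props = {}
        for k in comp:
            if te_defined:
                props[k] = delta_ci(prop_fn(k), models, spec.level, scale="identity")
            else:
                props[k] = Effect(np.nan, np.nan, np.nan, np.nan)
    return FourWayResult(eff["err_cde"], eff["err_intref"], eff["err_pie"], eff["err_intmed"],
                         props["err_cde"], props["err_intref"], props["err_pie"],
                         props["err_intmed"], point["rr_te"], tuple(c), spec.inference)


def mediate_linear_outcome(models: MediationModelPair, spec: MediationSpec) -> TwoWayResult:
    """Two-way decomposition on the mean-difference scale (linear outcome).

    Returns a TwoWayResult whose ``rr_*`` slots carry additive effects:
    ``rr_te`` = TE, ``rr_pde`` = PDE, ``rr_tie`` = TIE, all differences.
    """
    if models.outcome.family != "linear":
        raise ValueError("mediate_linear_outcome requires a linear outcome fit")
    c = models.resolve_c(spec)

    def qlin(v: np.ndarray, a: float, a_prime: float) -> float:
        th, be = _split(models, v)
        p = _p_med(be, a_prime, c)
        base = th[0] + th[1] * a + (th[4:] @ c if c.size else 0.0)
        return float(base + (th[2] + th[3] * a) * p)

    def pde(v): return qlin(v, spec.a, spec.a_star) - qlin(v, spec.a_star, spec.a_star)
    def tie(v): return qlin(v, spec.a, spec.a) - qlin(v, spec.a, spec.a_star)
    def te(v): return pde(v) + tie(v)

    x0 = np.concatenate([models.theta(), models.beta()])
    te0 = te(x0)
    pm_defined = abs(te0) > 1e-12
    eff = {
        "te": delta_ci(te, models, spec.level),
        "pde": delta_ci(pde, models, spec.level),
        "tie": delta_ci(tie, models, spec.level),
    }
    if pm_defined:
        eff["pm"] = delta_ci(lambda v: tie(v) / te(v), models, spec.level)
    else:
        eff["pm"] = Effect(np.nan, np.nan, np.nan, np.nan)
    return TwoWayResult(eff["te"], eff["pde"], eff["tie"], eff["pm"],
                        pm_defined, tuple(c), "delta")


# ----------------------------------------------------------------------
# Monte-Carlo potential-outcome oracle
# ----------------------------------------------------------------------

def monte_carlo_oracle(theta: Sequence[float], beta: Sequence[float],
                       c: Sequence[float] = (), n_draws: int = 1_000_000,
                       seed: int = 0, a: float = 1.0, a_star: float = 0.0,
                       ) -> dict[str, tuple[float, float]]:
    """Simulate M(a') and Y(a, m) directly from the two models and average.

    Returns ``{estimand: (value, mc_se)}`` for the same estimand set as
    the closed forms.  Each counterfactual mean is estimated from an
    independent batch of ``n_draws`` Bernoulli draws, so the standard
    errors propagate by the delta method over independent means.
    """
    theta = np.asarray(theta, dtype=float)
    beta = np.asarray(beta, dtype=float)
    c = np.asarray(c, dtype=float)
    risks = {(aa, mm): _risk(theta, aa, mm, c) for aa in (a_star, a) for mm in (0.0, 1.0)}
    if max(risks.values()) > 1.0 + 1e-12:
        raise ValueError(f"risk exceeds 1 for some (a, m): {risks}")
    p = {a: _p_med(beta, a, c), a_star: _p_med(beta, a_star, c)}
    rng = np.random.default_rng(seed)

    def mean_y(aa: float, a_prime: float | None, m_fixed: float | None) -> tuple[float, float]:
        if m_fixed is not None:
            risk = np.full(n_draws, risks[(aa, m_fixed)])
        else:
            m = rng.random(n_draws) < p[a_prime]
            risk = np.where(m, risks[(aa, 1.0)], risks[(aa, 0.0)])
        y = rng.random(n_draws) < risk
        ph = float(np.mean(y))
        return ph, float(np.sqrt(max(ph * (1 - ph), 1e-300) / n_draws))

    # six independent counterfactual means
    means = {
        "q11": mean_y(a, a, None),
        "q10": mean_y(a, a_star, None),
        "q00": mean_y(a_star, a_star, None),
        "q01": mean_y(a_star, a, None),
        "y_a1_m0": mean_y(a, None, 0.0),
        "y_a0_m0": mean_y(a_star, None, 0.0),
    }
    keys = list(means)
    vals = np.array([means[k][0] for k in keys])
    ses = np.array([means[k][1] for k in keys])

    def est(v: np.ndarray) -> dict[str, float]:
        q11, q10, q00, q01, y10, y00 = v
        rr_te = q11 / q00
        rr_pde = q10 / q00
        rr_tie = q11 / q10
        pm = rr_pde * (rr_tie - 1.0) / (rr_te - 1.0) if rr_te != 1.0 else np.nan
        return {
            "rr_te": rr_te, "rr_pde": rr_pde, "rr_tie": rr_tie, "pm": pm,
            "err_cde": (y10 - y00) / q00,
            "err_intref": (q10 - q00 - (y10 - y00)) / q00,
            "err_pie": (q01 - q00) / q00,
            "err_intmed": (q11 - q10 - (q01 - q00)) / q00,
        }

    point = est(vals)
    out: dict[str, tuple[float, float]] = {}
    for name in ESTIMANDS:
        if not np.isfinite(point[name]):
            out[name] = (point[name], np.inf)
            continue
        g = _fd_grad(lambda v, nm=name: est(v)[nm], vals, rel_step=1e-5)
        out[name] = (point[name], float(np.sqrt(np.sum((g * ses) ** 2))))
    return out
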