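"""Bivariate ACE/ADE variance-component models fitted by FIML.

Component covariance matrices (A, C-or-D, E) are estimated directly as
symmetric 2x2 matrices per sex — the variance-component parameterization, in
which component matrices may be indefinite and only the implied total
covariance of each group must be positive definite (the deviance is +inf
otherwise). Standardization yields univariate variance shares, bivariate
covariance shares (bivariate heritability), genetic/environmental
correlations and the model-implied phenotypic correlation, with
profile-likelihood confidence intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from . import _fiml
from ._optimize import BIG, finite, minimize_deviance, numeric_gradient
from .synthetic_data import CROSS_WEIGHTS, GroupParams, implied_pair_covariance
from .twin_data import GROUPS, TwinDataset, group_split, observed_count

COMPONENTS = ("A", "CorD", "E")
SEX_EQUALITY_MODES = ("none", "full", "scalar")
#: order of the packed entries of one symmetric 2x2 component
_TRI = ((0, 0), (0, 1), (1, 1))


class UndefinedCorrelationError(ValueError):
    """A component correlation is requested with a non-positive variance."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of a biometric model.

    ``components_by_sex`` lists the components present per sex (E always
    included); ``sex_equality`` is ``none`` (all components sex-specific),
    ``full`` (components equated across sexes) or ``scalar`` (male components
    free, female total variance a per-trait multiple k of the male one, all
    standardized quantities equal). Means are sex-specific, equal across twin
    order and zygosity, in every mode.
    """

    family: str
    components_by_sex: Mapping[str, tuple[str, ...]] = None
    sex_equality: str = "none"

    def __post_init__(self) -> None:
        if self.family not in ("ACE", "ADE"):
            raise ValueError("family must be 'ACE' or 'ADE'")
        comps = self.components_by_sex or {
            "F": ("A", "CorD", "E"), "M": ("A", "CorD", "E")
        }
        comps = {s: tuple(c) for s, c in comps.items()}
        if set(comps) != {"F", "M"}:
            raise ValueError("components_by_sex must have keys F and M")
        for s, cs in comps.items():
            if "E" not in cs:
                raise ValueError(f"E must be present for sex {s}")
            unknown = set(cs) - set(COMPONENTS)
            if unknown:
                raise ValueError(f"unknown components {sorted(unknown)}")
        if self.sex_equality not in SEX_EQUALITY_MODES:
            raise ValueError(f"sex_equality must be one of {SEX_EQUALITY_MODES}")
        if self.sex_equality in ("full", "scalar") and comps["F"] != comps["M"]:
            raise ValueError("sex-equality modes require identical component "
                             "sets for both sexes")
        object.__setattr__(self, "components_by_sex", comps)

    @property
    def n_free(self) -> int:
        if self.sex_equality == "none":
            n = sum(3 * len(cs) for cs in self.components_by_sex.values())
        elif self.sex_equality == "full":
            n = 3 * len(self.components_by_sex["M"])
        else:  # scalar
            n = 3 * len(self.components_by_sex["M"]) + 2
        return n + 4  # two means per sex

    def label(self) -> str:
        comps = "".join(c if c != "CorD" else ("C" if self.family == "ACE" else "D")
                        for c in self.components_by_sex["M"])
        tag = {"none": "sex diff", "full": "no sex diff", "scalar": "scalar"}
        return f"{comps} ({tag[self.sex_equality]})"


@dataclass
class BiometricParams:
    """Unstandardized parameter values of a biometric model."""

    components: dict[str, dict[str, np.ndarray]]  # sex -> comp -> 2x2
    mu: dict[str, np.ndarray]                     # sex -> (2,)
    k: np.ndarray | None = None                   # scalar mode: per-trait factor

    def effective_components(self, sex: str, spec: ModelSpec) -> dict[str, np.ndarray]:
        """Component matrices actually entering the likelihood for a sex."""
        if spec.sex_equality == "none":
            return self.components[sex]
        base = self.components["M"]
        if spec.sex_equality == "full" or sex == "M":
            return base
        s = np.diag(np.sqrt(self.k))
        return {c: s @ m @ s for c, m in base.items()}


@dataclass
class FitResult:
    """A fitted biometric model with fit statistics and diagnostics."""

    spec: ModelSpec
    params: BiometricParams
    minus2LL: float
    n_free: int
    df: int
    AIC: float
    converged: bool
    n_obs: int
    diagnostics: dict = field(default_factory=dict)
    _dataset: TwinDataset | None = field(default=None, repr=False)
    _free_vector: np.ndarray | None = field(default=None, repr=False)


# -- deviance ---------------------------------------------------------------

def _group_params(params: BiometricParams, spec: ModelSpec, sex: str) -> GroupParams:
    comps = params.effective_components(sex, spec)
    zero = np.zeros((2, 2))
    return GroupParams(
        A=comps.get("A", zero), CorD=comps.get("CorD", zero),
        E=comps["E"], mu=params.mu[sex],
    )


def _deviance_patterns(
    params: BiometricParams, spec: ModelSpec,
    patterns: Mapping[str, list],
) -> float:
    total = 0.0
    for g in GROUPS:
        zyg, sex = g[:2], g[2].upper()
        gp = _group_params(params, spec, sex)
        sigma = implied_pair_covariance(gp, spec.family, zyg)
        mu = np.concatenate([gp.mu, gp.mu])
        total += _fiml.neg2ll(patterns[g], mu, sigma)
        if not math.isfinite(total):
            return math.inf
    return total


def deviance(params: BiometricParams, spec: ModelSpec,
             dataset: TwinDataset) -> float:
    """-2 log-likelihood of the dataset under the model (FIML).

    +inf when any group's implied pair covariance is not positive definite.
    """
    groups = group_split(dataset)
    patterns = {g: _fiml.split_patterns(groups[g].y) for g in GROUPS}
    return _deviance_patterns(params, spec, patterns)


# -- parameter vector packing ----------------------------------------------

def _pack(params: BiometricParams, spec: ModelSpec) -> np.ndarray:
    out = []
    if spec.sex_equality == "none":
        for sex in ("F", "M"):
            for c in spec.components_by_sex[sex]:
                m = params.components[sex][c]
                out.extend(m[i, j] for i, j in _TRI)
    else:
        for c in spec.components_by_sex["M"]:
            m = params.components["M"][c]
            out.extend(m[i, j] for i, j in _TRI)
        if spec.sex_equality == "scalar":
            out.extend(np.log(params.k))
    for sex in ("F", "M"):
        out.extend(params.mu[sex])
    return np.array(out, dtype=float)


def _unpack(x: np.ndarray, spec: ModelSpec) -> BiometricParams:
    k_idx = 0

    def take_matrix():
        nonlocal k_idx
        m = np.empty((2, 2))
        for (i, j), v in zip(_TRI, x[k_idx:k_idx + 3]):
            m[i, j] = m[j, i] = v
        k_idx += 3
        return m

    components: dict[str, dict[str, np.ndarray]] = {}
    k = None
    if spec.sex_equality == "none":
        for sex in ("F", "M"):
            components[sex] = {c: take_matrix()
                               for c in spec.components_by_sex[sex]}
    else:
        shared = {c: take_matrix() for c in spec.components_by_sex["M"]}
        components = {"F": shared, "M": shared}
        if spec.sex_equality == "scalar":
            k = np.exp(x[k_idx:k_idx + 2])
            k_idx += 2
    mu = {}
    for sex in ("F", "M"):
        mu[sex] = x[k_idx:k_idx + 2].copy()
        k_idx += 2
    return BiometricParams(components=components, mu=mu, k=k)


# -- analytic gradient ------------------------------------------------------

def _layout(spec: ModelSpec) -> dict:
    """Offsets of the packed free-parameter vector (mirrors _pack)."""
    comp_slots: dict[tuple[str, str], int] = {}
    k = 0
    if spec.sex_equality == "none":
        for sex in ("F", "M"):
            for c in spec.components_by_sex[sex]:
                comp_slots[(sex, c)] = k
                k += 3
    else:
        for c in spec.components_by_sex["M"]:
            comp_slots[("M", c)] = k
            k += 3
    k_slot = None
    if spec.sex_equality == "scalar":
        k_slot = k
        k += 2
    mu_slots = {}
    for sex in ("F", "M"):
        mu_slots[sex] = k
        k += 2
    return {"comp": comp_slots, "k": k_slot, "mu": mu_slots, "n": k}


def _comp_weight(comp: str, family: str, zygosity: str) -> float:
    a_w, d_w = CROSS_WEIGHTS[(family, zygosity)]
    return {"A": a_w, "CorD": d_w, "E": 0.0}[comp]


def _deviance_and_grad(
    x: np.ndarray, spec: ModelSpec, patterns: Mapping[str, list]
) -> tuple[float, np.ndarray]:
    """Deviance and its exact gradient with respect to the packed vector.

    Uses d(-2LL)/dSigma = n * Sigma^-1 - Sigma^-1 S Sigma^-1 per missingness
    pattern (S the residual cross-product) and the linearity of the implied
    covariance in the component entries; the scalar-mode k factors enter via
    the chain rule through the sqrt(k) row/column scaling.
    """
    params = _unpack(x, spec)
    layout = _layout(spec)
    grad = np.zeros(layout["n"])
    dev = 0.0
    scalar = spec.sex_equality == "scalar"
    s_vec = np.sqrt(params.k) if scalar else None

    for g in GROUPS:
        zyg, sex = g[:2], g[2].upper()
        comps = params.effective_components(sex, spec)
        zero = np.zeros((2, 2))
        within = sum(comps.values())
        cross = sum(_comp_weight(c, spec.family, zyg) * m
                    for c, m in comps.items()) + zero
        sigma = np.block([[within, cross], [cross, within]])
        mu4 = np.concatenate([params.mu[sex], params.mu[sex]])

        gfull = np.zeros((4, 4))
        mgrad = np.zeros(4)
        for cols, ysub in patterns[g]:
            sub = sigma[np.ix_(cols, cols)]
            try:
                chol = np.linalg.cholesky(sub)
            except np.linalg.LinAlgError:
                return math.inf, grad
            n_i, kdim = ysub.shape
            logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
            resid = ysub - mu4[cols]
            z = np.linalg.solve(chol, resid.T)
            dev += n_i * (kdim * math.log(2.0 * math.pi) + logdet) \
                + float(np.sum(z * z))
            inv = np.linalg.solve(chol.T, np.linalg.solve(chol, np.eye(kdim)))
            tr = inv @ resid.T  # Sigma^-1 r_i, columns
            gfull[np.ix_(cols, cols)] += n_i * inv - tr @ tr.T
            mgrad[cols] += -2.0 * tr.sum(axis=1)

        gw = gfull[:2, :2] + gfull[2:, 2:]
        gx = gfull[:2, 2:] + gfull[2:, :2]
        comp_list = spec.components_by_sex[sex]
        for c in comp_list:
            w_c = _comp_weight(c, spec.family, zyg)
            mfull = gw + w_c * gx
            if spec.sex_equality == "none":
                slot = layout["comp"][(sex, c)]
            else:
                slot = layout["comp"][("M", c)]
                if scalar and sex == "F":
                    # d(effective F comp)/d(male comp entry) scales by s_a s_b
                    if layout["k"] is not None:
                        cf = comps[c]
                        for t in range(2):
                            dk = (mfull[t, t] * cf[t, t]
                                  + 0.5 * (mfull[t, 1 - t] + mfull[1 - t, t])
                                  * cf[t, 1 - t])
                            grad[layout["k"] + t] += dk
                    mfull = mfull * np.outer(s_vec, s_vec)
            grad[slot] += mfull[0, 0]
            grad[slot + 1] += mfull[0, 1] + mfull[1, 0]
            grad[slot + 2] += mfull[1, 1]
        mu_slot = layout["mu"][sex]
        grad[mu_slot:mu_slot + 2] += mgrad[:2] + mgrad[2:]
    return dev, grad


# -- starting values --------------------------------------------------------

def _sex_moments(dataset: TwinDataset) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-sex within-twin mean and 2x2 covariance from stacked twin columns."""
    out = {}
    for sex in ("F", "M"):
        rows = dataset.sex == sex
        stacked = np.vstack([dataset.y[rows][:, :2], dataset.y[rows][:, 2:]])
        mu = np.nanmean(stacked, axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d0 = stacked[:, 0] - mu[0]
            d1 = stacked[:, 1] - mu[1]
            v0 = np.nanmean(d0 * d0)
            v1 = np.nanmean(d1 * d1)
            c01 = np.nanmean(d0 * d1)
        cov = np.array([[v0, c01], [c01, v1]])
        out[sex] = (mu, _fiml.nearest_pd(cov, min_eig=1e-4))
    return out


def default_starts(dataset: TwinDataset, spec: ModelSpec) -> BiometricParams:
    """Data-driven starts: means from group averages, each present component
    an equal split of the pooled within-twin covariance."""
    moments = _sex_moments(dataset)
    components: dict[str, dict[str, np.ndarray]] = {}
    mu = {s: moments[s][0] for s in ("F", "M")}
    if spec.sex_equality == "none":
        for sex in ("F", "M"):
            comps = spec.components_by_sex[sex]
            components[sex] = {c: moments[sex][1] / len(comps) for c in comps}
        return BiometricParams(components=components, mu=mu)
    comps = spec.components_by_sex["M"]
    shared = {c: moments["M"][1] / len(comps) for c in comps}
    components = {"F": shared, "M": shared}
    k = None
    if spec.sex_equality == "scalar":
        k = np.clip(np.diag(moments["F"][1]) / np.diag(moments["M"][1]),
                    0.1, 10.0)
    return BiometricParams(components=components, mu=mu, k=k)


# -- fitting ----------------------------------------------------------------

def fit_biometric(
    dataset: TwinDataset,
    spec: ModelSpec,
    starts: BiometricParams | None = None,
    n_starts: int = 3,
    tol: float = 1e-8,
) -> FitResult:
    """Minimize the FIML deviance by quasi-Newton iteration with jittered
    multi-starts, returning the best optimum."""
    groups = group_split(dataset)
    for g in GROUPS:
        if len(groups[g]) == 0:
            raise ValueError(f"group {g} is empty")
    patterns = {g: _fiml.split_patterns(groups[g].y) for g in GROUPS}
    n_obs = observed_count(dataset)

    if starts is None:
        starts = default_starts(dataset, spec)
    x0 = _pack(starts, spec)

    def objective(x: np.ndarray) -> float:
        return _deviance_patterns(_unpack(x, spec), spec, patterns)

    x, dev, converged, diagnostics = minimize_deviance(
        objective, x0, n_starts=n_starts, tol=tol,
        fun_and_grad=lambda x: _deviance_and_grad(x, spec, patterns),
    )
    if not math.isfinite(dev) or dev >= BIG:
        raise RuntimeError(f"biometric fit failed to converge: {diagnostics}")
    n_free = spec.n_free
    df = n_obs - n_free
    return FitResult(
        spec=spec, params=_unpack(x, spec), minus2LL=dev, n_free=n_free,
        df=df, AIC=dev - 2.0 * df, converged=converged, n_obs=n_obs,
        diagnostics=diagnostics, _dataset=dataset, _free_vector=x,
    )


# -- component correlations -------------------------------------------------

def _component_correlation(m: np.ndarray, what: str) -> float:
    m = np.asarray(m, dtype=float)
    if m[0, 0] <= 0 or m[1, 1] <= 0:
        raise UndefinedCorrelationError(
            f"{what} correlation undefined: non-positive variance on the "
            "diagonal")
    r = float(m[0, 1] / math.sqrt(m[0, 0] * m[1, 1]))
    if abs(r) > 1.0:
        warnings.warn(f"{what} correlation {r:.3f} outside [-1, 1]: the "
                      "component matrix is indefinite", stacklevel=3)
    return r


def genetic_correlation(a: np.ndarray) -> float:
    """rg = VA12 / sqrt(VA11 * VA22); not truncated to [-1, 1]."""
    return _component_correlation(a, "genetic")


def environmental_correlation(e: np.ndarray) -> float:
    """re = VE12 / sqrt(VE11 * VE22); not truncated to [-1, 1]."""
    return _component_correlation(e, "environmental")


# -- standardization --------------------------------------------------------

@dataclass
class SexEstimates:
    """Standardized quantities for one sex."""

    shares: dict[str, tuple[float, float]]   # comp -> per-trait variance share
    biv_shares: dict[str, float] | None      # comp -> covariance share
    correlations: dict[str, float]           # comp -> rg / rc / rd / re
    r_ph_implied: float
    total: np.ndarray                        # model-implied 2x2 within-twin cov


@dataclass
class StandardizedEstimates:
    by_sex: dict[str, SexEstimates]
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)


def standardize(fit: FitResult, zero_cov_tol: float = 1e-12) -> StandardizedEstimates:
    """Univariate shares, bivariate covariance shares and component
    correlations per sex. Bivariate shares are None (flagged) when the
    model-implied phenotypic covariance is zero."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    spec = fit.spec
    by_sex = {}
    for sex in ("F", "M"):
        comps = fit.params.effective_components(sex, spec)
        total = sum(comps.values())
        shares = {c: (float(m[0, 0] / total[0, 0]), float(m[1, 1] / total[1, 1]))
                  for c, m in comps.items()}
        cov_ph = float(total[0, 1])
        if abs(cov_ph) > zero_cov_tol:
            biv = {c: float(m[0, 1] / cov_ph) for c, m in comps.items()}
        else:
            biv = None
        corr = {}
        for c, m in comps.items():
            try:
                corr[c] = _component_correlation(m, c)
            except UndefinedCorrelationError:
                corr[c] = math.nan
        r_ph = cov_ph / math.sqrt(total[0, 0] * total[1, 1])
        by_sex[sex] = SexEstimates(shares=shares, biv_shares=biv,
                                   correlations=corr, r_ph_implied=r_ph,
                                   total=total)
    return StandardizedEstimates(by_sex=by_sex)


# -- profile-likelihood confidence intervals --------------------------------

def _target_function(fit: FitResult, quantity: str):
    """Map a quantity label to a function of the free parameter vector.

    Labels: ``'F:A:11'`` (raw component entry, indices 11/12/22),
    ``'F:mu:1'``, ``'k:1'``, ``'F:share:A:1'`` (standardized variance share),
    ``'F:biv:A'`` (bivariate share), ``'F:corr:A'`` (component correlation),
    ``'F:rph'`` (model-implied phenotypic correlation).
    """
    spec = fit.spec
    parts = quantity.split(":")

    if parts[0] == "k":
        t = int(parts[1]) - 1

        def target(x):
            return float(_unpack(x, spec).k[t])
        return target

    sex = parts[0]
    if sex not in ("F", "M"):
        raise ValueError(f"bad quantity label {quantity!r}")

    if parts[1] == "mu":
        t = int(parts[2]) - 1

        def target(x):
            return float(_unpack(x, spec).mu[sex][t])
        return target

    if parts[1] in COMPONENTS:
        idx = {"11": (0, 0), "12": (0, 1), "22": (1, 1)}[parts[2]]

        def target(x):
            p = _unpack(x, spec)
            return float(p.effective_components(sex, spec)[parts[1]][idx])
        return target

    if parts[1] == "share":
        comp, t = parts[2], int(parts[3]) - 1

        def target(x):
            p = _unpack(x, spec)
            comps = p.effective_components(sex, spec)
            total = sum(comps.values())
            return float(comps[comp][t, t] / total[t, t])
        return target

    if parts[1] == "biv":
        comp = parts[2]

        def target(x):
            p = _unpack(x, spec)
            comps = p.effective_components(sex, spec)
            total = sum(comps.values())
            return float(comps[comp][0, 1] / total[0, 1])
        return target

    if parts[1] == "corr":
        comp = parts[2]

        def target(x):
            p = _unpack(x, spec)
            m = p.effective_components(sex, spec)[comp]
            denom = math.sqrt(max(m[0, 0] * m[1, 1], 1e-300))
            return float(m[0, 1] / denom)
        return target

    if parts[1] == "rph":
        def target(x):
            p = _unpack(x, spec)
            total = sum(p.effective_components(sex, spec).values())
            return float(total[0, 1] / math.sqrt(total[0, 0] * total[1, 1]))
        return target

    raise ValueError(f"bad quantity label {quantity!r}")


@dataclass
class ProfileInterval:
    lower: float
    upper: float
    level: float
    open_lower: bool = False
    open_upper: bool = False


def profile_interval(
    objective,
    x_hat: np.ndarray,
    target,
    crit: float,
    se_guess: float | None = None,
    max_doublings: int = 14,
    t_tol: float = 1e-5,
    g_tol: float = 1e-4,
    inner_ftol: float = 1e-9,
    objective_and_grad=None,
) -> ProfileInterval:
    """Likelihood-based interval for ``target`` under ``objective``.

    The bound on each side is the value of the target at which the
    re-optimized objective (all other parameters free, target pinned by an
    equality constraint) exceeds its minimum by ``crit``. A Wald-style step
    (``se_guess`` times the normal quantile) seeds the bracket when
    available, then bisection with quadratic interpolation refines it,
    stopping once the deviance gap is within ``g_tol`` or the bound within
    ``t_tol`` (relative). Open ends are flagged when no bracket is found
    within the search range.
    """
    f = finite(objective)
    f_min = f(x_hat)
    t_hat = target(x_hat)

    if objective_and_grad is not None:
        def inner(x):
            v, g = objective_and_grad(x)
            return (BIG, g) if not math.isfinite(v) else (v, g)
        inner_kwargs = {"fun": inner, "jac": True}
    else:
        inner_kwargs = {"fun": f}

    def profiled(t0: float, x_start: np.ndarray) -> tuple[float, np.ndarray]:
        cons = [{"type": "eq", "fun": lambda x: target(x) - t0}]
        res = minimize(x0=x_start, method="SLSQP", constraints=cons,
                       options={"maxiter": 100, "ftol": inner_ftol},
                       **inner_kwargs)
        val = res.fun if math.isfinite(res.fun) else BIG
        return float(val), np.asarray(res.x)

    if se_guess is not None and math.isfinite(se_guess) and se_guess > 0:
        step0 = math.sqrt(crit) * se_guess
    else:
        step0 = 0.1 * (abs(t_hat) + 0.1)

    def bound(direction: float) -> tuple[float, bool]:
        step = step0
        x_start = x_hat.copy()
        t_in, g_in = t_hat, -crit
        bracket = None
        g = math.nan
        for _ in range(max_doublings):
            t_try = t_hat + direction * step
            val, x_sol = profiled(t_try, x_start)
            g = val - f_min - crit
            if abs(g) < g_tol:
                return t_try, False
            if g > 0:
                bracket = (t_in, t_try)
                break
            t_in, g_in, x_start = t_try, g, x_sol
            step *= 2.0
        if bracket is None:
            return t_in, True
        lo, hi = bracket  # g(lo) < 0 < g(hi)
        g_lo, g_hi = g_in, g
        t_best = (lo + hi) / 2.0
        for _ in range(40):
            if abs(hi - lo) < t_tol * (abs(t_hat) + 1.0):
                break
            # near the optimum the deviance is ~quadratic in t, so the gap g
            # is ~quadratic too; interpolate the root on the sqrt scale
            w = math.sqrt(max(-g_lo, 1e-12))
            w2 = math.sqrt(max(g_hi + crit, 1e-12)) - math.sqrt(crit)
            frac = w / (w + w2) if (w + w2) > 0 else 0.5
            frac = min(max(frac, 0.05), 0.95)
            t_mid = lo + frac * (hi - lo)
            val, x_sol = profiled(t_mid, x_start)
            g_mid = val - f_min - crit
            if abs(g_mid) < g_tol:
                return t_mid, False
            if g_mid > 0:
                hi, g_hi = t_mid, g_mid
            else:
                lo, g_lo, x_start = t_mid, g_mid, x_sol
            t_best = (lo + hi) / 2.0
        return t_best, False

    up, open_up = bound(+1.0)
    lo, open_lo = bound(-1.0)
    return ProfileInterval(lower=min(lo, t_hat), upper=max(up, t_hat),
                           level=math.nan, open_lower=open_lo,
                           open_upper=open_up)


def profile_ci(fit: FitResult, quantity: str, level: float = 0.95) -> ProfileInterval:
    """Profile-likelihood CI for a parameter or standardized derived quantity.

    The interval is the set of target values whose re-optimized deviance lies
    within the chi-square(1) quantile at ``level`` (3.841 for 95%) of the
    minimum.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    if fit._dataset is None or fit._free_vector is None:
        raise ValueError("fit carries no dataset; refit before profiling")
    groups = group_split(fit._dataset)
    patterns = {g: _fiml.split_patterns(groups[g].y) for g in GROUPS}
    spec = fit.spec

    def objective(x: np.ndarray) -> float:
        return _deviance_patterns(_unpack(x, spec), spec, patterns)

    def objective_and_grad(x: np.ndarray):
        return _deviance_and_grad(x, spec, patterns)

    target = _target_function(fit, quantity)
    crit = float(chi2.ppf(level, df=1))

    # Wald SE via curvature of the deviance seeds the search; the interval
    # itself remains purely profile-likelihood based. The Hessian comes from
    # central differences of the analytic gradient.
    se_guess = None
    try:
        x_hat = fit._free_vector
        n = len(x_hat)
        h = 1e-5 * (np.abs(x_hat) + 1.0)
        hess = np.empty((n, n))
        for i in range(n):
            e = np.zeros(n)
            e[i] = h[i]
            _, gp = objective_and_grad(x_hat + e)
            _, gm = objective_and_grad(x_hat - e)
            hess[i] = (gp - gm) / (2.0 * h[i])
        hess = (hess + hess.T) / 2.0
        grad_t = numeric_gradient(target, x_hat)
        cov = 2.0 * np.linalg.inv(hess)
        var = float(grad_t @ cov @ grad_t)
        if var > 0:
            se_guess = math.sqrt(var)
    except np.linalg.LinAlgError:
        pass

    interval = profile_interval(objective, fit._free_vector, target, crit,
                                se_guess=se_guess, t_tol=1e-3, g_tol=0.02,
                                inner_ftol=1e-7,
                                objective_and_grad=objective_and_grad)
    interval.level = level
    return interval
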