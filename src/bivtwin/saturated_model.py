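"""Saturated (unstructured) FIML model for the four twin groups.

Estimates group-specific mean vectors and 4x4 covariance matrices by
full-information maximum likelihood and derives descriptive statistics:
phenotypic correlations, twin correlations and cross-twin cross-trait
correlations, plus the sex mean-difference likelihood-ratio test.

Supported constraint labels
---------------------------
``twin_order``
    Within each group, means and the within-twin covariance block are equal
    across twin 1 and twin 2 (covariance takes the form [[W, X], [X', W]]).
``sex_means_equal``
    Mean vectors equated across sexes within zygosity (MZf = MZm, DZf = DZm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _fiml
from ._optimize import minimize_deviance
from .twin_data import GROUPS, TwinDataset, group_split, observed_count

VALID_CONSTRAINTS = ("twin_order", "sex_means_equal")


@dataclass
class SaturatedFit:
    """Converged saturated-model estimates for all four groups."""

    means: dict[str, np.ndarray]
    covs: dict[str, np.ndarray]
    minus2LL: float
    n_params: int
    constraints_applied: tuple[str, ...]
    n_obs: int
    n_pairs_by_group: dict[str, int]
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_free(self) -> int:
        return self.n_params

    @property
    def df(self) -> int:
        return self.n_obs - self.n_params


class ConvergenceError(RuntimeError):
    pass


def _count_params(constraints: tuple[str, ...]) -> int:
    twin_order = "twin_order" in constraints
    sex_eq = "sex_means_equal" in constraints
    mean_per_set = 2 if twin_order else 4
    n_mean_sets = 2 if sex_eq else 4  # per zygosity vs per group
    cov_per_group = 7 if twin_order else 10
    return n_mean_sets * mean_per_set + 4 * cov_per_group


# -- covariance (un)packing -------------------------------------------------

def _chol_pack(sigma: np.ndarray) -> np.ndarray:
    chol = np.linalg.cholesky(sigma)
    params = []
    for i in range(4):
        for j in range(i + 1):
            params.append(math.log(chol[i, j]) if i == j else chol[i, j])
    return np.array(params)


def _chol_unpack(params: np.ndarray) -> np.ndarray:
    chol = np.zeros((4, 4))
    k = 0
    for i in range(4):
        for j in range(i + 1):
            chol[i, j] = math.exp(params[k]) if i == j else params[k]
            k += 1
    return chol @ chol.T


def _struct_pack(sigma: np.ndarray) -> np.ndarray:
    """Symmetrize to the twin-order structure [[W, X], [X', W]] and pack."""
    w = (sigma[:2, :2] + sigma[2:, 2:]) / 2.0
    x = (sigma[:2, 2:] + sigma[2:, :2].T) / 2.0
    return np.array([
        math.log(max(w[0, 0], 1e-8)), math.log(max(w[1, 1], 1e-8)), w[0, 1],
        x[0, 0], x[0, 1], x[1, 0], x[1, 1],
    ])


def _struct_unpack(params: np.ndarray) -> np.ndarray:
    w = np.array([[math.exp(params[0]), params[2]],
                  [params[2], math.exp(params[1])]])
    x = np.array([[params[3], params[4]], [params[5], params[6]]])
    return np.block([[w, x], [x.T, w]])


# -- fitting ----------------------------------------------------------------

def fit_saturated(
    dataset: TwinDataset,
    constraints: tuple[str, ...] = (),
    n_starts: int = 1,
    tol: float = 1e-8,
) -> SaturatedFit:
    """FIML fit of group means and unstructured/structured covariances."""
    for c in constraints:
        if c not in VALID_CONSTRAINTS:
            raise ValueError(f"unknown constraint label {c!r}")
    groups = group_split(dataset)
    for g in GROUPS:
        if len(groups[g]) == 0:
            raise ValueError(f"group {g} is empty; all four groups are required")

    twin_order = "twin_order" in constraints
    sex_eq = "sex_means_equal" in constraints
    n_obs = observed_count(dataset)
    n_pairs = {g: len(groups[g]) for g in GROUPS}
    complete = all(not np.isnan(groups[g].y).any() for g in GROUPS)

    if not twin_order and not sex_eq and complete:
        means, covs, dev = _closed_form_fit(groups)
        diagnostics = {"method": "closed-form"}
        converged = True
    elif not twin_order and sex_eq and complete:
        means, covs, dev, diagnostics = _flip_flop_fit(groups, tol)
        converged = True
    else:
        means, covs, dev, converged, diagnostics = _numeric_fit(
            groups, twin_order, sex_eq, n_starts, tol
        )
    if not math.isfinite(dev):
        raise ConvergenceError(f"saturated fit diverged: {diagnostics}")
    return SaturatedFit(
        means=means, covs=covs, minus2LL=dev,
        n_params=_count_params(tuple(constraints)),
        constraints_applied=tuple(constraints), n_obs=n_obs,
        n_pairs_by_group=n_pairs, converged=converged, diagnostics=diagnostics,
    )


def _closed_form_fit(groups):
    means, covs, dev = {}, {}, 0.0
    for g in GROUPS:
        mu, sigma = _fiml.complete_moments(groups[g].y)
        means[g], covs[g] = mu, sigma
        dev += _fiml.neg2ll([(np.arange(4), groups[g].y)], mu, sigma)
    return means, covs, dev


def _flip_flop_fit(groups, tol):
    """Alternating closed-form updates for equal means across sex (complete
    data, unstructured covariance). Each half-step is an exact conditional
    maximizer, so the deviance decreases monotonically."""
    ybar = {g: groups[g].y.mean(axis=0) for g in GROUPS}
    s_in = {}
    for g in GROUPS:
        resid = groups[g].y - ybar[g]
        s_in[g] = resid.T @ resid / len(groups[g])
    pairs_by_zyg = {"MZ": ("MZf", "MZm"), "DZ": ("DZf", "DZm")}
    mu = {z: np.mean([ybar[g] for g in gs], axis=0)
          for z, gs in pairs_by_zyg.items()}
    covs = dict(s_in)
    prev = math.inf
    for it in range(200):
        # means given covariances: per-zygosity GLS pool
        for z, gs in pairs_by_zyg.items():
            a = np.zeros((4, 4))
            b = np.zeros(4)
            for g in gs:
                w = len(groups[g]) * np.linalg.inv(covs[g])
                a += w
                b += w @ ybar[g]
            mu[z] = np.linalg.solve(a, b)
        # covariances given means: ML update
        dev = 0.0
        for z, gs in pairs_by_zyg.items():
            for g in gs:
                d = ybar[g] - mu[z]
                covs[g] = s_in[g] + np.outer(d, d)
                dev += _fiml.neg2ll([(np.arange(4), groups[g].y)], mu[z], covs[g])
        if prev - dev < tol:
            break
        prev = dev
    means = {g: mu[g[:2]].copy() for g in GROUPS}
    return means, covs, dev, {"method": "flip-flop", "n_iter": it + 1}


def _numeric_fit(groups, twin_order, sex_eq, n_starts, tol):
    patterns = {g: _fiml.split_patterns(groups[g].y) for g in GROUPS}
    starts_mu, starts_cov = {}, {}
    for g in GROUPS:
        mu, cov = _fiml.pairwise_moments(groups[g].y)
        starts_mu[g] = mu
        starts_cov[g] = _fiml.nearest_pd(cov)

    mean_sets = ("MZ", "DZ") if sex_eq else GROUPS
    mean_len = 2 if twin_order else 4
    cov_len = 7 if twin_order else 10

    def pack_start() -> np.ndarray:
        parts = []
        for ms in mean_sets:
            src = [g for g in GROUPS if g.startswith(ms)] if sex_eq else [ms]
            mu = np.mean([starts_mu[g] for g in src], axis=0)
            if twin_order:
                mu = (mu[:2] + mu[2:]) / 2.0
            parts.append(mu)
        for g in GROUPS:
            sigma = starts_cov[g]
            parts.append(_struct_pack(sigma) if twin_order else _chol_pack(sigma))
        return np.concatenate(parts)

    def unpack(x: np.ndarray):
        means, covs = {}, {}
        k = 0
        mus = {}
        for ms in mean_sets:
            m = x[k:k + mean_len]
            mus[ms] = np.concatenate([m, m]) if twin_order else m
            k += mean_len
        for g in GROUPS:
            means[g] = mus[g[:2]] if sex_eq else mus[g]
            raw = x[k:k + cov_len]
            covs[g] = _struct_unpack(raw) if twin_order else _chol_unpack(raw)
            k += cov_len
        return means, covs

    def objective(x: np.ndarray) -> float:
        means, covs = unpack(x)
        total = 0.0
        for g in GROUPS:
            total += _fiml.neg2ll(patterns[g], means[g], covs[g])
            if not math.isfinite(total):
                return math.inf
        return total

    x, dev, converged, diagnostics = minimize_deviance(
        objective, pack_start(), n_starts=n_starts, tol=tol
    )
    means, covs = unpack(x)
    diagnostics["method"] = "L-BFGS-B"
    return means, covs, dev, converged, diagnostics


# -- descriptive correlations ----------------------------------------------

@dataclass
class CorrelationSummary:
    """Phenotypic, twin and cross-twin cross-trait correlations."""

    r_ph: dict[str, float]                       # per sex
    twin_r: dict[str, tuple[float, float]]       # per group, (trait1, trait2)
    cross_twin_cross_trait: dict[str, float]     # per group
    ci: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = list(self.r_ph.values())
        for t in self.twin_r.values():
            vals.extend(t)
        vals.extend(self.cross_twin_cross_trait.values())
        if any(abs(v) > 1 + 1e-9 for v in vals):
            raise ValueError("correlation outside [-1, 1]")


def _corr(cov: np.ndarray, i: int, j: int) -> float:
    vi, vj = cov[i, i], cov[j, j]
    if vi <= 0 or vj <= 0:
        raise ValueError("non-positive variance in fitted covariance")
    return float(cov[i, j] / math.sqrt(vi * vj))


def correlations_from_fit(
    fit: SaturatedFit, twin_order_pooling: bool = True
) -> CorrelationSummary:
    """Convert fitted covariances into the descriptive correlation summary.

    Phenotypic correlations pool the within-twin blocks across twin order
    (when the flag is set) and across zygosity within sex, weighted by pair
    counts; zygosity does not enter the within-person distribution.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    twin_r, cross = {}, {}
    for g in GROUPS:
        c = fit.covs[g]
        twin_r[g] = (_corr(c, 0, 2), _corr(c, 1, 3))
        if twin_order_pooling:
            cross[g] = (_corr(c, 0, 3) + _corr(c, 1, 2)) / 2.0
        else:
            cross[g] = _corr(c, 0, 3)
    r_ph = {}
    for sex, gs in (("F", ("MZf", "DZf")), ("M", ("MZm", "DZm"))):
        w = np.zeros((2, 2))
        n_tot = 0
        for g in gs:
            c = fit.covs[g]
            block = (c[:2, :2] + c[2:, 2:]) / 2.0 if twin_order_pooling else c[:2, :2]
            n = fit.n_pairs_by_group[g]
            w += n * block
            n_tot += n
        w /= n_tot
        r_ph[sex] = _corr(w, 0, 1)
    return CorrelationSummary(r_ph=r_ph, twin_r=twin_r,
                              cross_twin_cross_trait=cross)


def test_sex_mean_difference(dataset: TwinDataset, n_starts: int = 1):
    """LRT of sex-equal means against sex-specific means (saturated model).

    Returns a :class:`bivtwin.model_comparison.ComparisonResult`; the df
    difference equals the number of mean parameters equated (8: four per
    zygosity).
    """
    from .model_comparison import lrt_from_values

    free = fit_saturated(dataset, (), n_starts=n_starts)
    constrained = fit_saturated(dataset, ("sex_means_equal",), n_starts=n_starts)
    return lrt_from_values(
        base_label="saturated, sex-specific means",
        nested_label="saturated, sex-equal means",
        base_minus2ll=free.minus2LL,
        nested_minus2ll=constrained.minus2LL,
        delta_df=free.n_params - constrained.n_params,
        alpha=0.05,
    )
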