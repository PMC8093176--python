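"""Nested-model ladder: family choice heuristic, likelihood-ratio tests,
AIC and the standard testing sequence (drop C/D, sex-difference tests,
scalar sex-limitation variant).

Degrees-of-freedom convention: df = total observed data points - free
parameters, and AIC = -2LL - 2*df. Note this differs from the common
AIC = -2LL + 2*(free parameters); see the table arithmetic it reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import chi2

from .biometric_model import FitResult, ModelSpec, fit_biometric
from .saturated_model import correlations_from_fit, fit_saturated
from .twin_data import TwinDataset


@dataclass
class ComparisonResult:
    """One likelihood-ratio comparison between nested models."""

    base_label: str
    nested_label: str
    delta_minus2LL: float
    delta_df: int
    p: float
    alpha: float
    decision: str  # "retain nested" | "retain base"


@dataclass
class LadderRow:
    label: str
    fit: FitResult
    comparison: ComparisonResult | None = None
    retained: bool = False


@dataclass
class ModelLadder:
    rows: list[LadderRow]
    alpha: float
    family: str
    saturated: object = None
    correlations: object = None

    @property
    def retained_label(self) -> str:
        for row in reversed(self.rows):
            if row.retained:
                return row.label
        raise ValueError("no retained model")

    def retained_fit(self) -> FitResult:
        for row in reversed(self.rows):
            if row.retained:
                return row.fit
        raise ValueError("no retained model")


def chi2_upper_tail(x: float, df: int) -> float:
    """Upper-tail (survival) probability of the chi-square distribution."""
    if x < 0:
        raise ValueError("test statistic must be non-negative")
    if df <= 0:
        raise ValueError("df must be positive")
    return float(chi2.sf(x, df))


def aic(fit) -> float:
    """AIC = -2LL - 2*df with df = observed data points - free parameters."""
    return float(fit.minus2LL - 2.0 * fit.df)


def lrt_from_values(
    base_label: str,
    nested_label: str,
    base_minus2ll: float,
    nested_minus2ll: float,
    delta_df: int,
    alpha: float = 0.01,
) -> ComparisonResult:
    """LRT mechanics on raw deviances; used by both saturated and biometric
    comparisons."""
    delta = nested_minus2ll - base_minus2ll
    if delta < 0:
        if delta > -1e-6:
            delta = 0.0  # optimizer jitter
        else:
            raise RuntimeError(
                f"nested model fits better than its base by {-delta:.3g}; "
                "optimizer diagnostics required")
    if delta_df <= 0:
        raise ValueError("nested model must have fewer free parameters")
    p = chi2_upper_tail(delta, delta_df)
    decision = "retain base" if p < alpha else "retain nested"
    return ComparisonResult(
        base_label=base_label, nested_label=nested_label,
        delta_minus2LL=delta, delta_df=delta_df, p=p, alpha=alpha,
        decision=decision,
    )


def lrt(base: FitResult, nested: FitResult, alpha: float = 0.01,
        base_label: str | None = None,
        nested_label: str | None = None) -> ComparisonResult:
    """Likelihood-ratio test of two fits of the same dataset."""
    if nested.n_free >= base.n_free:
        raise ValueError("nested model must have fewer free parameters than "
                         "its base")
    if nested.n_obs != base.n_obs:
        raise ValueError("fits are not on the same data "
                         f"({nested.n_obs} vs {base.n_obs} observed values)")
    return lrt_from_values(
        base_label or base.spec.label(),
        nested_label or nested.spec.label(),
        base.minus2LL, nested.minus2LL,
        nested.df - base.df, alpha,
    )


def choose_family(corr, rule: str = "any") -> dict[str, str]:
    """ACE-vs-ADE heuristic per sex from twin correlations.

    A trait indicates dominance when its MZ twin correlation exceeds twice
    the DZ one; the family for a sex is ADE when at least one trait (``any``,
    the default) or every trait (``all``) indicates dominance. Ties go to ACE.
    """
    if rule not in ("any", "all"):
        raise ValueError("rule must be 'any' or 'all'")
    out = {}
    for sex, (mz_g, dz_g) in (("F", ("MZf", "DZf")), ("M", ("MZm", "DZm"))):
        indicated = [corr.twin_r[mz_g][t] > 2.0 * corr.twin_r[dz_g][t]
                     for t in (0, 1)]
        dominant = any(indicated) if rule == "any" else all(indicated)
        out[sex] = "ADE" if dominant else "ACE"
    return out


@dataclass
class LadderConfig:
    alpha: float = 0.01
    family: str = "auto"          # "auto" | "ACE" | "ADE"
    family_rule: str = "any"
    scalar: bool = True
    per_sex_drops: bool = False
    n_starts: int = 3
    saturated_constraints: tuple[str, ...] = ("twin_order",)


def run_ladder(dataset: TwinDataset, config: LadderConfig | None = None) -> ModelLadder:
    """Execute the nested testing sequence and return the fitted ladder.

    Order: saturated descriptives and family choice; full ACE/ADE with sex
    differences; drop C (or D) for both sexes (optionally per sex); equate
    all components across sexes; optionally the scalar sex-limitation
    variant, compared against the retained sex-difference model.
    """
    config = config or LadderConfig()
    sat = fit_saturated(dataset, config.saturated_constraints,
                        n_starts=1)
    corr = correlations_from_fit(sat)
    if config.family == "auto":
        per_sex = choose_family(corr, config.family_rule)
        family = "ADE" if "ADE" in per_sex.values() else "ACE"
    else:
        family = config.family

    full_comps = ("A", "CorD", "E")
    ae_comps = ("A", "E")
    rows: list[LadderRow] = []

    def fit_spec(comps_f, comps_m, sex_equality):
        spec = ModelSpec(family=family,
                         components_by_sex={"F": comps_f, "M": comps_m},
                         sex_equality=sex_equality)
        return fit_biometric(dataset, spec, n_starts=config.n_starts)

    full = fit_spec(full_comps, full_comps, "none")
    rows.append(LadderRow(label=full.spec.label(), fit=full, retained=True))

    drop = fit_spec(ae_comps, ae_comps, "none")
    cmp_drop = lrt(full, drop, alpha=config.alpha)
    rows.append(LadderRow(label=drop.spec.label(), fit=drop,
                          comparison=cmp_drop,
                          retained=cmp_drop.decision == "retain nested"))
    retained = drop if cmp_drop.decision == "retain nested" else full

    if config.per_sex_drops and cmp_drop.decision == "retain base":
        for sex_drop, comps in (("F", (ae_comps, full_comps)),
                                ("M", (full_comps, ae_comps))):
            sub = fit_spec(*comps, "none")
            c = lrt(full, sub, alpha=config.alpha)
            ok = c.decision == "retain nested"
            rows.append(LadderRow(
                label=f"{sub.spec.label()}, dropped for {sex_drop} only",
                fit=sub, comparison=c, retained=False))
            if ok and sub.minus2LL <= retained.minus2LL + 1e-9:
                retained = sub
                rows[-1].retained = True

    comps = retained.spec.components_by_sex
    if comps["F"] == comps["M"]:
        nosex = fit_spec(comps["F"], comps["M"], "full")
        cmp_nosex = lrt(retained, nosex, alpha=config.alpha)
        rows.append(LadderRow(label=nosex.spec.label(), fit=nosex,
                              comparison=cmp_nosex,
                              retained=cmp_nosex.decision == "retain nested"))
        final = nosex if cmp_nosex.decision == "retain nested" else retained

        if config.scalar:
            scalar = fit_spec(comps["F"], comps["M"], "scalar")
            cmp_scalar = lrt(retained, scalar, alpha=config.alpha)
            rows.append(LadderRow(label=scalar.spec.label(), fit=scalar,
                                  comparison=cmp_scalar, retained=False))
            if (cmp_scalar.decision == "retain nested"
                    and cmp_nosex.decision == "retain base"):
                rows[-1].retained = True
                final = scalar
    else:
        final = retained

    for row in rows:
        row.retained = row.fit is final
    return ModelLadder(rows=rows, alpha=config.alpha, family=family,
                       saturated=sat, correlations=corr)


def ladder_table(ladder: ModelLadder) -> list[dict]:
    """Table-style summary rows: ep, -2LL, df, AIC, delta(-2LL), delta df, p."""
    out = []
    for row in ladder.rows:
        f = row.fit
        rec = {
            "model": row.label, "ep": f.n_free, "minus2LL": f.minus2LL,
            "df": f.df, "AIC": f.AIC, "dLL": None, "ddf": None, "p": None,
            "retained": row.retained,
        }
        if row.comparison is not None:
            rec["dLL"] = row.comparison.delta_minus2LL
            rec["ddf"] = row.comparison.delta_df
            rec["p"] = row.comparison.p
        out.append(rec)
    return out
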