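"""End-to-end analysis orchestration and deterministic table rendering.

The canonical outputs are plain-text tables mirroring a twin-study report:
per-sex descriptives, the correlation summary, the model-fitting ladder and
standardized estimates. Rendering is byte-stable for identical inputs.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biometric_model import StandardizedEstimates, profile_ci, standardize
from .model_comparison import LadderConfig, ModelLadder, ladder_table, run_ladder
from .saturated_model import CorrelationSummary
from .synthetic_data import nrt_like_spec, simulate_dataset, spec_to_dict
from .twin_data import GROUPS, TwinDataset, observed_count


def descriptives(dataset: TwinDataset) -> pd.DataFrame:
    """Per-sex, per-trait observed n, mean, SD (n-1), and min-max range.

    SD is reported missing when fewer than two values are observed.
    """
    records = []
    for sex in ("F", "M"):
        rows = dataset.sex == sex
        for t, name in enumerate(dataset.trait_names):
            vals = np.concatenate([dataset.y[rows][:, t],
                                   dataset.y[rows][:, t + 2]])
            vals = vals[~np.isnan(vals)]
            n = len(vals)
            records.append({
                "sex": sex,
                "trait": name,
                "n": n,
                "mean": float(np.mean(vals)) if n else math.nan,
                "sd": float(np.std(vals, ddof=1)) if n >= 2 else math.nan,
                "min": float(np.min(vals)) if n else math.nan,
                "max": float(np.max(vals)) if n else math.nan,
            })
    return pd.DataFrame.from_records(records)


@dataclass
class AnalysisReport:
    descriptives: pd.DataFrame
    correlations: CorrelationSummary
    ladder: ModelLadder
    estimates: StandardizedEstimates
    metadata: dict = field(default_factory=dict)


def _fmt(x, nd: int) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x:.{nd}f}"


def _correlation_lines(corr: CorrelationSummary) -> list[str]:
    lines = ["Phenotypic correlations (per sex)"]
    for sex in ("F", "M"):
        lines.append(f"  {sex}\t{_fmt(corr.r_ph[sex], 3)}")
    lines.append("Twin correlations (trait1, trait2) and cross-twin cross-trait")
    for g in GROUPS:
        r1, r2 = corr.twin_r[g]
        lines.append(f"  {g}\t{_fmt(r1, 3)}\t{_fmt(r2, 3)}"
                     f"\t{_fmt(corr.cross_twin_cross_trait[g], 3)}")
    return lines


def _ladder_lines(ladder: ModelLadder) -> list[str]:
    header = "model\tep\t-2LL\tdf\tAIC\tdLL\tddf\tp\tretained"
    lines = [header]
    for rec in ladder_table(ladder):
        lines.append("\t".join([
            rec["model"], str(rec["ep"]), _fmt(rec["minus2LL"], 1),
            str(rec["df"]), _fmt(rec["AIC"], 1),
            _fmt(rec["dLL"], 1) if rec["dLL"] is not None else "",
            str(rec["ddf"]) if rec["ddf"] is not None else "",
            _fmt(rec["p"], 4) if rec["p"] is not None else "",
            "*" if rec["retained"] else "",
        ]))
    return lines


def _estimate_lines(est: StandardizedEstimates) -> list[str]:
    lines = ["sex\tquantity\ttrait1\ttrait2"]
    for sex in ("F", "M"):
        se = est.by_sex[sex]
        for comp, (s1, s2) in sorted(se.shares.items()):
            lines.append(f"{sex}\tshare {comp}\t{_fmt(s1, 3)}\t{_fmt(s2, 3)}")
        if se.biv_shares is not None:
            for comp, b in sorted(se.biv_shares.items()):
                lines.append(f"{sex}\tbiv {comp}\t{_fmt(b, 3)}\t")
        for comp, r in sorted(se.correlations.items()):
            lines.append(f"{sex}\tr {comp}\t{_fmt(r, 3)}\t")
        lines.append(f"{sex}\tr_ph implied\t{_fmt(se.r_ph_implied, 3)}\t")
    for label, (lo, hi) in sorted(est.ci.items()):
        lines.append(f"CI\t{label}\t{_fmt(lo, 3)}\t{_fmt(hi, 3)}")
    return lines


def render_report(report: AnalysisReport, fmt: str = "text",
                  out_dir: str | Path = ".") -> list[Path]:
    """Write the report tables; returns the file paths.

    ``text`` produces one human-readable file, ``tsv`` one TSV per table.
    Output bytes depend only on the report contents.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt not in ("text", "tsv"):
        raise ValueError(f"unknown format {fmt!r}")

    desc = report.descriptives.copy()
    for col, nd in (("mean", 3), ("sd", 3), ("min", 3), ("max", 3)):
        desc[col] = desc[col].map(lambda v: _fmt(v, nd))

    if fmt == "tsv":
        paths = []
        p = out_dir / "descriptives.tsv"
        desc.to_csv(p, sep="\t", index=False)
        paths.append(p)
        for name, lines in (("correlations", _correlation_lines(report.correlations)),
                            ("ladder", _ladder_lines(report.ladder)),
                            ("estimates", _estimate_lines(report.estimates))):
            p = out_dir / f"{name}.tsv"
            p.write_text("\n".join(lines) + "\n")
            paths.append(p)
        return paths

    sections = [
        "# Descriptives",
        desc.to_string(index=False),
        "",
        "# Correlations (saturated model)",
        *_correlation_lines(report.correlations),
        "",
        f"# Model-fitting ladder (alpha={report.ladder.alpha}, "
        f"family={report.ladder.family})",
        *_ladder_lines(report.ladder),
        "",
        f"# Standardized estimates ({report.ladder.retained_label})",
        *_estimate_lines(report.estimates),
        "",
        "# Metadata",
        json.dumps(report.metadata, sort_keys=True, indent=2, default=str),
    ]
    if not report.ladder.rows:
        sections.insert(3, "NOTICE: empty model ladder; descriptives only.")
    path = out_dir / "report.txt"
    path.write_text("\n".join(sections) + "\n")
    return [path]


def analyze(dataset: TwinDataset, config: LadderConfig | None = None,
            metadata: dict | None = None,
            ci_quantities: list[str] | None = None) -> AnalysisReport:
    """Run descriptives, the model ladder and standardization on a dataset.

    ``ci_quantities`` lists profile-CI labels (see
    :func:`bivtwin.biometric_model.profile_ci`) to evaluate on the retained
    model, e.g. ``["F:share:A:1", "F:corr:A"]``.
    """
    ladder = run_ladder(dataset, config)
    est = standardize(ladder.retained_fit())
    for q in ci_quantities or ():
        iv = profile_ci(ladder.retained_fit(), q)
        est.ci[q] = (iv.lower, iv.upper)
    meta = {
        "n_pairs": dataset.n_pairs,
        "n_observed": observed_count(dataset),
        "retained_model": ladder.retained_label,
        "bivtwin_version": __version__,
    }
    meta.update(metadata or {})
    return AnalysisReport(
        descriptives=descriptives(dataset),
        correlations=ladder.correlations,
        ladder=ladder,
        estimates=est,
        metadata=meta,
    )


def run_demo(seed: int = 2021, config: LadderConfig | None = None,
             n_scale: float = 1.0) -> AnalysisReport:
    """Simulate the packaged demo spec and run the full analysis.

    ``n_scale`` shrinks (or grows) the packaged group sizes, mainly for
    quick smoke runs.
    """
    spec = nrt_like_spec(seed=seed)
    if n_scale != 1.0:
        spec.n_pairs = {g: max(20, int(n * n_scale))
                        for g, n in spec.n_pairs.items()}
    dataset = simulate_dataset(spec)
    cfg_hash = hashlib.sha256(
        json.dumps(spec_to_dict(spec), sort_keys=True).encode()
    ).hexdigest()[:12]
    return analyze(dataset, config,
                   metadata={"seed": seed, "config_hash": cfg_hash,
                             "source": "nrt_like_spec"})
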