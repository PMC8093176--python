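# bivtwin

Bivariate twin modelling for the classical four-group same-sex design
(MZ female, DZ female, MZ male, DZ male). The package fits saturated and
ACE/ADE variance-component models to pair-level data on two continuous
traits by full-information maximum likelihood (FIML), runs the standard
nested-model testing sequence, and reports bivariate heritability and
genetic/environmental correlations with profile-likelihood confidence
intervals.

## What it does

- **`twin_data`** — pair-level data model and wide-CSV I/O (one row per twin
  pair: zygosity, sex, four phenotype values; missing entries allowed).
- **`synthetic_data`** — model-implied 4×4 pair covariances
  (`implied_pair_covariance`) and dataset simulation (`simulate_dataset`),
  including a packaged demo design (`nrt_like_spec`) with ~1200 pairs per
  group, sex mean differences and 5% random missingness.
- **`saturated_model`** — unstructured FIML means/covariances per group,
  descriptive correlations (phenotypic, twin, cross-twin cross-trait) and
  the sex mean-difference likelihood-ratio test.
- **`biometric_model`** — the core ACE/ADE likelihood in the
  variance-component parameterization (component matrices estimated
  directly, possibly indefinite; only each group's implied total covariance
  must be positive definite). Supports per-sex component sets, full sex
  equality, and a scalar sex-limitation mode (female total variance equals
  a per-trait factor k times the male one). Fits use analytic gradients.
  `standardize` produces variance shares, bivariate covariance shares
  (bivariate heritability), rg/rc/rd/re and the model-implied phenotypic
  correlation; `profile_ci` gives likelihood-based intervals.
- **`model_comparison`** — ACE-vs-ADE choice heuristic (MZ vs twice-DZ twin
  correlations), likelihood-ratio tests, AIC, and `run_ladder` for the full
  sequence: full model → drop C/D → no-sex-difference → scalar variant.
  The df convention is `df = observed data points − free parameters` with
  `AIC = −2LL − 2·df`.
- **`report`** / CLI — descriptives, deterministic text/TSV report
  rendering, and an end-to-end demo.

## CLI

```sh
bivtwin simulate --out twins.csv                  # packaged demo design
bivtwin simulate --config myspec.yaml --seed 7 --out twins.csv
bivtwin describe twins.csv --out-dir desc/
bivtwin fit twins.csv --family ACE --drop-cord --out fit.json
bivtwin compare twins.csv --alpha 0.01 --out-dir cmp/
bivtwin report twins.csv --format text --out-dir report/
bivtwin demo --seed 2021 --out-dir demo_output/
```

`simulate` accepts a YAML spec (see `bivtwin.synthetic_data.save_spec` for
the layout). Exit codes are non-zero on non-convergence.

## Library example

```python
import bivtwin as bt

ds = bt.simulate_dataset(bt.nrt_like_spec(seed=1))
ladder = bt.run_ladder(ds)            # saturated → ACE → AE → no-sex-diff → scalar
est = bt.standardize(ladder.retained_fit())
print(est.by_sex["F"].biv_shares)     # bivariate heritability etc.
print(est.by_sex["F"].correlations)   # rg / re
ci = bt.profile_ci(ladder.retained_fit(), "F:share:A:1")
```

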