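# vitdmr

Observational and Mendelian-randomization (MR) analysis of serum
25-hydroxyvitamin D [25(OH)D] against incident dementia, incident stroke
and brain-volume outcomes — including the nonlinear (stratified LACE +
fractional polynomial) MR used to probe threshold effects of vitamin D
status — packaged as a tested, reusable pipeline for epidemiologists and
genetic-epidemiology methodologists.

Cohort studies of vitamin D and neurodegeneration face two linked
problems: confounding (frail, inactive, unwell people have both low
25(OH)D and high dementia risk) and nonlinearity (any causal benefit of
raising 25(OH)D should plateau once sufficiency is reached).  The package
implements the full analytic ladder used to address them:

* **Observational arm** — kinship-weighted linear models (brain volumes,
  log-transformed white-matter hyperintensity) and Cox models (dementia,
  stroke) per 10 nmol/L 25(OH)D, progressive covariate adjustment,
  quadratic nonlinearity tests, categorical analyses with 50–74.9 nmol/L
  as reference, Schoenfeld proportional-hazards diagnostics, and
  likelihood-ratio interaction tests.
* **Genetic instruments** — GWAS summary-statistics harmonization
  (allele alignment, palindromic-variant rules), replication-based
  instrument selection (MAF > 5%, directional consistency), a weighted
  genetic risk score (GRS), instrument-strength diagnostics
  (R², F = R²(n−2)/(1−R²)) and leave-block-out sub-scores.
* **Linear MR** — per-variant Wald ratios β_Y/β_X combined by
  random-effects IVW, MR-Egger, weighted median, weighted mode and
  MR-PRESSO (global pleiotropy test, outlier flags, corrected estimate,
  distortion test), plus the same estimators within strata of
  instrument-free 25(OH)D.
* **Nonlinear MR** — K = 40 equal-size strata of instrument-free exposure
  (the residual of 25(OH)D on the GRS, re-centred to nmol/L); per-stratum
  localized average causal effects LACE_k = β_GY/β_GX estimating the local
  derivative h′(x) of the causal log-odds dose–response; weighted
  fractional-polynomial meta-regression of the LACE profile
  (h(x) = Σ_d θ_d x^{p_d}, powers from {−2, −1, −0.5, 0, 0.5, 1, 2, 3},
  power 0 = ln x); nonlinearity tests; and the reconstructed curve
  OR(x) = exp(h(x) − h(50)) with simulation-based confidence bands.
* **Potential impact fraction** —
  PIF = (Σ RR(x_i) − Σ RR(max(x_i, t))) / Σ RR(x_i): the fraction of
  dementia preventable by raising every exposure below threshold t up to t,
  with a joint individual/coefficient bootstrap CI.
* **Synthetic cohort** — a seeded generator producing the world the
  analysis assumes (35 Hardy–Weinberg instruments explaining 2.8% of
  exposure variance, seasonal and confounded exposure on the nmol/L scale,
  a dementia hazard with a plateau above 50 nmol/L, a confounded but
  causally null stroke outcome, confounder-driven U-shaped brain volumes),
  so every stage is testable without restricted data.  See
  `docs/methods.md` for the stated parameter values and their provenance.

## Worked example

Run the full pipeline on a simulated cohort of 20,000 (about a minute):

```python
from vitdmr.pipeline import PipelineConfig, run_pipeline
from vitdmr.simulate import SimParams

cfg = PipelineConfig(output_dir="demo",
                     simulation=SimParams(n_individuals=20_000),
                     n_bootstrap=200, presso_n_sim=500)
run_pipeline(cfg)
```

(the `vitdmr all --config cfg.yaml --out demo` CLI is equivalent).

This writes, into `demo/`: the variant panel and cohort
(`panel.tsv`, `cohort.tsv.gz`), instrument diagnostics
(`grs_diagnostics.json`), a Table-2-shaped observational summary
(`observational_table2.tsv`, `observational_categorical.tsv`), linear-MR
results (`linear_mr.json`), the per-stratum LACE table and fitted curve
(`stratum_lace.tsv`, `effect_curve.tsv`, `nlmr_model.json`), the impact
fraction (`pif.json`) and a reproducibility log (`run_log.json`).
Numbers printed by that run:

```
grs_diagnostics.json   r2 = 0.0292, F = 594.7  (n = 19,769 after filters)
linear_mr.json         IVW (dementia): -0.0664 log-odds per nmol/L, p = 3.4e-10
                       MR-PRESSO global p = 0.986, 0 outlier variants
nlmr_model.json        selected powers (1, 2); p_fp = 8.6e-08
                       OR(25 vs 50 nmol/L) = 6.35 (95% CI 3.47, 11.61)
pif.json               pif = 0.088 (95% CI 0.001, 0.806)
```

Reading them: the GRS explains ~2.9% of exposure variance at this n
(target 2.8%; a strong instrument, F ≫ 10); no pleiotropy is simulated and
MR-PRESSO finds none; the fractional-polynomial test rejects a linear
dose–response; the odds of dementia at 25 nmol/L are several-fold those at
50 nmol/L under the steep simulated threshold (the generator's
deficient-range slope is anchored to an OR of 0.35 per 10 nmol/L); and the
PIF estimates the share of dementia preventable by raising everyone to
50 nmol/L, with a wide interval at this cohort size.  Re-running with the
same seeds reproduces every artifact byte for byte.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the analytic identity linking instrument
strength to instrument-free stratification: it simulates a cohort of
1,000,000, calibrates the GRS to explain 2.8% of exposure variance,
regresses the exposure on the GRS, and reports the Pearson correlation
between the measured exposure and the residual (√(1 − R²) ≈ 0.986),
rounded to three decimals.
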