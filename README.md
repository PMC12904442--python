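# pancox

Pan-cancer vs single-cancer prognostic survival modeling on synthetic
linked clinico-genomic cohorts.

The package implements an end-to-end, seeded pipeline:

- **`pancox.simulate`** — synthetic cohort generator: K cancer cohorts of
  heterogeneous size under a Weibull proportional-hazards model with
  shared and cancer-specific log-hazard effects, delayed database entry
  (time from first-line therapy to genomic testing) inducing left
  truncation, right censoring, prognostically drifting longitudinal lab
  series with limits of normal, per-(gene, variant-class) panel calls
  with unmeasured entries, a gene-embedding table and a pathway map.
  The hidden true linear predictor is recorded for oracle checks.
- **`pancox.features`** — feature engineering: 11 windowed lab-series
  summaries (mean, median, variance, max, min, approximate entropy,
  last-2 difference and slope, test count, test rate, proportion
  abnormal) normalized to limits of normal over 60- and 720-day windows;
  genomic encodings (binary gene-class indicators, pathway-impact flags,
  embedding averages over affected genes); data-driven screening
  (zero-variance, near-zero-variance dummies < 20 counts, > 30%
  missing); one-hot encoding with majority reference level; z-scoring
  with ±3-z truncation; structured-missingness zero-fill for
  cancer-specific features.  All fitted statistics derive from training
  rows only.
- **`pancox.impute`** — deterministic kNN imputation for genomic blocks
  (optionally augmented with external reference donor rows) and
  chained-equation imputation with predictive-mean matching for clinical
  blocks.
- **`pancox.model`** — lasso-penalized Cox proportional hazards on
  left-truncated, right-censored data: risk sets `{j : entry_j < t <=
  exit_j}`, Breslow ties, IRLS + cyclic coordinate descent (numba-JIT
  kernel) with warm starts along a log-spaced λ path, KKT-certified
  convergence, unpenalized entry-time / cancer-type covariates, optional
  cancer-type strata, 5-fold CV selecting λ by held-out concordance, and
  a Breslow baseline for survival-curve prediction.
- **`pancox.evaluate`** — truncation-aware concordance index, IPCW
  integrated Brier score, median-split low-vs-high hazard ratio with
  per-cohort training-median thresholds, and bias-corrected bootstrap
  percentile confidence intervals.
- **`pancox.experiment`** — the pan-vs-single comparison harness:
  stratified 80/20 split by cancer type; pan-scope models fit once on
  pooled training data with unpenalized cancer-type covariates;
  single-scope models refit per cancer with that cancer's own
  screening/normalization statistics; both scored per cancer.

## CLI

```bash
pancox simulate  --seed 1 --out-dir run/            # write cohort tables (CSV + manifest)
pancox featurize --data-dir run/ --out-dir run/     # raw feature matrix
pancox impute    --data-dir run/ --out-dir run/     # screen + impute + finalize
pancox fit       --data-dir run/ --out-dir run/ --model full
pancox evaluate  --data-dir run/ --out-dir run/ --model full --bootstrap-B 200
pancox compare   --seed 1 --out-dir run/ --models benchmark,full \
                 --bootstrap-B 200 --fast-bootstrap
```

`compare` emits the comparison table (`comparison.csv`) with one row per
(cancer, model, training scope): c-index, IBS and low-vs-high HR with
confidence intervals, selected-feature counts, and sample sizes.
Comparator models: `benchmark` (9 clinical features), `ropro_like`
(benchmark + ~20 lab summaries), `full` (all surviving features).

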