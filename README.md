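# ndr — neural population decoding in Python

A modular pipeline for decoding experimental conditions from neural
population activity: per-site spike-train **raster** tables are converted
into a **binned** firing-rate table, assembled into **pseudo-population**
training/test splits over many resample runs, classified with
cross-validation at every time bin (optionally train-time × test-time,
"temporal cross-decoding"), and reduced to decoding-accuracy metrics that
are saved in a managed, parameter-indexed results log. A synthetic
tuned-neuron generator makes the whole pipeline testable offline with
known ground truth.

## Components

| Stage | Module | What it does |
| --- | --- | --- |
| raster I/O | `ndr.raster` | read/write/validate per-site trial × time CSV tables (`site_info.` / `labels.` / `time.<start>_<end>` columns), spike-event extraction, tick plots |
| binning | `ndr.binning` | sliding-window mean/sum over raw samples → one stacked table with a `siteID` column |
| label info | `ndr.label_info` | per-site label repetition counts; the k-vs-usable-sites trade-off curve |
| datasources | `ndr.datasource` | `ds_basic` (train/test on the same levels) and `ds_generalization` (train on one level set, test on an index-paired set) pseudo-population splits |
| preprocessors | `ndr.preprocess` | train-set-fitted z-scoring and top-k ANOVA-F feature selection |
| classifiers | `ndr.classify` | maximum-correlation, Poisson naive Bayes (spike counts), optional SVM adapter |
| cross-validator | `ndr.crossval` | resample runs × folds × time bins; parallel across runs; bit-reproducible for any worker count |
| metrics | `ndr.metrics` | zero-one accuracy, normalized rank, decision values; TCD matrices; confusion matrices |
| results log | `ndr.results_log` | portable plain-text archives + a `manifest.csv` queryable by name or parameter values |
| synthetic data | `ndr.synthetic` | tuned Bernoulli/Poisson spiking sites with controllable decodability |

## Quick start (CLI)

```bash
# 1. simulate a small tuned population (2 orientations × 25 people)
ndr simulate --out rasters --sites 30 --orientations 2 --people 25 \
    --trials 3 --peak-rate 200 --seed 1

# 2. sanity-check the files and bin at 30 ms width / 10 ms steps
ndr validate-raster rasters
ndr bin --raster-dir rasters --prefix demo --bin-width 30 --sampling-interval 10

# 3. how many sites support k cross-validation splits?
ndr inspect --binned demo_30bins_10sampled.csv \
    --label orient_person_combo --k 3

# 4. decode from a config file and log the result
ndr decode --config run.yaml --seed 1 --out results/ --result-name "left profiles"

# 5. plot and query the log
ndr plot --results-dir results --names "left profiles" --out accuracy.png
ndr log list --results-dir results
ndr log query datasource.num_cv_splits=3 --results-dir results
```

A minimal `run.yaml`:

```yaml
binned: demo_30bins_10sampled.csv
datasource:
  type: basic            # or: generalization (+ train/test_label_levels)
  label: orient_person_combo
  num_cv_splits: 3
  site_ids: auto-k       # all sites with enough repetitions
preprocessors:
  - {type: zscore}
classifier:
  type: max_correlation  # or: poisson_naive_bayes (bin with --aggregate sum)
metrics: [main_results, confusion_matrix]
cross_validator:
  num_resample_runs: 50
  run_TCD: true
seed: 1
```

## Python API

```python
import ndr

spec = (ndr.Pipe("demo_30bins_10sampled.csv")
        .datasource(labels="orient_person_combo", num_cv_splits=3,
                    label_levels=[f"left profile {i}" for i in range(1, 26)])
        .preprocessor({"type": "zscore"})
        .classifier({"type": "max_correlation"})
        .metric("main_results")
        .cross_validator(num_resample_runs=50, seed=1)
        .build())
results = ndr.run_decoding(spec)
ndr.log_save_results(results, "results", result_name="left profiles")
```

Explicit constructors (`ndr.ds_basic`, `ndr.ds_generalization`,
`ndr.cv_standard`) build the identical specification.

## Reproducibility

All sampling flows through counter-based substreams of a single master
seed keyed by (run, site), so a decoding run is bit-identical for any
`num_parallel_workers` and any scheduling order. The results log stores
the seed with every saved analysis.

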