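"""The standard cross-validator: resample runs × folds × time bins.

One decoding run proceeds, for each resample run, as:

1. build that run's pseudo-population :class:`~ndr.datasource.SplitData`;
2. for each cv fold, fit the feature preprocessors on the fold's
   training data only and apply them to training and test data;
3. for each train time bin, train the classifier and evaluate it on
   every test time bin (run_TCD=true) or only the same bin
   (run_TCD=false);
4. hand the full prediction record set to the result metrics, which
   average fold means within each run and then across runs.

Runs are independent and may execute in parallel; all randomness flows
through counter-based substreams of the master seed keyed by run index,
so results are bit-identical for any worker count.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .classify import make_classifier, predict_from_decision_values
from .datasource import DataSourceSpec, make_split
from .errors import ConfigError
from .metrics import (
    MainResults,
    ConfusionMatrixSet,
    RawPredictionSet,
    compute_confusion_matrix_set,
    compute_main_results,
)
from .preprocess import make_preprocessor

__all__ = [
    "CrossValidatorSpec",
    "cv_standard",
    "DecodingResults",
    "run_decoding",
    "pipe_builder",
    "Pipe",
]

VALID_METRICS = ("main_results", "confusion_matrix")


def _default_workers() -> int:
    return max(1, (os.cpu_count() or 2) // 2)


@dataclass
class CrossValidatorSpec:
    """Complete description of a decoding analysis.

    ``preprocessors`` is an ordered list of config mappings (applied
    left-to-right), ``classifier`` a config mapping, and ``metrics`` a
    list drawn from {"main_results", "confusion_matrix"}. With
    ``run_TCD=False`` only train==test time bins are evaluated.
    ``num_parallel_workers`` of None means half the logical processors.
    """

    datasource: DataSourceSpec
    classifier: dict = field(default_factory=lambda: {"type": "max_correlation"})
    preprocessors: list = field(default_factory=list)
    metrics: list = field(default_factory=lambda: ["main_results"])
    num_resample_runs: int = 50
    run_TCD: bool = True
    num_parallel_workers: Optional[int] = None
    seed: int = 0
    keep_raw_predictions: bool = False

    def __post_init__(self):
        if self.num_resample_runs < 1:
            raise ConfigError("num_resample_runs must be >= 1")
        for m in self.metrics:
            if m not in VALID_METRICS:
                raise ConfigError(
                    f"unknown result metric {m!r}; valid: {VALID_METRICS}")
        if not self.metrics:
            raise ConfigError("at least one result metric is required")
        # fail fast on malformed component specs
        make_classifier(dict(self.classifier))
        for p in self.preprocessors:
            make_preprocessor(dict(p))

    def params(self) -> dict:
        """Flattened parameter record with dotted keys."""
        flat = {}
        for key, value in self.datasource.params().items():
            flat[f"datasource.{key}"] = value
        for key, value in dict(self.classifier).items():
            flat[f"classifier.{key}"] = value
        for i, p in enumerate(self.preprocessors):
            for key, value in dict(p).items():
                flat[f"preprocessors.{i}.{key}"] = value
        flat["metrics"] = list(self.metrics)
        flat["cross_validator.num_resample_runs"] = self.num_resample_runs
        flat["cross_validator.run_TCD"] = self.run_TCD
        flat["cross_validator.seed"] = self.seed
        return flat


def cv_standard(datasource: DataSourceSpec, classifier=None,
                feature_preprocessors=None, result_metrics=None,
                num_resample_runs: int = 50, run_TCD: bool = True,
                num_parallel_workers: Optional[int] = None,
                seed: int = 0, **kwargs) -> CrossValidatorSpec:
    """Constructor taking component objects or config mappings."""
    def to_spec(obj, default):
        if obj is None:
            return default
        if isinstance(obj, dict):
            return dict(obj)
        return obj.params()

    classifier = to_spec(classifier, {"type": "max_correlation"})
    preprocessors = [to_spec(p, None) for p in (feature_preprocessors or [])]
    metrics = list(result_metrics) if result_metrics else ["main_results"]
    return CrossValidatorSpec(
        datasource=datasource, classifier=classifier,
        preprocessors=preprocessors, metrics=metrics,
        num_resample_runs=num_resample_runs, run_TCD=run_TCD,
        num_parallel_workers=num_parallel_workers, seed=seed, **kwargs)


@dataclass
class DecodingResults:
    """Aggregated metrics plus the full parameter record of the run."""

    params: dict
    main_results: Optional[MainResults] = None
    confusion_matrices: Optional[ConfusionMatrixSet] = None
    raw_predictions: Optional[RawPredictionSet] = None


def _check_compatibility(spec: CrossValidatorSpec) -> None:
    if spec.classifier.get("type") == "poisson_naive_bayes" and not \
            spec.classifier.get("allow_rounding", False):
        from .binning import load_binned_data
        table = load_binned_data(spec.datasource.binned)
        data = table.data_matrix()
        if not np.allclose(data, np.round(data)):
            raise ConfigError(
                "poisson_naive_bayes needs integer spike counts but the "
                "binned data contains non-integer values; re-bin with "
                "aggregate='sum' (or set classifier.allow_rounding)")


def _run_one(spec: CrossValidatorSpec, run_index: int) -> pd.DataFrame:
    """Execute one resample run and return its prediction records."""
    split = make_split(spec.datasource, run_index)
    k = split.num_cv_splits
    bin_starts = [s for s, _ in split.time_bins]
    n_bins = len(bin_starts)
    classes = split.classes
    # tie-breaking consumes this stream in a fixed (fold, bin, bin) order,
    # so records are reproducible regardless of scheduling
    tie_rng = np.random.default_rng([spec.seed, run_index, 2**20])

    frames = []
    for fold in range(k):
        Xtr_all, ytr = split.fold_train(fold)   # (B, n, S)
        Xte_all, yte = split.fold_test(fold)
        for bi in range(n_bins):
            preprocs = [make_preprocessor(dict(p)) for p in spec.preprocessors]
            Xtr = Xtr_all[bi]
            for p in preprocs:
                p.fit(Xtr, ytr)
                Xtr = p.transform(Xtr)
            clf = make_classifier(dict(spec.classifier))
            clf.fit(Xtr, ytr)
            test_bins = range(n_bins) if spec.run_TCD else [bi]
            for bj in test_bins:
                Xte = Xte_all[bj]
                for p in preprocs:
                    Xte = p.transform(Xte)
                dv = clf.decision_function(Xte)
                predicted, ties = predict_from_decision_values(
                    dv, clf.classes_, tie_rng)
                frame = pd.DataFrame({
                    "run": run_index,
                    "fold": fold,
                    "train_time": bin_starts[bi],
                    "test_time": bin_starts[bj],
                    "actual": yte,
                    "predicted": np.asarray(clf.classes_, dtype=object)[predicted],
                    "tie": ties,
                })
                for ci, cname in enumerate(clf.classes_):
                    frame[f"dv.{cname}"] = dv[:, ci]
                frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def run_decoding(spec: CrossValidatorSpec) -> DecodingResults:
    """Run the full decoding analysis described by ``spec``.

    Validates feasibility up front (datasource sampling requirements,
    classifier/data compatibility), executes the resample runs (in
    parallel across runs when ``num_parallel_workers > 1``), and
    aggregates the requested result metrics. Deterministic for a given
    master seed, independent of worker count.
    """
    _check_compatibility(spec)
    if spec.datasource.seed == 0 and spec.seed != 0:
        spec.datasource.seed = spec.seed
    # fail before any compute if the datasource is infeasible
    make_split(spec.datasource, 0)

    n_runs = spec.num_resample_runs
    workers = (spec.num_parallel_workers if spec.num_parallel_workers
               else _default_workers())
    workers = min(workers, n_runs)

    if workers > 1:
        from joblib import Parallel, delayed
        frames = Parallel(n_jobs=workers)(
            delayed(_run_one)(spec, run) for run in range(n_runs))
    else:
        frames = [_run_one(spec, run) for run in range(n_runs)]

    preds = RawPredictionSet(pd.concat(frames, ignore_index=True))
    results = DecodingResults(params=spec.params())
    if "main_results" in spec.metrics:
        results.main_results = compute_main_results(preds)
    if "confusion_matrix" in spec.metrics:
        results.confusion_matrices = compute_confusion_matrix_set(preds)
    if spec.keep_raw_predictions:
        results.raw_predictions = preds
    return results


_STAGE_ORDER = ("datasource", "preprocessor", "classifier", "metric", "options")


class Pipe:
    """Fluent construction of a :class:`CrossValidatorSpec`.

    Stages must be added in pipeline order — datasource, then zero or
    more preprocessors, then the classifier, then one or more result
    metrics, then optional cross-validator options. The finished spec is
    identical to one built explicitly.
    """

    def __init__(self, binned_path):
        self.binned_path = binned_path
        self._stages = []

    def _add(self, kind: str, obj) -> "Pipe":
        order = {k: i for i, k in enumerate(_STAGE_ORDER)}
        if self._stages:
            last_kind = self._stages[-1][0]
            if order[kind] < order[last_kind]:
                raise ConfigError(
                    f"pipeline stage {kind!r} cannot follow {last_kind!r}; "
                    f"the order is datasource -> preprocessors -> classifier "
                    f"-> metrics -> options")
        if kind in ("datasource", "classifier", "options") and any(
                k == kind for k, _ in self._stages):
            raise ConfigError(f"duplicate pipeline stage {kind!r}")
        self._stages.append((kind, obj))
        return self

    def datasource(self, **kwargs) -> "Pipe":
        from .datasource import ds_basic, ds_generalization
        if "train_label_levels" in kwargs:
            ds = ds_generalization(self.binned_path, **kwargs)
        else:
            ds = ds_basic(self.binned_path, **kwargs)
        return self._add("datasource", ds)

    def preprocessor(self, spec: dict) -> "Pipe":
        make_preprocessor(dict(spec))
        return self._add("preprocessor", dict(spec))

    def classifier(self, spec: dict) -> "Pipe":
        make_classifier(dict(spec))
        return self._add("classifier", dict(spec))

    def metric(self, name: str) -> "Pipe":
        if name not in VALID_METRICS:
            raise ConfigError(f"unknown result metric {name!r}")
        return self._add("metric", name)

    def cross_validator(self, **options) -> "Pipe":
        return self._add("options", options)

    def build(self) -> CrossValidatorSpec:
        kinds = [k for k, _ in self._stages]
        if "datasource" not in kinds:
            raise ConfigError("pipeline is missing a datasource stage")
        if "classifier" not in kinds:
            raise ConfigError("pipeline is missing a classifier stage")
        if "metric" not in kinds:
            raise ConfigError("pipeline is missing a result metric stage")
        ds = next(obj for k, obj in self._stages if k == "datasource")
        preprocessors = [obj for k, obj in self._stages if k == "preprocessor"]
        classifier = next(obj for k, obj in self._stages if k == "classifier")
        metrics = [obj for k, obj in self._stages if k == "metric"]
        options = next((obj for k, obj in self._stages if k == "options"), {})
        return CrossValidatorSpec(
            datasource=ds, classifier=classifier,
            preprocessors=preprocessors, metrics=metrics, **options)

    def run(self) -> DecodingResults:
        return run_decoding(self.build())


def pipe_builder(binned_path, *components) -> CrossValidatorSpec:
    """Build a spec from components supplied in pipeline order.

    Components are recognized by kind: a :class:`DataSourceSpec`,
    preprocessor config mappings (``{"type": "zscore"}``), a classifier
    config mapping, metric names, and a final options mapping for the
    cross-validator (``{"num_resample_runs": ..., ...}``). Out-of-order
    or duplicate stages raise :class:`ConfigError`.
    """
    pipe = Pipe(binned_path)
    for comp in components:
        if isinstance(comp, DataSourceSpec):
            pipe._add("datasource", comp)
        elif isinstance(comp, str):
            pipe.metric(comp)
        elif isinstance(comp, dict) and comp.get("type") in (
                "zscore", "select_k_features"):
            pipe.preprocessor(comp)
        elif isinstance(comp, dict) and comp.get("type") in (
                "max_correlation", "poisson_naive_bayes", "svm"):
            pipe.classifier(comp)
        elif isinstance(comp, dict):
            pipe.cross_validator(**comp)
        else:
            raise ConfigError(f"unrecognized pipeline component: {comp!r}")
    return pipe.build()
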