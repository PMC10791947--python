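import numpy as np
import pandas as pd
import pytest

from ndr.crossval import (
    CrossValidatorSpec,
    Pipe,
    cv_standard,
    pipe_builder,
    run_decoding,
)
from ndr.datasource import ds_basic
from ndr.errors import ConfigError, DataSourceError
from ndr.metrics import compute_main_results


LEVELS = [f"left profile {i}" for i in range(1, 5)]


def small_cv(binned_table, **overrides):
    ds = ds_basic(binned_table, "orient_person_combo", 3,
                  label_levels=LEVELS, seed=9)
    defaults = dict(
        feature_preprocessors=[{"type": "zscore"}],
        result_metrics=["main_results"],
        num_resample_runs=2, run_TCD=False, num_parallel_workers=1, seed=9)
    defaults.update(overrides)
    return cv_standard(ds, **defaults)


class TestRunDecoding:
    def test_grid_arithmetic(self, binned_table):
        n_bins = len(binned_table.time_columns)
        res = run_decoding(small_cv(binned_table, keep_raw_predictions=True))
        pairs = res.raw_predictions.df[
            ["train_time", "test_time"]].drop_duplicates()
        assert len(pairs) == n_bins  # run_TCD=False → diagonal only

        res_tcd = run_decoding(small_cv(binned_table, run_TCD=True,
                                        keep_raw_predictions=True))
        pairs = res_tcd.raw_predictions.df[
            ["train_time", "test_time"]].drop_duplicates()
        assert len(pairs) == n_bins ** 2

    def test_records_per_cell(self, binned_table):
        res = run_decoding(small_cv(binned_table, keep_raw_predictions=True))
        counts = res.raw_predictions.df.groupby(
            ["run", "fold", "train_time", "test_time"]).size()
        # one test pseudo-trial per class per fold
        assert (counts == len(LEVELS)).all()

    def test_worker_count_does_not_change_results(self, binned_table):
        res1 = run_decoding(small_cv(binned_table, num_parallel_workers=1,
                                     num_resample_runs=4))
        res4 = run_decoding(small_cv(binned_table, num_parallel_workers=4,
                                     num_resample_runs=4))
        from ndr.results_log import results_equal
        assert results_equal(res1, res4)

    def test_metrics_match_replayed_records(self, binned_table):
        res = run_decoding(small_cv(binned_table, keep_raw_predictions=True))
        replayed = compute_main_results(res.raw_predictions)
        pd.testing.assert_frame_equal(
            res.main_results.zero_one_accuracy, replayed.zero_one_accuracy)

    def test_infeasible_datasource_fails_before_compute(self, binned_table):
        ds = ds_basic(binned_table, "orient_person_combo", 9,
                      label_levels=LEVELS, seed=0)
        cv = cv_standard(ds, num_resample_runs=1, num_parallel_workers=1)
        with pytest.raises(DataSourceError, match="site"):
            run_decoding(cv)

    def test_poisson_on_mean_binned_data_rejected(self, binned_table):
        cv = small_cv(binned_table,
                      classifier={"type": "poisson_naive_bayes"})
        with pytest.raises(ConfigError, match="integer spike counts"):
            run_decoding(cv)

    def test_poisson_on_sum_binned_data_works(self, binned_counts_table):
        ds = ds_basic(binned_counts_table, "orient_person_combo", 3,
                      label_levels=LEVELS, seed=9)
        cv = cv_standard(ds, classifier={"type": "poisson_naive_bayes"},
                         num_resample_runs=1, run_TCD=False,
                         num_parallel_workers=1, seed=9)
        res = run_decoding(cv)
        assert res.main_results is not None

    def test_confusion_metric_produced(self, binned_table):
        res = run_decoding(small_cv(
            binned_table,
            result_metrics=["main_results", "confusion_matrix"]))
        assert res.confusion_matrices is not None
        n_bins = len(binned_table.time_columns)
        assert len(res.confusion_matrices.matrices) == n_bins

    def test_params_record_complete(self, binned_table):
        res = run_decoding(small_cv(binned_table))
        p = res.params
        assert p["datasource.num_cv_splits"] == 3
        assert p["classifier.type"] == "max_correlation"
        assert p["preprocessors.0.type"] == "zscore"
        assert p["cross_validator.num_resample_runs"] == 2
        assert p["cross_validator.run_TCD"] is False


class TestSpecValidation:
    def test_bad_metric_rejected(self, binned_table):
        ds = ds_basic(binned_table, "orient_person_combo", 3,
                      label_levels=LEVELS)
        with pytest.raises(ConfigError, match="unknown result metric"):
            cv_standard(ds, result_metrics=["bogus"])

    def test_bad_classifier_rejected(self, binned_table):
        ds = ds_basic(binned_table, "orient_person_combo", 3,
                      label_levels=LEVELS)
        with pytest.raises(ConfigError, match="classifier"):
            cv_standard(ds, classifier={"type": "perceptron"})

    def test_zero_runs_rejected(self, binned_table):
        ds = ds_basic(binned_table, "orient_person_combo", 3,
                      label_levels=LEVELS)
        with pytest.raises(ConfigError, match="num_resample_runs"):
            cv_standard(ds, num_resample_runs=0)


class TestPipeBuilder:
    def test_pipe_equals_explicit_construction(self, binned_table):
        explicit = small_cv(binned_table)
        ds = ds_basic(binned_table, "orient_person_combo", 3,
                      label_levels=LEVELS, seed=9)
        piped = pipe_builder(
            binned_table, ds, {"type": "zscore"},
            {"type": "max_correlation"}, "main_results",
            {"num_resample_runs": 2, "run_TCD": False,
             "num_parallel_workers": 1, "seed": 9})
        assert piped.classifier == explicit.classifier
        assert piped.preprocessors == explicit.preprocessors
        assert piped.metrics == explicit.metrics
        assert piped.num_resample_runs == explicit.num_resample_runs
        assert piped.run_TCD == explicit.run_TCD
        assert piped.datasource.params() == explicit.datasource.params()

    def test_missing_datasource_rejected(self, binned_table):
        with pytest.raises(ConfigError, match="datasource"):
            pipe_builder(binned_table, {"type": "max_correlation"},
                         "main_results")

    def test_out_of_order_rejected(self, binned_table):
        ds = ds_basic(binned_table, "orient_person_combo", 3,
                      label_levels=LEVELS)
        with pytest.raises(ConfigError, match="cannot follow"):
            pipe_builder(binned_table, ds, {"type": "max_correlation"},
                         {"type": "zscore"}, "main_results")

    def test_duplicate_classifier_rejected(self, binned_table):
        ds = ds_basic(binned_table, "orient_person_combo", 3,
                      label_levels=LEVELS)
        with pytest.raises(ConfigError, match="duplicate"):
            pipe_builder(binned_table, ds, {"type": "max_correlation"},
                         {"type": "max_correlation"}, "main_results")

    def test_fluent_interface_runs_end_to_end(self, binned_table, tmp_path):
        from ndr.results_log import (log_load_results_from_result_name,
                                     log_save_results, results_equal)
        spec = (Pipe(binned_table)
                .datasource(labels="orient_person_combo", num_cv_splits=3,
                            label_levels=LEVELS, seed=9)
                .preprocessor({"type": "zscore"})
                .classifier({"type": "max_correlation"})
                .metric("main_results")
                .cross_validator(num_resample_runs=1, run_TCD=False,
                                 num_parallel_workers=1, seed=9)
                .build())
        results = run_decoding(spec)
        log_save_results(results, tmp_path / "results", result_name="piped")
        loaded = log_load_results_from_result_name("piped",
                                                   tmp_path / "results")
        assert results_equal(results, loaded)


class TestStatisticalProperties:
    def test_ceiling_on_strong_low_noise_data(self, tmp_path):
        from ndr.binning import BinningConfig, create_binned_data, \
            load_binned_data
        from ndr.synthetic import SyntheticDesign, generate_raster_dir

        design = SyntheticDesign(
            n_orientations=1, n_people=5, n_sites=20,
            trials_per_stimulus_per_site=3, trial_length_ms=150,
            latency_ms=50, stimulus_on_ms=100, baseline_rate_hz=1.0,
            peak_rate_hz=300.0, person_tuning_width=0.8, seed=33)
        raster_dir = tmp_path / "rasters"
        generate_raster_dir(design, raster_dir)
        path = create_binned_data(raster_dir, str(tmp_path / "S"),
                                  BinningConfig(50, 50))
        ds = ds_basic(load_binned_data(path), "person", 3, seed=33)
        cv = cv_standard(ds, feature_preprocessors=[{"type": "zscore"}],
                         num_resample_runs=3, run_TCD=False,
                         num_parallel_workers=1, seed=33)
        res = run_decoding(cv)
        acc = res.main_results.zero_one_accuracy
        post = [t for t in acc.index if t >= design.latency_ms]
        assert min(acc.at[t, t] for t in post) >= 0.95
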