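import numpy as np
import pandas as pd
import pytest

from ndr.errors import MetricError
from ndr.metrics import (
    ConfusionMatrixSet,
    RawPredictionSet,
    compute_confusion_matrix,
    compute_confusion_matrix_set,
    compute_main_results,
    results_to_plot_tables,
)


def make_predictions(records):
    """records: list of dicts with run, fold, train_time, test_time,
    actual, predicted, and dv mapping."""
    classes = sorted({c for r in records for c in r["dv"]})
    rows = []
    for r in records:
        row = {k: r[k] for k in ("run", "fold", "train_time", "test_time",
                                 "actual", "predicted")}
        row["tie"] = r.get("tie", False)
        for c in classes:
            row[f"dv.{c}"] = r["dv"][c]
        rows.append(row)
    return RawPredictionSet(pd.DataFrame(rows))


def random_prediction_set(rng, n_classes=4, n_runs=3, n_folds=2,
                          times=(0, 10)):
    classes = [f"c{i}" for i in range(n_classes)]
    records = []
    for run in range(n_runs):
        for fold in range(n_folds):
            for t1 in times:
                for t2 in times:
                    for actual in classes:
                        dv = {c: float(rng.normal()) for c in classes}
                        predicted = max(dv, key=dv.get)
                        records.append(dict(
                            run=run, fold=fold, train_time=t1, test_time=t2,
                            actual=actual, predicted=predicted, dv=dv))
    return make_predictions(records)


class TestNormalizedRank:
    @pytest.mark.parametrize("rank,expected", [(1, 1.0), (13, 0.5), (25, 0.0)])
    def test_endpoints_and_midpoint_c25(self, rank, expected):
        classes = [f"c{i:02d}" for i in range(25)]
        # actual class c00 gets the rank-th largest decision value
        dv = {c: float(-i) for i, c in enumerate(classes)}
        actual_dv = -(rank - 1)
        dv["c00"], dv[classes[rank - 1]] = actual_dv, dv["c00"]
        preds = make_predictions([dict(
            run=0, fold=0, train_time=0, test_time=0, actual="c00",
            predicted=max(dv, key=dv.get), dv=dv)])
        results = compute_main_results(preds)
        assert results.normalized_rank.iat[0, 0] == pytest.approx(expected)

    def test_random_decision_values_average_half(self, rng):
        preds = random_prediction_set(rng, n_classes=5, n_runs=10, n_folds=5,
                                      times=(0,))
        results = compute_main_results(preds)
        n_records = 10 * 5 * 5
        se = np.sqrt(1 / 12 / n_records)  # normalized rank ~ U{0..1}
        assert abs(results.normalized_rank.iat[0, 0] - 0.5) < 4 * se


class TestComputeMainResults:
    def test_all_correct_gives_accuracy_one(self):
        records = [dict(run=0, fold=0, train_time=t, test_time=t,
                        actual=c, predicted=c,
                        dv={"a": 1.0 if c == "a" else 0.0,
                            "b": 1.0 if c == "b" else 0.0})
                   for t in (0, 10) for c in ("a", "b")]
        results = compute_main_results(make_predictions(records))
        diag = results.diagonal_series()
        assert (diag["zero_one_accuracy"] == 1.0).all()

    def test_matches_independent_record_replay(self, rng):
        preds = random_prediction_set(rng)
        results = compute_main_results(preds)
        # oracle: replay the stored records with plain loops/dicts
        classes = preds.classes
        C = len(classes)
        cells = {}
        for _, row in preds.df.iterrows():
            key = (row["run"], row["fold"], row["train_time"],
                   row["test_time"])
            dvs = {c: row[f"dv.{c}"] for c in classes}
            correct = float(row["predicted"] == row["actual"])
            worse = sum(1 for c in classes if dvs[c] < dvs[row["actual"]])
            equal = sum(1 for c in classes if dvs[c] == dvs[row["actual"]])
            r = C - worse - (equal - 1) / 2  # average rank, 1 = best
            cells.setdefault(key, []).append(
                (correct, (C - r) / (C - 1), dvs[row["actual"]]))
        # fold means -> run means -> grand mean
        grand = {}
        for (run, fold, t1, t2), vals in cells.items():
            grand.setdefault((t1, t2), {}).setdefault(run, []).append(
                np.mean(vals, axis=0))
        for (t1, t2), by_run in grand.items():
            run_means = [np.mean(v, axis=0) for v in by_run.values()]
            acc, rank, dv = np.mean(run_means, axis=0)
            assert results.zero_one_accuracy.at[t1, t2] == pytest.approx(acc)
            assert results.normalized_rank.at[t1, t2] == pytest.approx(rank)
            assert results.decision_values.at[t1, t2] == pytest.approx(dv)

    def test_single_class_rejected(self):
        preds = make_predictions([dict(run=0, fold=0, train_time=0,
                                       test_time=0, actual="a",
                                       predicted="a", dv={"a": 1.0})])
        with pytest.raises(MetricError, match="2 classes"):
            compute_main_results(preds)

    def test_diagonal_only_off_diagonal_nan(self):
        records = [dict(run=0, fold=0, train_time=t, test_time=t, actual="a",
                        predicted="b", dv={"a": 0.0, "b": 1.0})
                   for t in (0, 10)]
        results = compute_main_results(make_predictions(records))
        assert np.isnan(results.zero_one_accuracy.at[0, 10])


class TestConfusionMatrix:
    def test_perfect_classifier_is_diagonal(self):
        records = [dict(run=r, fold=0, train_time=0, test_time=0,
                        actual=c, predicted=c, dv={"a": 0.0, "b": 0.0})
                   for r in range(3) for c in ("a", "b")]
        cm = compute_confusion_matrix(make_predictions(records), 0)
        assert cm.counts.at["a", "a"] == 3 and cm.counts.at["b", "b"] == 3
        assert cm.counts.at["a", "b"] == 0 and cm.counts.at["b", "a"] == 0

    def test_hand_tally_eight_records(self):
        # 8 hand-enumerable records: a→a ×3, a→b ×1, b→b ×2, b→a ×2
        pairs = [("a", "a")] * 3 + [("a", "b")] + [("b", "b")] * 2 + \
            [("b", "a")] * 2
        records = [dict(run=0, fold=i % 2, train_time=5, test_time=5,
                        actual=act, predicted=pred, dv={"a": 0.0, "b": 0.0})
                   for i, (act, pred) in enumerate(pairs)]
        cm = compute_confusion_matrix(make_predictions(records), 5)
        assert cm.counts.at["a", "a"] == 3
        assert cm.counts.at["a", "b"] == 1
        assert cm.counts.at["b", "b"] == 2
        assert cm.counts.at["b", "a"] == 2
        assert cm.accuracy == pytest.approx(5 / 8)

    def test_diagonal_fraction_equals_zero_one_accuracy(self, rng):
        preds = random_prediction_set(rng, n_runs=2, n_folds=3)
        results = compute_main_results(preds)
        for t in preds.train_times:
            cm = compute_confusion_matrix(preds, t)
            # balanced folds → pooled fraction == mean of fold means
            assert cm.accuracy == pytest.approx(
                results.zero_one_accuracy.at[t, t])

    def test_normalized_rows_sum_to_one(self, rng):
        preds = random_prediction_set(rng)
        cm = compute_confusion_matrix(preds, 0)
        sums = cm.normalized().sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_unpopulated_bin_error_lists_available(self, rng):
        preds = random_prediction_set(rng)
        with pytest.raises(MetricError, match="available train times"):
            compute_confusion_matrix(preds, 999)


class TestPlotTables:
    def test_line_view_single_bin(self, rng):
        preds = random_prediction_set(rng, times=(0,))
        results = compute_main_results(preds)
        table = results_to_plot_tables(results, "line")
        assert len(table) == 1  # one bin × one metric
        table_all = results_to_plot_tables(results, "line",
                                           results_to_show="all")
        assert len(table_all) == 3

    def test_chance_reference_is_one_over_c(self, rng):
        preds = random_prediction_set(rng, n_classes=25, n_runs=1, n_folds=1,
                                      times=(0,))
        results = compute_main_results(preds)
        assert 1.0 / results.num_classes == pytest.approx(0.04)

    def test_tcd_view_requires_full_grid(self):
        records = [dict(run=0, fold=0, train_time=t, test_time=t, actual="a",
                        predicted="a", dv={"a": 1.0, "b": 0.0})
                   for t in (0, 10)]
        results = compute_main_results(make_predictions(records))
        with pytest.raises(MetricError, match="run_TCD"):
            results_to_plot_tables(results, "TCD")

    def test_tcd_view_long_form(self, rng):
        preds = random_prediction_set(rng, times=(0, 10, 20))
        results = compute_main_results(preds)
        table = results_to_plot_tables(results, "TCD")
        assert len(table) == 9
        assert {"train_time", "test_time", "accuracy"} <= set(table.columns)

    def test_nearest_bin_selection(self, rng):
        preds = random_prediction_set(rng, times=(196, 206))
        cms = compute_confusion_matrix_set(preds)
        # documented rule: first bin starting at or after the request
        assert cms.nearest(200).train_time == 206
        assert cms.nearest(196).train_time == 196
        assert cms.nearest(999).train_time == 206  # past the end: last bin
        table = results_to_plot_tables(cms, "matrix", train_time=203)
        assert (table["train_time"] == 206).all()

    def test_unknown_view_rejected(self, rng):
        preds = random_prediction_set(rng, times=(0,))
        results = compute_main_results(preds)
        with pytest.raises(MetricError, match="unknown view"):
            results_to_plot_tables(results, "pie")


class TestChanceProperties:
    def test_uniform_random_predictions_hit_one_over_c(self, rng):
        C = 4
        classes = [f"c{i}" for i in range(C)]
        records = []
        for i in range(2500):
            dv = {c: float(rng.normal()) for c in classes}
            records.append(dict(
                run=0, fold=0, train_time=0, test_time=0,
                actual=classes[rng.integers(C)],
                predicted=max(dv, key=dv.get), dv=dv))
        results = compute_main_results(make_predictions(records))
        se = np.sqrt(0.25 * 0.75 / 2500)
        assert abs(results.zero_one_accuracy.iat[0, 0] - 1 / C) < 3.5 * se
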