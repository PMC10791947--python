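"""Decoding-accuracy result metrics.

Raw classifier predictions, keyed by (resample run, cv fold, train time
bin, test time bin), are reduced to three headline measures:

* zero-one accuracy — fraction of test records whose predicted class
  equals the actual class;
* normalized rank — per record, ``(C - r) / (C - 1)`` where r is the
  rank of the actual class's decision value (1 = highest, ties get the
  average rank); 1 is best, 0 is worst, 0.5 is chance;
* decision values — the mean decision value assigned to the actual class.

Aggregation is fold-mean within each run, then mean across runs (the two
orders coincide for balanced folds); per-run values are retained for
dispersion estimates. Confusion matrices pool raw counts over runs and
folds, so their diagonal fraction equals the zero-one accuracy exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import MetricError

__all__ = [
    "RawPredictionSet",
    "MainResults",
    "ConfusionMatrix",
    "ConfusionMatrixSet",
    "compute_main_results",
    "compute_confusion_matrix",
    "compute_confusion_matrix_set",
    "results_to_plot_tables",
    "plot_main_results",
]

_KEY_COLS = ["run", "fold", "train_time", "test_time"]
_DV_PREFIX = "dv."


class RawPredictionSet:
    """Flat table of prediction records.

    Columns: ``run, fold, train_time, test_time, actual, predicted,
    tie`` plus one ``dv.<class>`` column per training class. Time keys
    are bin start times in ms.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in _KEY_COLS + ["actual", "predicted"]
                   if c not in df.columns]
        if missing:
            raise MetricError(f"prediction set is missing columns {missing}")
        self.df = df.reset_index(drop=True)

    @property
    def classes(self) -> list:
        return [c[len(_DV_PREFIX):] for c in self.df.columns
                if c.startswith(_DV_PREFIX)]

    @property
    def dv_columns(self) -> list:
        return [c for c in self.df.columns if c.startswith(_DV_PREFIX)]

    @property
    def train_times(self) -> list:
        return sorted(self.df["train_time"].unique().tolist())

    @property
    def test_times(self) -> list:
        return sorted(self.df["test_time"].unique().tolist())

    @property
    def is_full_grid(self) -> bool:
        pairs = self.df[["train_time", "test_time"]].drop_duplicates()
        return len(pairs) == len(self.train_times) * len(self.test_times)


@dataclass
class MainResults:
    """Aggregated accuracy / rank / decision-value matrices.

    The three pivot frames are indexed by train time (rows) × test time
    (columns); cells for (train, test) pairs that were never evaluated
    (run_TCD=false off-diagonals) hold NaN. ``per_run`` keeps the
    run-level values that the grand means were taken over.
    """

    num_classes: int
    zero_one_accuracy: pd.DataFrame
    normalized_rank: pd.DataFrame
    decision_values: pd.DataFrame
    per_run: pd.DataFrame  # run, train_time, test_time, accuracy, rank, dv

    def diagonal_series(self) -> pd.DataFrame:
        """Long table of the train==test diagonal for line plots."""
        rows = []
        for t in self.zero_one_accuracy.index:
            if t in self.zero_one_accuracy.columns:
                rows.append({
                    "test_time": t,
                    "zero_one_accuracy": self.zero_one_accuracy.at[t, t],
                    "normalized_rank": self.normalized_rank.at[t, t],
                    "decision_values": self.decision_values.at[t, t],
                })
        return pd.DataFrame(rows)


def _per_record_metrics(preds: RawPredictionSet):
    df = preds.df
    classes = preds.classes
    C = len(classes)
    if C < 2:
        raise MetricError(f"need >= 2 classes, got {C}")
    dv = df[preds.dv_columns].to_numpy(dtype=float)
    actual = df["actual"].to_numpy()
    class_pos = {c: i for i, c in enumerate(classes)}
    actual_idx = np.array([class_pos[a] for a in actual])

    correct = (df["predicted"].to_numpy() == actual).astype(float)
    # rank 1 = highest decision value; ties share the average rank
    ranks = rankdata(-dv, axis=1, method="average")
    r = ranks[np.arange(len(df)), actual_idx]
    norm_rank = (C - r) / (C - 1)
    actual_dv = dv[np.arange(len(df)), actual_idx]
    return correct, norm_rank, actual_dv, C


def compute_main_results(preds: RawPredictionSet) -> MainResults:
    """Reduce raw predictions to the three decoding-accuracy measures."""
    correct, norm_rank, actual_dv, C = _per_record_metrics(preds)
    work = preds.df[_KEY_COLS].copy()
    work["accuracy"] = correct
    work["rank"] = norm_rank
    work["dv"] = actual_dv

    fold_means = work.groupby(_KEY_COLS, sort=True).mean().reset_index()
    per_run = (fold_means
               .groupby(["run", "train_time", "test_time"], sort=True)
               [["accuracy", "rank", "dv"]].mean().reset_index())
    grand = (per_run.groupby(["train_time", "test_time"], sort=True)
             [["accuracy", "rank", "dv"]].mean().reset_index())

    def pivot(col):
        return grand.pivot(index="train_time", columns="test_time",
                           values=col).sort_index(axis=0).sort_index(axis=1)

    return MainResults(
        num_classes=C,
        zero_one_accuracy=pivot("accuracy"),
        normalized_rank=pivot("rank"),
        decision_values=pivot("dv"),
        per_run=per_run)


@dataclass
class ConfusionMatrix:
    """C×C prediction counts at one (train time, test time) cell.

    Rows are the actual class, columns the predicted class, pooled over
    runs and folds. ``normalized()`` divides each nonempty row by its sum.
    """

    train_time: int
    test_time: int
    counts: pd.DataFrame

    def normalized(self) -> pd.DataFrame:
        sums = self.counts.sum(axis=1)
        out = self.counts.div(sums.where(sums > 0, 1), axis=0)
        return out

    @property
    def accuracy(self) -> float:
        total = self.counts.to_numpy().sum()
        return float(np.diag(self.counts.to_numpy()).sum() / total)


@dataclass
class ConfusionMatrixSet:
    """Confusion matrices keyed by train time (train==test by default)."""

    matrices: dict = field(default_factory=dict)

    @property
    def train_times(self) -> list:
        return sorted(self.matrices)

    def nearest(self, requested_time: float) -> ConfusionMatrix:
        """Matrix at the first bin starting at or after the request.

        A request of "around 200 ms" with bins starting ...196, 206...
        resolves to the bin starting at 206 (the first one whose window
        begins after the requested time). Requests beyond the last bin
        fall back to the last bin.
        """
        if not self.matrices:
            raise MetricError("no confusion matrices available")
        at_or_after = [t for t in self.train_times if t >= requested_time]
        best = at_or_after[0] if at_or_after else self.train_times[-1]
        return self.matrices[best]


def compute_confusion_matrix(
    preds: RawPredictionSet, train_time: int,
    test_time: Optional[int] = None,
) -> ConfusionMatrix:
    """Pool prediction counts at one (train, test) cell (test defaults
    to the train time)."""
    if test_time is None:
        test_time = train_time
    classes = preds.classes
    df = preds.df
    sub = df[(df["train_time"] == train_time) & (df["test_time"] == test_time)]
    if len(sub) == 0:
        raise MetricError(
            f"no predictions at train_time={train_time}, "
            f"test_time={test_time}; available train times: "
            f"{preds.train_times}")
    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    tally = sub.groupby(["actual", "predicted"]).size()
    for (a, p), n in tally.items():
        counts.at[a, p] = int(n)
    return ConfusionMatrix(train_time=int(train_time),
                           test_time=int(test_time), counts=counts)


def compute_confusion_matrix_set(preds: RawPredictionSet) -> ConfusionMatrixSet:
    """Confusion matrix at train==test for every populated train time."""
    out = {}
    for t in preds.train_times:
        out[int(t)] = compute_confusion_matrix(preds, t)
    return ConfusionMatrixSet(matrices=out)


def results_to_plot_tables(
    results: Union[MainResults, ConfusionMatrixSet],
    view: str,
    results_to_show: str = "accuracy",
    train_time: Optional[float] = None,
    out_path=None,
):
    """Tidy table (and optional figure) for one view of the results.

    * ``line`` — diagonal (train==test) series vs test time; one row per
      (test_time, metric). ``results_to_show`` is ``"accuracy"`` or
      ``"all"`` (adds normalized rank and decision values).
    * ``TCD`` — full train×test accuracy grid in long form; requires
      results computed with run_TCD=true.
    * ``matrix`` — one confusion matrix in long form, selected as the
      bin whose start time is nearest ``train_time``.

    Time axis labels use bin start times.
    """
    if view == "line":
        if not isinstance(results, MainResults):
            raise MetricError("line view needs MainResults")
        diag = results.diagonal_series()
        metrics = (["zero_one_accuracy"] if results_to_show == "accuracy"
                   else ["zero_one_accuracy", "normalized_rank",
                         "decision_values"])
        table = diag.melt(id_vars="test_time", value_vars=metrics,
                          var_name="metric", value_name="value")
        if out_path is not None:
            _plot_line(table, 1.0 / results.num_classes, out_path)
        return table

    if view == "TCD":
        if not isinstance(results, MainResults):
            raise MetricError("TCD view needs MainResults")
        acc = results.zero_one_accuracy
        long = acc.reset_index().melt(
            id_vars="train_time", var_name="test_time", value_name="accuracy")
        if long["accuracy"].isna().any():
            raise MetricError(
                "TCD view requires a full train×test grid; these results "
                "were computed with run_TCD=false (diagonal only)")
        if out_path is not None:
            _plot_tcd(acc, out_path)
        return long

    if view == "matrix":
        if not isinstance(results, ConfusionMatrixSet):
            raise MetricError("matrix view needs a ConfusionMatrixSet")
        if train_time is None:
            raise MetricError("matrix view needs a train_time")
        cm = results.nearest(train_time)
        norm = cm.normalized()
        long = (cm.counts.rename_axis("actual").reset_index()
                .melt(id_vars="actual", var_name="predicted",
                      value_name="count"))
        long["proportion"] = (
            norm.rename_axis("actual").reset_index()
            .melt(id_vars="actual", var_name="predicted",
                  value_name="p")["p"])
        long.insert(0, "train_time", cm.train_time)
        if out_path is not None:
            _plot_confusion(cm, out_path)
        return long

    raise MetricError(f"unknown view {view!r}; use line, TCD, or matrix")


def plot_main_results(results_dir, result_names: list, out_path=None):
    """Overlay the diagonal accuracy series of several saved results.

    Loads each named result from the results log and returns a tidy
    comparison table (result_name, test_time, zero_one_accuracy);
    optionally renders an overlay line plot with one series per name.
    """
    from .results_log import log_load_results_from_result_name

    frames = []
    for name in result_names:
        res = log_load_results_from_result_name(name, results_dir)
        if res.main_results is None:
            raise MetricError(
                f"result {name!r} was saved without main results")
        diag = res.main_results.diagonal_series()[
            ["test_time", "zero_one_accuracy"]].copy()
        diag.insert(0, "result_name", name)
        frames.append(diag)
    table = pd.concat(frames, ignore_index=True)

    if out_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        for name, grp in table.groupby("result_name", sort=False):
            ax.plot(grp["test_time"], grp["zero_one_accuracy"], label=name)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("zero-one accuracy")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return table


def _plot_line(table: pd.DataFrame, chance: float, out_path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for metric, grp in table.groupby("metric", sort=False):
        ax.plot(grp["test_time"], grp["value"], label=metric)
    ax.axhline(chance, color="gray", ls=":", label=f"chance = {chance:.3g}")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("value")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def _plot_tcd(acc: pd.DataFrame, out_path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(acc.to_numpy(), origin="lower", aspect="auto",
                   extent=(min(acc.columns), max(acc.columns),
                           min(acc.index), max(acc.index)))
    fig.colorbar(im, ax=ax, label="zero-one accuracy")
    ax.set_xlabel("test time (ms)")
    ax.set_ylabel("train time (ms)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def _plot_confusion(cm: ConfusionMatrix, out_path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    norm = cm.normalized()
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(norm.to_numpy(), aspect="auto")
    fig.colorbar(im, ax=ax, label="proportion")
    ax.set_xlabel("predicted class")
    ax.set_ylabel("actual class")
    ax.set_title(f"train time {cm.train_time} ms")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
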