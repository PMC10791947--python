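"""Raster-format data: one recording site's trials at native temporal resolution.

A raster table has one row per experimental trial. Every column name must
carry exactly one of three prefixes:

* ``site_info.<name>`` — metadata that is constant across all trials of the
  site (e.g. subject, brain region);
* ``labels.<name>`` — the experimental condition present on each trial;
* ``time.<start>_<end>`` — activity recorded in the half-open window
  ``[start, end)`` milliseconds relative to the trial's alignment event.

For spiking data at millisecond resolution the ``time.`` values are 0/1
spike indicators and consecutive columns are contiguous
(``time.1_2, time.2_3, ...``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .errors import RasterFormatError, RasterValidationError

__all__ = [
    "RasterTable",
    "ValidationIssue",
    "ValidationReport",
    "read_raster_data",
    "write_raster_data",
    "validate_raster",
    "raster_event_table",
    "plot_raster",
]

_TIME_RE = re.compile(r"^time\.(-?\d+)_(-?\d+)$")
_SITE_INFO_PREFIX = "site_info."
_LABELS_PREFIX = "labels."
_TIME_PREFIX = "time."


def _parse_time_column(name: str) -> tuple[int, int]:
    m = _TIME_RE.match(name)
    if m is None:
        raise RasterFormatError(
            f"column {name!r} starts with 'time.' but does not match "
            f"'time.<start>_<end>' with integer start/end"
        )
    return int(m.group(1)), int(m.group(2))


def time_column_name(start: int, end: int) -> str:
    """Render a ``time.`` column name for the half-open window [start, end)."""
    return f"time.{start}_{end}"


@dataclass
class RasterTable:
    """One site's trials × (site_info / labels / time) data.

    Attributes
    ----------
    site_info
        Mapping from name (without prefix) to the site-constant value.
    labels
        Per-trial categorical values, one column per label (no prefix).
    time_columns
        Ordered ``(start_ms, end_ms)`` half-open windows.
    data
        ``(n_trials, n_windows)`` array of activity values.
    """

    site_info: dict = field(default_factory=dict)
    labels: pd.DataFrame = field(default_factory=pd.DataFrame)
    time_columns: list = field(default_factory=list)
    data: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def start_time(self) -> int:
        return self.time_columns[0][0]

    @property
    def end_time(self) -> int:
        return self.time_columns[-1][1]

    def to_dataframe(self) -> pd.DataFrame:
        """Assemble the full prefixed table (site_info, labels, time order)."""
        n = self.n_trials
        cols = {}
        for name, value in self.site_info.items():
            cols[_SITE_INFO_PREFIX + name] = np.repeat(value, n)
        for name in self.labels.columns:
            cols[_LABELS_PREFIX + name] = self.labels[name].to_numpy()
        df = pd.DataFrame(cols, index=pd.RangeIndex(n))
        time_names = [time_column_name(s, e) for s, e in self.time_columns]
        time_df = pd.DataFrame(self.data, columns=time_names, index=df.index)
        return pd.concat([df, time_df], axis=1)

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, RasterTable):
            return NotImplemented
        return (
            self.site_info == other.site_info
            and self.time_columns == other.time_columns
            and self.labels.equals(other.labels)
            and np.array_equal(self.data, other.data)
        )


@dataclass
class ValidationIssue:
    severity: str  # "error" | "warning"
    column: str
    message: str


@dataclass
class ValidationReport:
    issues: list

    @property
    def ok(self) -> bool:
        return not any(issue.severity == "error" for issue in self.issues)

    def __str__(self) -> str:
        if not self.issues:
            return "OK (no issues)"
        lines = [f"[{i.severity}] {i.column}: {i.message}" for i in self.issues]
        return "\n".join(lines)


def _partition_columns(columns: Iterable[str]) -> tuple[list, list, list]:
    site_info_cols, label_cols, time_cols = [], [], []
    for col in columns:
        if col.startswith(_SITE_INFO_PREFIX):
            site_info_cols.append(col)
        elif col.startswith(_LABELS_PREFIX):
            label_cols.append(col)
        elif col.startswith(_TIME_PREFIX):
            time_cols.append(col)
        else:
            raise RasterFormatError(
                f"column {col!r} does not start with one of the required "
                f"prefixes 'site_info.', 'labels.', 'time.'"
            )
    return site_info_cols, label_cols, time_cols


def read_raster_data(path: Union[str, Path]) -> RasterTable:
    """Load a raster-format CSV file for one recording site.

    Columns are partitioned by prefix, ``time.`` columns are sorted by
    window start, and trial order is preserved from the file. Raises
    :class:`RasterFormatError` for grammar violations and
    :class:`RasterValidationError` if a ``site_info.`` column is not
    constant across trials.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.shape[1] == 0 or any(col.startswith("Unnamed") for col in df.columns):
        bad = [c for c in df.columns if c.startswith("Unnamed")]
        raise RasterFormatError(
            f"{path.name}: missing or garbled header (offending column(s): {bad})"
        )
    return raster_from_dataframe(df, source=path.name)


def raster_from_dataframe(df: pd.DataFrame, source: str = "<dataframe>") -> RasterTable:
    """Build a :class:`RasterTable` from a prefixed dataframe."""
    site_info_cols, label_cols, time_cols = _partition_columns(df.columns)
    if len(df) < 1:
        raise RasterValidationError(f"{source}: raster has no trials")

    site_info = {}
    for col in site_info_cols:
        values = df[col].to_numpy()
        if len(pd.unique(values)) != 1:
            raise RasterValidationError(
                f"{source}: site_info column {col!r} is not constant across trials"
            )
        site_info[col[len(_SITE_INFO_PREFIX):]] = values[0]

    labels = df[label_cols].copy()
    labels.columns = [c[len(_LABELS_PREFIX):] for c in label_cols]
    labels.index = pd.RangeIndex(len(labels))

    windows = [_parse_time_column(c) for c in time_cols]
    order = np.argsort([w[0] for w in windows], kind="stable")
    time_columns = [windows[i] for i in order]
    data = df[[time_cols[i] for i in order]].to_numpy()
    if np.issubdtype(data.dtype, np.number):
        if np.isnan(data).any():
            raise RasterValidationError(f"{source}: time columns contain missing values")
    else:
        raise RasterFormatError(f"{source}: time columns contain non-numeric values")

    return RasterTable(site_info=site_info, labels=labels,
                       time_columns=time_columns, data=data)


def write_raster_data(raster: RasterTable, path: Union[str, Path]) -> Path:
    """Write a raster table as CSV; inverse of :func:`read_raster_data`."""
    path = Path(path)
    df = raster.to_dataframe()
    # integer spike indicators round-trip exactly when written as ints
    if np.issubdtype(raster.data.dtype, np.number) and np.all(
        raster.data == np.round(raster.data)
    ):
        for s, e in raster.time_columns:
            df[time_column_name(s, e)] = df[time_column_name(s, e)].astype(int)
    df.to_csv(path, index=False)
    return path


def validate_raster(obj: Union[RasterTable, pd.DataFrame]) -> ValidationReport:
    """Check raster-format invariants and report every violation found.

    Accepts either a parsed :class:`RasterTable` or a raw prefixed
    dataframe (useful for inspecting files that fail to parse cleanly).
    All problems are collected into the report; nothing is raised.
    """
    issues: list[ValidationIssue] = []

    if isinstance(obj, pd.DataFrame):
        try:
            site_info_cols, label_cols, time_cols = _partition_columns(obj.columns)
        except RasterFormatError as exc:
            issues.append(ValidationIssue("error", "<columns>", str(exc)))
            known = [c for c in obj.columns if c.startswith(
                (_SITE_INFO_PREFIX, _LABELS_PREFIX, _TIME_PREFIX))]
            site_info_cols, label_cols, time_cols = _partition_columns(known)
        for col in site_info_cols:
            if len(pd.unique(obj[col].to_numpy())) > 1:
                issues.append(ValidationIssue(
                    "error", col, "site_info column is not constant across trials"))
        windows = []
        for col in time_cols:
            try:
                windows.append(_parse_time_column(col))
            except RasterFormatError as exc:
                issues.append(ValidationIssue("error", col, str(exc)))
        windows.sort()
        if len(obj) < 1:
            issues.append(ValidationIssue("error", "<rows>", "raster has no trials"))
        data = obj[time_cols].to_numpy() if time_cols else np.empty((len(obj), 0))
    else:
        windows = list(obj.time_columns)
        data = obj.data
        if obj.n_trials < 1:
            issues.append(ValidationIssue("error", "<rows>", "raster has no trials"))

    issues.extend(_check_windows(windows))

    if np.issubdtype(np.asarray(data).dtype, np.number):
        arr = np.asarray(data, dtype=float)
        if np.isnan(arr).any():
            issues.append(ValidationIssue(
                "error", "<data>", "time columns contain missing values"))
    else:
        issues.append(ValidationIssue(
            "error", "<data>", "time columns contain non-numeric values"))

    return ValidationReport(issues=issues)


def _check_windows(windows: list) -> list:
    issues = []
    for start, end in windows:
        if end <= start:
            issues.append(ValidationIssue(
                "error", time_column_name(start, end),
                f"window end {end} is not after start {start}"))
    gaps, strides = [], []
    for (s0, e0), (s1, e1) in zip(windows, windows[1:]):
        if s1 < e0:
            issues.append(ValidationIssue(
                "error", time_column_name(s1, e1),
                f"window overlaps the previous window ending at {e0}"))
        elif s1 > e0:
            gaps.append((e0, s1))
        strides.append(s1 - s0)
    if gaps:
        # a uniform stride > 1 looks like down-sampled data: warn, don't fail
        if len(set(strides)) == 1:
            issues.append(ValidationIssue(
                "warning", "<time>",
                f"time windows have a uniform stride of {strides[0]} ms with gaps "
                f"between windows; data may be down-sampled"))
        else:
            for e0, s1 in gaps:
                issues.append(ValidationIssue(
                    "error", time_column_name(s1, s1),
                    f"gap in time coverage between {e0} and {s1} ms"))
    return issues


def raster_event_table(raster: RasterTable) -> pd.DataFrame:
    """Long table of spike events: one row per 1 in the data matrix.

    Returns a dataframe with columns ``trial_index`` (0-based row order)
    and ``event_time_ms`` (the window start of the spike). Only defined
    for 0/1 spike-indicator data.
    """
    data = np.asarray(raster.data)
    if not np.isin(data, (0, 1)).all():
        raise RasterValidationError(
            "event plots require 0/1 spike-indicator data; "
            "this raster contains other values"
        )
    trials, cols = np.nonzero(data)
    starts = np.array([s for s, _ in raster.time_columns])
    return pd.DataFrame({
        "trial_index": trials.astype(int),
        "event_time_ms": starts[cols].astype(int),
    })


def plot_raster(raster: RasterTable, out_path: Union[str, Path]) -> Path:
    """Render a basic tick plot (trials on y, time on x) to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    events = raster_event_table(raster)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.scatter(events["event_time_ms"], events["trial_index"],
               marker="|", s=12, color="black", linewidths=0.6)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("trial")
    ax.set_ylim(-0.5, raster.n_trials - 0.5)
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)
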