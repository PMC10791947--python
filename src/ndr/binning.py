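"""Convert directories of raster files into a single binned-format table.

Binned format stacks all recording sites as rows of one table with a
``siteID`` column (1-based, assigned in lexicographically sorted file-name
order), carries the ``site_info.``/``labels.`` columns over from each
raster, and replaces the native-resolution ``time.`` columns with
sliding-window aggregates named ``time.<start>_<start + bin_width>``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import BinningError
from .raster import (
    RasterTable,
    read_raster_data,
    time_column_name,
    _parse_time_column,
)

__all__ = [
    "BinningConfig",
    "BinnedTable",
    "bin_site",
    "create_binned_data",
    "load_binned_data",
]


@dataclass(frozen=True)
class BinningConfig:
    """Sliding-window binning parameters.

    ``bin_width`` is the window length in ms over which activity is
    aggregated; ``sampling_interval`` is the step between successive
    window starts. ``aggregate`` is ``"mean"`` (firing-rate semantics,
    the default) or ``"sum"`` (integer spike counts, required by the
    Poisson naive Bayes classifier). Optional ``start_time``/``end_time``
    restrict the binned range. Incomplete trailing windows are dropped.
    """

    bin_width: int
    sampling_interval: int
    start_time: Optional[int] = None
    end_time: Optional[int] = None
    aggregate: str = "mean"

    def __post_init__(self):
        if self.bin_width < 1:
            raise BinningError(f"bin_width must be >= 1, got {self.bin_width}")
        if self.sampling_interval < 1:
            raise BinningError(
                f"sampling_interval must be >= 1, got {self.sampling_interval}")
        if self.aggregate not in ("mean", "sum"):
            raise BinningError(
                f"aggregate must be 'mean' or 'sum', got {self.aggregate!r}")


class BinnedTable:
    """All sites stacked into one table with a ``siteID`` column."""

    def __init__(self, df: pd.DataFrame):
        if "siteID" not in df.columns:
            raise BinningError("binned table must have a 'siteID' column")
        self.df = df.reset_index(drop=True)

    @property
    def site_ids(self) -> list:
        return sorted(int(s) for s in self.df["siteID"].unique())

    @property
    def label_columns(self) -> list:
        return [c for c in self.df.columns if c.startswith("labels.")]

    @property
    def time_columns(self) -> list:
        cols = [c for c in self.df.columns if c.startswith("time.")]
        return sorted((_parse_time_column(c) for c in cols), key=lambda w: w[0])

    @property
    def time_column_names(self) -> list:
        return [time_column_name(s, e) for s, e in self.time_columns]

    def data_matrix(self) -> np.ndarray:
        """Rows × time-bins activity values, bins in ascending start order."""
        return self.df[self.time_column_names].to_numpy(dtype=float)

    def labels_for(self, label: str) -> pd.Series:
        col = f"labels.{label}"
        if col not in self.df.columns:
            available = [c[len("labels."):] for c in self.label_columns]
            raise KeyError(
                f"label {label!r} not found; available labels: {available}")
        return self.df[col]

    def to_csv(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        self.df.to_csv(path, index=False)
        return path

    @classmethod
    def read_csv(cls, path: Union[str, Path]) -> "BinnedTable":
        return cls(pd.read_csv(path))

    def __len__(self) -> int:
        return len(self.df)


def _bin_starts(t0: int, t_end: int, config: BinningConfig) -> list:
    starts = []
    s = t0
    while s + config.bin_width <= t_end:
        starts.append(s)
        s += config.sampling_interval
    return starts


def bin_site(raster: RasterTable, config: BinningConfig) -> pd.DataFrame:
    """Aggregate one site's raster into sliding-window bins.

    Bins start at the raster's first sample time (or ``config.start_time``)
    and advance by ``sampling_interval``; each covers ``[start,
    start + bin_width)`` and holds the mean (or sum) of the raw values
    whose windows fall inside it. Trailing windows that would overrun the
    raster are dropped. Returns the site's rows with ``site_info.``,
    ``labels.`` and the new ``time.`` columns (no ``siteID``).
    """
    raster_start = raster.start_time
    raster_end = raster.end_time
    t0 = raster_start if config.start_time is None else config.start_time
    if t0 < raster_start:
        raise BinningError(
            f"start_time {t0} is before the raster's first sample "
            f"at {raster_start}")
    t_end = raster_end if config.end_time is None else min(config.end_time, raster_end)
    if t0 + config.bin_width > t_end:
        raise BinningError(
            f"bin_width {config.bin_width} does not fit in the raster span "
            f"[{t0}, {t_end})")

    raw_starts = np.array([s for s, _ in raster.time_columns])
    raw_ends = np.array([e for _, e in raster.time_columns])
    data = np.asarray(raster.data, dtype=float)

    starts = _bin_starts(t0, t_end, config)
    out = np.empty((raster.n_trials, len(starts)))
    for j, s in enumerate(starts):
        lo = np.searchsorted(raw_starts, s, side="left")
        hi = np.searchsorted(raw_ends, s + config.bin_width, side="right")
        window = data[:, lo:hi]
        if config.aggregate == "mean":
            out[:, j] = window.mean(axis=1)
        else:
            out[:, j] = window.sum(axis=1)

    cols = {}
    for name, value in raster.site_info.items():
        cols[f"site_info.{name}"] = np.repeat(value, raster.n_trials)
    for name in raster.labels.columns:
        cols[f"labels.{name}"] = raster.labels[name].to_numpy()
    df = pd.DataFrame(cols)
    for j, s in enumerate(starts):
        df[time_column_name(s, s + config.bin_width)] = out[:, j]
    return df


def create_binned_data(
    raster_dir: Union[str, Path],
    save_prefix: str,
    config: BinningConfig,
) -> Path:
    """Bin every raster CSV in a directory and write one stacked table.

    Sites get 1-based ``siteID`` values in lexicographically sorted
    file-name order; a ``<prefix>_sites.csv`` manifest records the
    (siteID, file, site_info) assignment. The binned table is written to
    ``<save_prefix>_<bin_width>bins_<sampling_interval>sampled.csv`` and
    its path is returned. Deterministic given the directory contents.
    """
    raster_dir = Path(raster_dir)
    files = sorted(p for p in raster_dir.glob("*.csv"))
    if not files:
        raise BinningError(f"no raster CSV files found in {raster_dir}")

    frames, manifest_rows = [], []
    reference_span = None
    for site_id, path in enumerate(files, start=1):
        raster = read_raster_data(path)
        span = (raster.start_time, raster.end_time,
                raster.time_columns[0][1] - raster.time_columns[0][0])
        if reference_span is None:
            reference_span, reference_file = span, path.name
        elif span != reference_span:
            raise BinningError(
                f"raster files have incompatible time ranges/resolutions: "
                f"{reference_file} spans {reference_span} but {path.name} "
                f"spans {span}")
        binned = bin_site(raster, config)
        binned.insert(0, "siteID", site_id)
        frames.append(binned)
        row = {"siteID": site_id, "file": path.name}
        row.update({f"site_info.{k}": v for k, v in raster.site_info.items()})
        manifest_rows.append(row)

    stacked = pd.concat(frames, ignore_index=True)
    out_path = Path(
        f"{save_prefix}_{config.bin_width}bins_"
        f"{config.sampling_interval}sampled.csv")
    out_path.parent.mkdir(parents=True, exist_ok=True)
    stacked.to_csv(out_path, index=False)
    pd.DataFrame(manifest_rows).to_csv(
        out_path.with_name(out_path.stem + "_sites.csv"), index=False)
    return out_path


def load_binned_data(source) -> BinnedTable:
    """Accept a path, dataframe, or BinnedTable and return a BinnedTable."""
    if isinstance(source, BinnedTable):
        return source
    if isinstance(source, pd.DataFrame):
        return BinnedTable(source)
    return BinnedTable.read_csv(source)
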