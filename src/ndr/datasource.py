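"""Pseudo-population datasources.

Recording sites are usually collected in separate sessions, so real
simultaneous population responses are unavailable; instead, for each
"resample run", every site independently contributes freshly sampled
trials of each required label level and these are concatenated into
pseudo-population vectors. Two datasources are provided:

* basic — train and test on the same label levels;
* generalization — class i is trained on ``train_label_levels[i]`` and
  tested on ``test_label_levels[i]``, probing whether the code abstracts
  across the paired conditions.

Sampling uses a counter-based substream per (seed, run, site), so splits
are bit-reproducible and independent of any parallel scheduling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .binning import BinnedTable, load_binned_data
from .errors import DataSourceError

__all__ = [
    "DataSourceSpec",
    "ds_basic",
    "ds_generalization",
    "SplitData",
    "make_split_data",
    "make_generalization_split_data",
    "make_split",
]


@dataclass
class DataSourceSpec:
    """Everything needed to build one resample run's training/test sets.

    For the basic datasource set ``label_levels``; for generalization set
    ``train_label_levels`` and ``test_label_levels`` (equal length; index
    i of each list defines class i). ``site_ids`` of None means all sites
    in the binned table. Each of the k cv splits receives
    ``num_label_repeats_per_cv_split`` pseudo-trials per class.
    """

    binned: object
    label: str
    num_cv_splits: int
    label_levels: Optional[list] = None
    train_label_levels: Optional[list] = None
    test_label_levels: Optional[list] = None
    site_ids: Optional[list] = None
    num_label_repeats_per_cv_split: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.num_cv_splits < 2:
            raise DataSourceError(
                f"num_cv_splits must be >= 2, got {self.num_cv_splits}")
        if self.num_label_repeats_per_cv_split < 1:
            raise DataSourceError(
                "num_label_repeats_per_cv_split must be >= 1")
        basic = self.label_levels is not None
        gen = (self.train_label_levels is not None
               or self.test_label_levels is not None)
        if basic and gen:
            raise DataSourceError(
                "give either label_levels (basic) or train/test_label_levels "
                "(generalization), not both")
        if gen:
            if self.train_label_levels is None or self.test_label_levels is None:
                raise DataSourceError(
                    "generalization needs both train_label_levels and "
                    "test_label_levels")
            if len(self.train_label_levels) != len(self.test_label_levels):
                raise DataSourceError(
                    f"train_label_levels has {len(self.train_label_levels)} "
                    f"entries but test_label_levels has "
                    f"{len(self.test_label_levels)}; they must be index-paired")

    @property
    def is_generalization(self) -> bool:
        return self.train_label_levels is not None

    def params(self) -> dict:
        p = {
            "type": "generalization" if self.is_generalization else "basic",
            "label": self.label,
            "num_cv_splits": self.num_cv_splits,
            "num_label_repeats_per_cv_split": self.num_label_repeats_per_cv_split,
            "site_ids": self.site_ids,
        }
        if self.is_generalization:
            p["train_label_levels"] = list(self.train_label_levels)
            p["test_label_levels"] = list(self.test_label_levels)
        else:
            p["label_levels"] = (None if self.label_levels is None
                                 else list(self.label_levels))
        return p


def ds_basic(binned, labels: str, num_cv_splits: int,
             label_levels: Optional[Sequence] = None,
             site_IDs_to_use: Optional[Sequence] = None,
             num_label_repeats_per_cv_split: int = 1,
             seed: int = 0) -> DataSourceSpec:
    """Constructor mirroring the standard same-levels datasource."""
    table = load_binned_data(binned)
    if label_levels is None:
        label_levels = sorted(table.labels_for(labels).unique().tolist())
    return DataSourceSpec(
        binned=table, label=labels, num_cv_splits=num_cv_splits,
        label_levels=list(label_levels),
        site_ids=None if site_IDs_to_use is None else list(site_IDs_to_use),
        num_label_repeats_per_cv_split=num_label_repeats_per_cv_split,
        seed=seed)


def ds_generalization(binned, labels: str, num_cv_splits: int,
                      train_label_levels: Sequence,
                      test_label_levels: Sequence,
                      site_IDs_to_use: Optional[Sequence] = None,
                      num_label_repeats_per_cv_split: int = 1,
                      seed: int = 0) -> DataSourceSpec:
    """Constructor for the train-on-one-set, test-on-another datasource."""
    return DataSourceSpec(
        binned=load_binned_data(binned), label=labels,
        num_cv_splits=num_cv_splits,
        train_label_levels=list(train_label_levels),
        test_label_levels=list(test_label_levels),
        site_ids=None if site_IDs_to_use is None else list(site_IDs_to_use),
        num_label_repeats_per_cv_split=num_label_repeats_per_cv_split,
        seed=seed)


@dataclass
class SplitData:
    """One resample run's pseudo-population data.

    ``train`` and ``test`` are (n_classes, k, r, n_sites, n_bins) arrays
    holding the sampled activity; for the basic datasource they are the
    same array. Fold j trains on splits != j of ``train`` and tests on
    split j of ``test``. ``classes`` holds the class identities (the
    training levels); ``sampled_train_indices``/``sampled_test_indices``
    are (n_classes, k, r, n_sites) arrays of raw binned-table row
    indices, kept for audit/invariant checks.
    """

    classes: list
    site_ids: list
    time_bins: list                     # (start, end) pairs
    train: np.ndarray
    test: np.ndarray
    sampled_train_indices: np.ndarray
    sampled_test_indices: np.ndarray

    @property
    def num_cv_splits(self) -> int:
        return self.train.shape[1]

    def fold_train(self, fold: int):
        """Training set for one fold: (X: (n_bins, n, n_sites), y: (n,))."""
        k = self.num_cv_splits
        keep = [j for j in range(k) if j != fold]
        sub = self.train[:, keep]              # (C, k-1, r, S, B)
        C, km1, r, S, B = sub.shape
        X = sub.reshape(C * km1 * r, S, B).transpose(2, 0, 1)
        y = np.repeat(np.arange(C), km1 * r)
        return X, np.asarray(self.classes, dtype=object)[y]

    def fold_test(self, fold: int):
        """Test set for one fold: (X: (n_bins, m, n_sites), y: (m,))."""
        sub = self.test[:, fold]               # (C, r, S, B)
        C, r, S, B = sub.shape
        X = sub.reshape(C * r, S, B).transpose(2, 0, 1)
        y = np.repeat(np.arange(C), r)
        return X, np.asarray(self.classes, dtype=object)[y]


class _SiteCache:
    """Per-site trial data and label row indices, built once per spec."""

    def __init__(self, table: BinnedTable, label: str, site_ids):
        self.time_bins = table.time_columns
        data = table.data_matrix()
        labels = table.labels_for(label).to_numpy()
        ids = table.df["siteID"].to_numpy()
        self.site_ids = (table.site_ids if site_ids is None
                         else sorted(int(s) for s in site_ids))
        missing = set(self.site_ids) - set(table.site_ids)
        if missing:
            raise DataSourceError(
                f"site_ids {sorted(missing)} do not exist in the binned data")
        self.rows_by_site_level = {}
        self.data = data
        for s in self.site_ids:
            site_rows = np.nonzero(ids == s)[0]
            by_level = {}
            for row in site_rows:
                by_level.setdefault(labels[row], []).append(row)
            self.rows_by_site_level[s] = {
                lv: np.asarray(rws) for lv, rws in by_level.items()}


def _check_feasible(cache: _SiteCache, levels, needed: int) -> None:
    for s in cache.site_ids:
        by_level = cache.rows_by_site_level[s]
        for lv in levels:
            have = len(by_level.get(lv, ()))
            if have < needed:
                raise DataSourceError(
                    f"site {s} has only {have} trials of level {lv!r} but "
                    f"{needed} are needed (num_cv_splits * repeats); use "
                    f"sites_with_k_repetitions() to pick usable sites")


def _sample_tensor(cache: _SiteCache, levels, k: int, r: int,
                   rngs: dict) -> tuple:
    """Sample k*r trials per (site, level) and deal them into k splits.

    ``rngs`` maps siteID -> Generator. Returns (data tensor
    (C, k, r, S, B), index tensor (C, k, r, S)).
    """
    C, S = len(levels), len(cache.site_ids)
    B = len(cache.time_bins)
    tensor = np.empty((C, k, r, S, B))
    idx = np.empty((C, k, r, S), dtype=int)
    for si, s in enumerate(cache.site_ids):
        rng = rngs[s]
        by_level = cache.rows_by_site_level[s]
        for ci, lv in enumerate(levels):
            rows = by_level[lv]
            chosen = rng.permutation(len(rows))[: k * r]
            picked = rows[chosen].reshape(k, r)
            idx[ci, :, :, si] = picked
            tensor[ci, :, :, si, :] = cache.data[picked]
    return tensor, idx


def _get_cache(spec: DataSourceSpec) -> _SiteCache:
    cache = getattr(spec, "_cache", None)
    if cache is None:
        table = load_binned_data(spec.binned)
        cache = _SiteCache(table, spec.label, spec.site_ids)
        object.__setattr__(spec, "_cache", cache)
    return cache


def make_split_data(spec: DataSourceSpec, run_index: int) -> SplitData:
    """Build one resample run's pseudo-population splits (basic datasource).

    For each site independently, k*r trials of every level are sampled
    uniformly without replacement and dealt into the k cv splits;
    pseudo-trial vectors concatenate the sites (ascending siteID) within
    the same (class, split, repeat) slot. Deterministic given
    (spec.seed, run_index).
    """
    if spec.is_generalization:
        raise DataSourceError(
            "spec defines train/test levels; use make_generalization_split_data")
    cache = _get_cache(spec)
    levels = (spec.label_levels if spec.label_levels is not None
              else sorted({lv for by in cache.rows_by_site_level.values()
                           for lv in by}))
    k, r = spec.num_cv_splits, spec.num_label_repeats_per_cv_split
    _check_feasible(cache, levels, k * r)
    rngs = {s: np.random.default_rng([spec.seed, run_index, s])
            for s in cache.site_ids}
    tensor, idx = _sample_tensor(cache, levels, k, r, rngs)
    return SplitData(
        classes=list(levels), site_ids=list(cache.site_ids),
        time_bins=list(cache.time_bins),
        train=tensor, test=tensor,
        sampled_train_indices=idx, sampled_test_indices=idx)


def make_generalization_split_data(spec: DataSourceSpec,
                                   run_index: int) -> SplitData:
    """Build one run's splits with distinct training and test levels.

    Class i trains on ``train_label_levels[i]`` and tests on
    ``test_label_levels[i]``. Train-level and test-level trials are
    sampled independently (separate substreams), each without
    replacement across the k splits.
    """
    if not spec.is_generalization:
        raise DataSourceError("spec has no train/test levels; use make_split_data")
    cache = _get_cache(spec)
    k, r = spec.num_cv_splits, spec.num_label_repeats_per_cv_split
    _check_feasible(cache, spec.train_label_levels, k * r)
    _check_feasible(cache, spec.test_label_levels, k * r)
    train_rngs = {s: np.random.default_rng([spec.seed, run_index, s, 0])
                  for s in cache.site_ids}
    test_rngs = {s: np.random.default_rng([spec.seed, run_index, s, 1])
                 for s in cache.site_ids}
    train, train_idx = _sample_tensor(
        cache, spec.train_label_levels, k, r, train_rngs)
    test, test_idx = _sample_tensor(
        cache, spec.test_label_levels, k, r, test_rngs)
    return SplitData(
        classes=list(spec.train_label_levels), site_ids=list(cache.site_ids),
        time_bins=list(cache.time_bins),
        train=train, test=test,
        sampled_train_indices=train_idx, sampled_test_indices=test_idx)


def make_split(spec: DataSourceSpec, run_index: int) -> SplitData:
    """Dispatch to the basic or generalization split builder."""
    if spec.is_generalization:
        return make_generalization_split_data(spec, run_index)
    return make_split_data(spec, run_index)
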