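"""Per-site label repetition counts.

The number of cross-validation splits k that an analysis can use is
limited by how many times each label level was repeated at each site:
a site can only contribute if it has at least k repetitions of *every*
level being decoded. These helpers count repetitions and summarize the
trade-off between k and the number of usable sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .binning import BinnedTable, load_binned_data

__all__ = [
    "LabelRepetitionInfo",
    "get_num_label_repetitions",
    "sites_with_k_repetitions",
    "get_siteIDs_with_k_label_repetitions",
    "repetition_curve",
]


@dataclass
class LabelRepetitionInfo:
    """Repetition counts for one label across all sites.

    ``per_site_level_counts`` has one row per (siteID, level) with the
    number of trials; every requested level appears for every site (count
    0 if absent). ``per_site_min`` holds each site's minimum count over
    the levels considered.
    """

    label: str
    levels: list
    per_site_level_counts: pd.DataFrame  # siteID, level, n_trials
    per_site_min: pd.DataFrame           # siteID, min_repeats


def get_num_label_repetitions(
    binned,
    label: str,
    levels: Optional[Sequence] = None,
) -> LabelRepetitionInfo:
    """Count trials per (site, level) for one label.

    ``binned`` may be a path, dataframe, or :class:`BinnedTable`. When
    ``levels`` is given, all other levels are ignored; sites lacking a
    requested level get an explicit count of 0 (and hence a per-site
    minimum of 0) rather than being dropped.
    """
    table = load_binned_data(binned)
    values = table.labels_for(label)
    if levels is None:
        levels = sorted(values.unique().tolist())
    else:
        levels = list(levels)
        present = set(values.unique().tolist())
        missing = [lv for lv in levels if lv not in present]
        if missing:
            raise ValueError(
                f"requested level(s) {missing} never occur in label {label!r}")

    sub = pd.DataFrame({"siteID": table.df["siteID"], "level": values})
    sub = sub[sub["level"].isin(levels)]
    counts = (sub.groupby(["siteID", "level"], sort=True)
              .size().rename("n_trials").reset_index())

    # cross join so absent (site, level) pairs appear with count 0
    full = pd.MultiIndex.from_product(
        [table.site_ids, levels], names=["siteID", "level"]).to_frame(index=False)
    counts = full.merge(counts, on=["siteID", "level"], how="left")
    counts["n_trials"] = counts["n_trials"].fillna(0).astype(int)

    per_site_min = (counts.groupby("siteID", sort=True)["n_trials"]
                    .min().rename("min_repeats").reset_index())
    return LabelRepetitionInfo(
        label=label, levels=levels,
        per_site_level_counts=counts, per_site_min=per_site_min)


def sites_with_k_repetitions(info: LabelRepetitionInfo, k: int) -> list:
    """Site IDs (ascending) with at least k repetitions of every level."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    mask = info.per_site_min["min_repeats"] >= k
    return sorted(int(s) for s in info.per_site_min.loc[mask, "siteID"])


def get_siteIDs_with_k_label_repetitions(
    binned, label: str, k: int, levels: Optional[Sequence] = None
) -> list:
    """One-call convenience: count repetitions, then filter sites by k."""
    return sites_with_k_repetitions(
        get_num_label_repetitions(binned, label, levels), k)


def repetition_curve(
    info: LabelRepetitionInfo, max_k: Optional[int] = None
) -> pd.DataFrame:
    """Table of (k, level, n_sites) with an 'ALL' row per k.

    For each k from 1 to the largest observed count, ``n_sites`` is the
    number of sites with at least k repetitions of that level; the 'ALL'
    rows count sites with at least k repetitions of every level, and are
    therefore a lower bound on every per-level row at the same k.
    """
    counts = info.per_site_level_counts
    if max_k is None:
        max_k = int(counts["n_trials"].max()) if len(counts) else 0
    rows = []
    for k in range(1, max_k + 1):
        per_level = (counts[counts["n_trials"] >= k]
                     .groupby("level").size())
        for level in info.levels:
            rows.append({"k": k, "level": level,
                         "n_sites": int(per_level.get(level, 0))})
        n_all = int((info.per_site_min["min_repeats"] >= k).sum())
        rows.append({"k": k, "level": "ALL", "n_sites": n_all})
    return pd.DataFrame(rows, columns=["k", "level", "n_sites"])


def plot_repetition_curve(info: LabelRepetitionInfo, out_path) -> None:
    """Line plot of sites-vs-k, one line per level plus the ALL curve."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curve = repetition_curve(info)
    fig, ax = plt.subplots(figsize=(7, 4))
    for level, grp in curve[curve["level"] != "ALL"].groupby("level"):
        ax.plot(grp["k"], grp["n_sites"], alpha=0.4, lw=0.8)
    all_rows = curve[curve["level"] == "ALL"]
    ax.plot(all_rows["k"], all_rows["n_sites"], "k--", lw=2, label="ALL levels")
    ax.set_xlabel("repetitions k")
    ax.set_ylabel("number of sites with >= k repetitions")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
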