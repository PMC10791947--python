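"""Synthetic raster-format data with known ground truth.

Generates tuned Poisson-spiking sites for a face-views-style design:
``n_orientations`` head orientations × ``n_people`` identities, trials of
millisecond-resolution 0/1 spike indicators, a stimulus-driven response
starting ``latency_ms`` after onset and lasting ``stimulus_on_ms``, and
optional per-site variation in how often each stimulus was repeated.

Spiking is a Bernoulli-per-millisecond approximation of an inhomogeneous
Poisson process (valid while rate·1ms ≪ 1): before the response latency a
site fires at ``baseline_rate_hz``; during the response window the rate is
``baseline + (peak - baseline) · similarity`` where similarity ∈ [0, 1]
measures how close the trial's stimulus is to the site's preferred
(orientation, person); afterwards the stimulus-driven component decays
exponentially back to baseline.

Every generated file passes raster validation, and the tuning parameters
give exact control over decodability: ``peak == baseline`` produces
label-independent data (chance decoding), strong narrow tuning produces
near-perfect decoding, and ``orientation_invariant=True`` makes person
tuning identical across orientations so cross-orientation generalization
succeeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import NdrError
from .raster import RasterTable, write_raster_data

__all__ = [
    "ORIENTATION_NAMES",
    "SyntheticDesign",
    "generate_raster",
    "generate_raster_dir",
    "generate_worked_fixture",
    "shuffle_labels_per_site",
]

# first two entries are the profile pair used in generalization demos
ORIENTATION_NAMES = [
    "left profile", "right profile", "frontal", "left 3/4",
    "right 3/4", "upward", "downward", "back",
]


@dataclass
class SyntheticDesign:
    """Parameters of the synthetic tuned-population experiment."""

    n_orientations: int = 8
    n_people: int = 25
    n_sites: int = 10
    trials_per_stimulus_per_site: Union[int, tuple] = 3
    trial_length_ms: int = 800
    stimulus_on_ms: int = 200
    isi_ms: int = 200
    latency_ms: int = 150
    baseline_rate_hz: float = 5.0
    peak_rate_hz: float = 60.0
    person_tuning_width: float = 1.0
    orientation_tuning_width: float = 1.0
    orientation_invariant: bool = False
    decay_tau_ms: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.n_orientations <= len(ORIENTATION_NAMES):
            raise NdrError(
                f"n_orientations must be in [1, {len(ORIENTATION_NAMES)}]")
        if self.baseline_rate_hz < 0 or self.peak_rate_hz < 0:
            raise NdrError("rates must be nonnegative")
        if self.latency_ms >= self.trial_length_ms:
            raise NdrError("latency_ms must be less than trial_length_ms")
        if max(self.baseline_rate_hz, self.peak_rate_hz) / 1000.0 >= 1.0:
            raise NdrError(
                "rate per 1 ms sample is >= 1 spike; lower the rates or use "
                "a finer resolution than the Bernoulli-per-ms approximation")

    @property
    def orientation_names(self) -> list:
        return ORIENTATION_NAMES[: self.n_orientations]

    def combo_label(self, orientation: int, person: int) -> str:
        return f"{self.orientation_names[orientation]} {person + 1}"

    def stimuli(self) -> list:
        """All (orientation_index, person_index) pairs in label order."""
        return [(o, p) for o in range(self.n_orientations)
                for p in range(self.n_people)]


def _circular_distance(a: int, b: int, n: int) -> float:
    d = abs(a - b) % n
    return min(d, n - d)


def _similarity(design: SyntheticDesign, site: int,
                orientation: int, person: int) -> float:
    pref_person = site % design.n_people
    pref_orient = site % design.n_orientations
    dp = _circular_distance(person, pref_person, design.n_people)
    sim_p = np.exp(-0.5 * (dp / design.person_tuning_width) ** 2)
    if design.orientation_invariant or design.n_orientations == 1:
        sim_o = 1.0
    else:
        do = _circular_distance(orientation, pref_orient, design.n_orientations)
        sim_o = np.exp(-0.5 * (do / design.orientation_tuning_width) ** 2)
    return float(sim_p * sim_o)


def _rate_profile(design: SyntheticDesign, similarity: float) -> np.ndarray:
    """Firing rate (Hz) at each 1 ms sample of the trial."""
    t = np.arange(design.trial_length_ms, dtype=float)
    base = design.baseline_rate_hz
    drive = (design.peak_rate_hz - base) * similarity
    rate = np.full_like(t, base)
    on = design.latency_ms
    off = min(design.latency_ms + design.stimulus_on_ms, design.trial_length_ms)
    rate[on:off] += drive
    after = t >= off
    rate[after] += drive * np.exp(-(t[after] - off) / design.decay_tau_ms)
    return rate


def _trial_counts(design: SyntheticDesign, site: int,
                  rng: np.random.Generator) -> dict:
    spec = design.trials_per_stimulus_per_site
    counts = {}
    for stim in design.stimuli():
        if isinstance(spec, int):
            counts[stim] = spec
        else:
            lo, hi = spec
            counts[stim] = int(rng.integers(lo, hi + 1))
    return counts


def generate_raster(design: SyntheticDesign, site: int) -> RasterTable:
    """Generate one site's raster table (deterministic given design.seed)."""
    rng = np.random.default_rng([design.seed, site])
    counts = _trial_counts(design, site, rng)

    trials = []
    for (o, p), n in counts.items():
        for _ in range(n):
            trials.append((o, p))
    order = rng.permutation(len(trials))
    trials = [trials[i] for i in order]

    T = design.trial_length_ms
    data = np.zeros((len(trials), T), dtype=int)
    labels = {"orientation": [], "person": [], "orient_person_combo": []}
    for i, (o, p) in enumerate(trials):
        prob = _rate_profile(design, _similarity(design, site, o, p)) / 1000.0
        data[i] = (rng.random(T) < prob).astype(int)
        labels["orientation"].append(design.orientation_names[o])
        labels["person"].append(f"person {p + 1}")
        labels["orient_person_combo"].append(design.combo_label(o, p))

    site_info = {
        "monkey": f"monkey_{1 + site % 2}",
        "region": "patch_A",
        "site_number": site + 1,
    }
    time_columns = [(t, t + 1) for t in range(1, T + 1)]
    return RasterTable(
        site_info=site_info,
        labels=pd.DataFrame(labels),
        time_columns=time_columns,
        data=data)


def generate_raster_dir(design: SyntheticDesign, out_dir) -> list:
    """Write one raster CSV per site; returns the file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for site in range(design.n_sites):
        raster = generate_raster(design, site)
        path = out_dir / f"synthetic_site_{site + 1:03d}.csv"
        write_raster_data(raster, path)
        paths.append(path)
    return paths


def expected_spike_count(design: SyntheticDesign, site: int,
                         orientation: int, person: int) -> float:
    """Analytic expected spikes per trial for one (site, stimulus)."""
    prob = _rate_profile(
        design, _similarity(design, site, orientation, person)) / 1000.0
    return float(prob.sum())


def shuffle_labels_per_site(binned, label: str, seed: int = 0):
    """Return a copy of a binned table with one label column shuffled
    independently within each site — destroys any real signal while
    preserving each site's label counts, so decoding must be at chance."""
    from .binning import BinnedTable, load_binned_data

    table = load_binned_data(binned)
    df = table.df.copy()
    col = f"labels.{label}"
    rng = np.random.default_rng(seed)
    for s in table.site_ids:
        rows = df.index[df["siteID"] == s].to_numpy()
        df.loc[rows, col] = df.loc[rows, col].to_numpy()[
            rng.permutation(len(rows))]
    return BinnedTable(df)


# ---------------------------------------------------------------------------
# worked fixtures: tiny datasets with hand-computed expected answers

def _fixture_two_class_separable():
    """Two linearly separated classes; same-time decoding must be perfect."""
    rng = np.random.default_rng(7)
    n_per = 12
    X = np.vstack([
        rng.normal(0.0, 0.05, size=(n_per, 4)) + np.array([1, 0, 1, 0]),
        rng.normal(0.0, 0.05, size=(n_per, 4)) + np.array([0, 1, 0, 1]),
    ])
    y = np.array(["a"] * n_per + ["b"] * n_per, dtype=object)
    return {"train_X": X, "train_y": y,
            "expected": {"self_prediction_accuracy": 1.0}}


def _fixture_tie_degenerate():
    """All-zero features: every decision value ties, accuracy is chance."""
    X = np.zeros((20, 5))
    y = np.array((["a"] * 10) + (["b"] * 10), dtype=object)
    return {"train_X": X, "train_y": y,
            "expected": {"chance_accuracy": 0.5}}


def _fixture_three_split_counts():
    """Small binned table with known per-(site, level) trial counts."""
    counts = {
        1: {"u": 3, "v": 3, "w": 3},
        2: {"u": 4, "v": 2, "w": 5},
        3: {"u": 1, "v": 6, "w": 3},
    }
    rows = []
    rng = np.random.default_rng(11)
    for site, by_level in counts.items():
        for level, n in by_level.items():
            for _ in range(n):
                rows.append({
                    "siteID": site,
                    "labels.stim": level,
                    "time.0_10": rng.random(),
                    "time.10_20": rng.random(),
                })
    from .binning import BinnedTable
    table = BinnedTable(pd.DataFrame(rows))
    # brute-force tally: min over levels per site, then threshold
    expected_min = {s: min(by.values()) for s, by in counts.items()}
    expected_sites_k3 = sorted(s for s, m in expected_min.items() if m >= 3)
    return {"binned": table, "counts": counts,
            "expected": {"per_site_min": expected_min,
                         "sites_with_3_repetitions": expected_sites_k3}}


_FIXTURES = {
    "two-class-separable": _fixture_two_class_separable,
    "tie-degenerate": _fixture_tie_degenerate,
    "three-split-counts": _fixture_three_split_counts,
}


def generate_worked_fixture(name: str) -> dict:
    """Return a documented fixture: data plus hand-computed answers.

    Catalog: "two-class-separable", "tie-degenerate", "three-split-counts".
    """
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise NdrError(
            f"unknown fixture {name!r}; catalog: {sorted(_FIXTURES)}") from None
    return builder()
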