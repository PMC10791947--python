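"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from ndr.binning import BinningConfig, create_binned_data, load_binned_data
from ndr.synthetic import SyntheticDesign, generate_raster_dir


@pytest.fixture(scope="session")
def small_design():
    """2 orientations × 4 people, 6 sites, 3 trials per stimulus."""
    return SyntheticDesign(
        n_orientations=2, n_people=4, n_sites=6,
        trials_per_stimulus_per_site=3, trial_length_ms=120,
        latency_ms=50, stimulus_on_ms=60, baseline_rate_hz=8.0,
        peak_rate_hz=120.0, person_tuning_width=0.8, seed=101)


@pytest.fixture(scope="session")
def raster_dir(small_design, tmp_path_factory):
    out = tmp_path_factory.mktemp("rasters")
    generate_raster_dir(small_design, out)
    return out


@pytest.fixture(scope="session")
def binned_table(raster_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("binned")
    path = create_binned_data(
        raster_dir, str(out / "small"), BinningConfig(20, 20))
    return load_binned_data(path)


@pytest.fixture(scope="session")
def binned_counts_table(raster_dir, tmp_path_factory):
    """Same data binned with aggregate='sum' (integer counts)."""
    out = tmp_path_factory.mktemp("binned_sum")
    path = create_binned_data(
        raster_dir, str(out / "small_sum"),
        BinningConfig(20, 20, aggregate="sum"))
    return load_binned_data(path)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
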