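"""Shared fixtures: small synthetic screens and CSV fixtures on disk.

All fixture data is generated programmatically (via the package's own
simulator or tiny hand-written tables); nothing is read from outside the
test session.
"""

from __future__ import annotations

import pandas as pd
import pytest

from stopleak import SimulationConfig, simulate_screen


@pytest.fixture(scope="session")
def default_screen():
    """One full screen at default conditions (3 replicates x 96 wells)."""
    return simulate_screen(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def small_screen():
    """A quick screen: 2 replicates x 12 wells per construct."""
    cfg = SimulationConfig(seed=7, n_replicates=2, wells_per_construct=12)
    return simulate_screen(cfg)


@pytest.fixture()
def tiny_measurements() -> pd.DataFrame:
    """Hand-written two-plate table with known blank means.

    Plate P1 blanks: venus {48, 52} (mean 50), od750 {0.1, 0.1}, chl {10, 10}.
    Plate P2 blanks: venus {10, 30} (mean 20), od750 {0.2, 0.2}, chl {5, 15}.
    """
    rows = [
        ("P1", "A1", "blank", 0.10, 48.0, 10.0),
        ("P1", "A2", "blank", 0.10, 52.0, 10.0),
        ("P1", "B1", "sample", 0.60, 150.0, 110.0),
        ("P1", "B2", "sample", 0.10, 50.0, 10.0),
        ("P2", "A1", "blank", 0.20, 10.0, 5.0),
        ("P2", "A2", "blank", 0.20, 30.0, 15.0),
        ("P2", "B1", "sample", 0.70, 120.0, 60.0),
    ]
    return pd.DataFrame(
        rows, columns=["plate_id", "well", "role", "od750", "venus", "chl"]
    )


@pytest.fixture()
def tiny_layout() -> pd.DataFrame:
    rows = [
        ("P1", "B1", "leaky", "T222", "rep1"),
        ("P1", "B2", "no_venus", "T222", "rep1"),
        ("P2", "B1", "leaky", "T222", "rep2"),
    ]
    return pd.DataFrame(
        rows, columns=["plate_id", "well", "construct", "strain", "replicate"]
    )


@pytest.fixture()
def screen_csvs(tmp_path, small_screen):
    """The small screen written out in the documented CSV schemas."""
    measurements, layout, _ = small_screen
    meas_path = tmp_path / "measurements.csv"
    layout_path = tmp_path / "layout.csv"
    measurements.to_csv(meas_path, index=False)
    layout.to_csv(layout_path, index=False)
    return meas_path, layout_path
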