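"""Shared fixtures: a synthetic one-island seascape and canned telemetry."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sharkmove.simulate.movement import MovementParams, SharkSpec, simulate_shark_track
from sharkmove.simulate.seascape import Island, generate_seascape

ISLAND_CENTER = (20.8, -156.6)
CORE_CENTER = (20.73, -156.45)  # on the shelf SE of the island


@pytest.fixture(scope="session")
def island():
    return Island(center=ISLAND_CENTER, land_radius_km=8.0, shelf_width_km=15.0)


@pytest.fixture(scope="session")
def grid(island):
    """One-island seascape, ~1.6 km cells, 120 x 120."""
    return generate_seascape(
        [island], origin=(20.0, -157.6), n_rows=120, n_cols=120, cell_deg=0.015
    )


@pytest.fixture(scope="session")
def shark_spec():
    return SharkSpec(
        shark_id="S1",
        sex="F",
        total_length_cm=320.0,
        island="Maui",
        tagging_position=CORE_CENTER,
        tagged_at=pd.Timestamp("2014-03-01"),
    )


@pytest.fixture(scope="session")
def core_params():
    return MovementParams(
        attraction_center=CORE_CENTER,
        attraction_per_h=0.5,
        noise_km=0.5,
        excursion_rate_per_day=0.0,
    )


@pytest.fixture(scope="session")
def core_track(shark_spec, core_params, grid):
    """Core-attracted track, 5,000 one-minute steps, fixed seed."""
    days = 5000 / (24 * 60)
    return simulate_shark_track(shark_spec, core_params, grid, duration_days=days, seed=11)


def random_detection_log(rng: np.random.Generator, n: int, n_receivers: int = 3) -> pd.DataFrame:
    """A random single-shark detection log with clustered and sparse gaps."""
    t0 = pd.Timestamp("2014-06-01")
    gaps_min = rng.choice([1.0, 5.0, 20.0, 29.9, 30.0, 45.0, 300.0], size=n)
    times = t0 + pd.to_timedelta(np.cumsum(gaps_min), unit="m")
    recs = rng.integers(0, n_receivers, size=n)
    return pd.DataFrame(
        {
            "time": times,
            "transmitter_id": "T1",
            "receiver_id": [f"R{k}" for k in recs],
        }
    )
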