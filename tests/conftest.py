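import numpy as np
import pandas as pd
import pytest

from gulftrack.synthetic import SimParams, build_habitat, build_threat_layers, simulate_tracks


@pytest.fixture(scope="session")
def habitat():
    return build_habitat()


@pytest.fixture(scope="session")
def threats(habitat):
    return build_threat_layers(habitat, seed=11)


@pytest.fixture(scope="session")
def small_cohort(habitat):
    """Three full-itinerary turtles with Argos noise, shared across tests."""
    params = SimParams(n_turtles=3, seed=42)
    return simulate_tracks(params, habitat)


@pytest.fixture(scope="session")
def clean_track():
    """One noise-free, gap-free track (continuous duty cycle)."""
    params = SimParams(
        n_turtles=1,
        seed=7,
        lc_scale={c: 0.0 for c in "3210ABZ"},
        gap_rate=0.0,
        duty_cycle="continuous",
    )
    return simulate_tracks(params)[0]


def make_fix_frame(times, lons, lats, lcs, animal="a1"):
    return pd.DataFrame(
        {
            "animal_id": animal,
            "timestamp": pd.to_datetime(times, utc=True),
            "lon": np.asarray(lons, dtype=float),
            "lat": np.asarray(lats, dtype=float),
            "lc": list(lcs),
        }
    )
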