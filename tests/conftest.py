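import numpy as np
import pandas as pd
import pytest

import geomob as g


@pytest.fixture(scope="session")
def grid3() -> g.ZoneSystem:
    return g.generate_zones(3, 3, 0.01, (51.5, -0.1))


@pytest.fixture(scope="session")
def grid5() -> g.ZoneSystem:
    return g.generate_zones(5, 5, 0.02, (51.4, -0.3))


@pytest.fixture(scope="session")
def grid6() -> g.ZoneSystem:
    return g.generate_zones(6, 6, 0.02, (51.4, -0.3))


@pytest.fixture(scope="session")
def small_stream():
    """A small seeded synthetic scenario shared across tests.

    200 users x 10 days keeps recovery tests meaningful while the
    whole fixture generates in a few seconds.
    """
    zones = g.generate_zones(8, 8, 0.04, (51.35, -0.35))
    scenario = g.ActivityScenario(n_users=200, n_days=10, seed=42)
    points, truth_trips, truth_days = g.generate_activity_stream(zones, scenario)
    return {
        "zones": zones,
        "scenario": scenario,
        "points": points,
        "truth_trips": truth_trips,
        "truth_days": truth_days,
    }


def make_points(rows):
    """rows: iterable of (user, iso_ts, lat, lon)."""
    df = pd.DataFrame(rows, columns=["user_id", "timestamp", "lat", "lon"])
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
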