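import datetime as dt

import matplotlib
import numpy as np
import pytest
from hypothesis import settings

matplotlib.use("Agg")

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from pheromap.events import EventLog, PlaceMapping
from pheromap.pheromone import PheromoneParams

DAY0 = dt.date(2022, 3, 1)
T0 = dt.datetime(2022, 3, 1, 0, 0, 0)


def make_log(rows, dialect="synthetic"):
    """rows: (seconds_offset, sensor_id, value, sensor_type)."""
    import pandas as pd

    frame = pd.DataFrame(
        [
            {
                "timestamp": T0 + dt.timedelta(seconds=s),
                "sensor_id": sid,
                "value": val,
                "sensor_type": st,
            }
            for s, sid, val, st in rows
        ],
        columns=["timestamp", "sensor_id", "value", "sensor_type"],
    )
    return EventLog(frame, dialect=dialect)


@pytest.fixture
def hh126():
    return PlaceMapping.hh126()


@pytest.fixture
def small_params():
    """A 16-grid with the four places at quadrant centers (oracle-sized)."""
    return PheromoneParams(
        grid_size=16,
        sigma=6.0,
        tau=60.0,
        place_positions={"P1": (4, 4), "P2": (4, 12), "P3": (12, 4), "P4": (12, 12)},
        intensity_cap=10.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20220301)
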