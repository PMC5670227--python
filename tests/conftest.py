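import numpy as np
import pandas as pd
import pytest

from reefstress.scoring import QuadratMap, Region, SubstrateLabel
from reefstress.thermal import Climatology, TemperatureSeries


@pytest.fixture
def constant_day_series():
    """96 records of 30.0 C on a single calendar day."""
    times = pd.date_range("2016-01-01", periods=96, freq="15min")
    return TemperatureSeries(
        site_id="site1",
        habitat="subtidal",
        times=times,
        temperatures=np.full(96, 30.0),
    )


@pytest.fixture
def clim():
    return Climatology(site_id="site1", mmm=30.827, source="test")


def make_series(daily_temps, site_id="site1", habitat="subtidal", start="2016-01-01"):
    """One series with 96 constant records per day from a list of daily temps."""
    frames = []
    t0 = pd.Timestamp(start)
    for i, temp in enumerate(daily_temps):
        times = pd.date_range(t0 + pd.Timedelta(days=i), periods=96, freq="15min")
        frames.append(pd.Series(np.full(96, float(temp)), index=times))
    s = pd.concat(frames)
    return TemperatureSeries(
        site_id=site_id, habitat=habitat, times=s.index, temperatures=s.to_numpy()
    )


@pytest.fixture
def split_map():
    """Unit square split 60/40 between coral and rock."""
    coral = SubstrateLabel("hard_coral", genus="Acropora", morphology="branching", health="UB")
    return QuadratMap(
        quadrat_id="q1",
        transect_id="t1",
        regions=[
            Region(coral, (0.0, 0.0, 0.6, 1.0)),
            Region(SubstrateLabel("rock"), (0.6, 0.0, 1.0, 1.0)),
        ],
    )


@pytest.fixture
def single_label_map():
    coral = SubstrateLabel("hard_coral", genus="Acropora", morphology="branching", health="UB")
    return QuadratMap(
        quadrat_id="q1",
        transect_id="t1",
        regions=[Region(coral, (0.0, 0.0, 1.0, 1.0))],
    )
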