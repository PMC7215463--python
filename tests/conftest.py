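from datetime import date, timedelta

import numpy as np
import pytest

from heatrisk import DailyIndicatorSeries, MortalitySeries


def make_series(values, start=date(2010, 6, 1), name="Tmax"):
    dates = tuple(start + timedelta(days=i) for i in range(len(values)))
    return DailyIndicatorSeries(dates, np.asarray(values, dtype=float), name)


def make_mortality(deaths, population=1_000_000.0, start=date(2010, 6, 1)):
    deaths = np.asarray(deaths, dtype=float)
    dates = tuple(start + timedelta(days=i) for i in range(len(deaths)))
    return MortalitySeries(dates, deaths, np.full(len(deaths), population))


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture
def mortality_factory():
    return make_mortality
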