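import datetime as dt

import numpy as np
import pandas as pd
import pytest

from cgmcoda.cgm_io import CGMSeries

#: the worked-example day: minutes in the five glucose ranges
WORKED_MINUTES = np.array([200.0, 200.0, 435.0, 485.0, 120.0])
WORKED_COUNTS = np.array([40, 40, 87, 97, 24])
WORKED_CLR = np.array([-0.2304, -0.2304, 0.5466, 0.6554, -0.7412])
WORKED_ILR = np.array([-0.4207, 0.0, -0.4813, -0.9876])


def make_series(glucose, start=dt.datetime(2021, 1, 1), cadence=5,
                patient_id="T", drop_slots=()):
    """Gap-free series from a glucose array, with optional slots removed."""
    glucose = np.asarray(glucose, dtype=float)
    times = (np.datetime64(start, "ns")
             + np.arange(len(glucose)) * np.timedelta64(cadence * 60, "s"))
    keep = np.ones(len(glucose), dtype=bool)
    keep[list(drop_slots)] = False
    return CGMSeries(patient_id, times[keep], glucose[keep], cadence)


@pytest.fixture
def flat_day_series():
    """One gap-free day entirely in normoglycemia."""
    return make_series(np.full(288, 110.0))


@pytest.fixture
def worked_example_series():
    """A gap-free day realizing the worked-example range counts."""
    values = np.concatenate([
        np.full(40, 48.0),    # <54
        np.full(40, 60.0),    # 54-70
        np.full(87, 120.0),   # 70-180
        np.full(97, 200.0),   # 180-250
        np.full(24, 300.0),   # >250
    ])
    return make_series(values)


def write_cgm_csv(path, series: CGMSeries) -> str:
    pd.DataFrame({
        "timestamp": pd.to_datetime(series.times).strftime("%Y-%m-%dT%H:%M:%S"),
        "glucose": series.glucose,
    }).to_csv(path, index=False)
    return str(path)
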