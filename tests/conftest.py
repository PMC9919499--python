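from datetime import datetime, timedelta

import numpy as np
import pytest
from scipy.special import expit

from amcm.tracker import MinuteSample, MissionRecord

NOW = datetime(2020, 4, 27, 12, 0)


def make_logistic_records(
    n,
    beta0,
    intercept,
    rng,
    geohash="wy6wfm8",
    bids=None,
    spacing_minutes=30,
    participant="p",
    end=NOW,
):
    """Mission records drawn from a logistic ground truth, ending at `end`."""
    grid = np.round(np.arange(0.3, 3.01, 0.3), 10)
    records = []
    for i in range(n):
        t = end - timedelta(minutes=(n - i) * spacing_minutes)
        bid = float(rng.choice(grid)) if bids is None else float(bids[i])
        p = expit(beta0 * bid + intercept)
        records.append(
            MissionRecord(participant, t, geohash, bid, bool(rng.random() < p))
        )
    return records


def sedentary_stream(start, minutes, steps=0, location=(36.37, 127.362)):
    return [
        MinuteSample(start + timedelta(minutes=i), steps, location)
        for i in range(minutes)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
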