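from datetime import datetime, time

import numpy as np
import pytest

from flyrhythm import ActivitySeries, LightSchedule


@pytest.fixture
def schedule() -> LightSchedule:
    """LD 12:12 for 3 days then 7 days of DD, lights on at 08:00."""
    return LightSchedule(lights_on_clock=time(8, 0), photoperiod_hours=12.0,
                         n_ld_days=3, n_dd_days=7)


@pytest.fixture
def make_series():
    """Factory for ad-hoc ActivitySeries starting at lights-on (08:00)."""

    def _make(counts, bin_minutes=30, fly_id="f1", genotype="test"):
        return ActivitySeries(
            fly_id=fly_id, genotype=genotype,
            start_time=datetime(2016, 1, 4, 8, 0),
            bin_minutes=bin_minutes, counts=np.asarray(counts),
        )

    return _make
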