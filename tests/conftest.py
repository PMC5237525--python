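from datetime import datetime, timedelta

import pytest

from hipaki.cohort import PatientEpisode
from hipaki.renal import CreatinineSeries

ADMIT = datetime(2009, 6, 1, 12, 0)
DISCHARGE = datetime(2009, 6, 15, 14, 0)


def make_series(pre=(), inpatient=(), post=(), admit=ADMIT, discharge=DISCHARGE):
    """Series from (days_before_admission, value), (day_in_admission, value),
    (days_after_discharge, value) triples of tuples."""
    times, values = [], []
    for d, v in pre:
        times.append(admit - timedelta(days=d, hours=2))
        values.append(v)
    for d, v in inpatient:
        times.append(admit + timedelta(days=d, hours=1))
        values.append(v)
    for d, v in post:
        times.append(discharge + timedelta(days=d, hours=2))
        values.append(v)
    return CreatinineSeries(times=times, values=values, admission_ts=admit, discharge_ts=discharge)


def make_episode(**kwargs):
    defaults = dict(
        episode_id="E1",
        age_years=83.0,
        sex="F",
        ethnicity="non_black",
        admit_ts=ADMIT,
        discharge_ts=DISCHARGE,
        admitted_from_home=1,
        amts=9,
        admission_hb_g_per_l=120.0,
    )
    defaults.update(kwargs)
    return PatientEpisode(**defaults)


@pytest.fixture
def episode():
    return make_episode()
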