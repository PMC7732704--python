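import logging

import numpy as np
import pytest
from hypothesis import settings

from mhengage.event_model import EventRecord, EventStream

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

logging.getLogger("mhengage").setLevel(logging.ERROR)


def make_record(
    install_id="u1",
    ts=1_533_081_600_000,
    event="other",
    duration_s=1.0,
    area=None,
    payload=None,
):
    return EventRecord(
        install_id=install_id,
        timestamp=ts,
        event_name=event,
        duration_s=duration_s,
        content_area=area,
        payload=payload,
    )


def make_events(gaps_s, install_id="u1", t0=1_533_081_600_000, duration_s=1.0):
    """One record at t0 then one after each gap (seconds)."""
    ts = t0
    out = [make_record(install_id, ts, duration_s=duration_s)]
    for g in gaps_s:
        ts += int(g * 1000)
        out.append(make_record(install_id, ts, duration_s=duration_s))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_user_stream():
    """Hand-built stream: user a has 2 visits (gap 2 h) and accepted the
    license; user b never accepted."""
    t0 = 1_533_081_600_000
    recs = [
        make_record("a", t0, "launch", 5.0, payload={"platform": "android"}),
        make_record("a", t0 + 10_000, "eula_accepted", 2.0),
        make_record("a", t0 + 20_000, "screen_view", 30.0, area="home"),
        make_record("a", t0 + 40_000, "screen_view", 60.0, area="training_plan"),
        # second visit 2 hours later
        make_record("a", t0 + 7_200_000, "launch", 5.0, payload={"platform": "android"}),
        make_record("a", t0 + 7_210_000, "screen_view", 0.0, area="home"),
        make_record("a", t0 + 7_220_000, "screen_view", 45.0, area="practice_now"),
        make_record("b", t0 + 100_000, "launch", 3.0, payload={"platform": "ios"}),
        make_record("b", t0 + 110_000, "screen_view", 10.0, area="home"),
    ]
    return EventStream.from_records(recs, source="fixture")
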