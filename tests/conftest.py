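from __future__ import annotations

from datetime import date, datetime, timedelta

import pytest

from rhythmkit import AlgorithmConfig, RawEvent
from rhythmkit.events import NonUsageEpisode


@pytest.fixture
def cfg() -> AlgorithmConfig:
    return AlgorithmConfig()


def dt(day: int, h: int, m: int = 0, s: int = 0) -> datetime:
    """Shorthand: day offset from 2018-02-05 (a Monday) + clock time."""
    return datetime(2018, 2, 5 + day, h, m, s) if day < 24 else datetime(
        2018, 3, day - 23, h, m, s
    )


@pytest.fixture
def mkdt():
    return dt


def gap(start: datetime, end: datetime, **kw) -> NonUsageEpisode:
    return NonUsageEpisode(start=start, end=end, **kw)


@pytest.fixture
def mkgap():
    return gap


def screen_session(on: datetime, off: datetime) -> list[RawEvent]:
    return [RawEvent(on, "screen_on"), RawEvent(off, "screen_off")]
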