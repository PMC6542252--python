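"""Nightly sleep detection from non-usage episodes.

The rule: within the nightly window (22:00 to 10:00 the next morning by
default) the **maximal non-usage episode** is the night's sleep.  Episodes
crossing the window edges first get *dummy* boundaries — a provisional
screen-off at 22:00 and/or screen-on at 10:00 — so that the comparison is
between within-window durations; if the winner carries a dummy boundary,
the original screen-off/screen-on outside the window is resumed as the true
sleep onset / wake time.  This lets a 21:30 bedtime or an 11:00 lie-in be
recovered while still anchoring the search to the night.

Resumption is bounded by a per-night scan window (noon to next noon by
default) so it can never wander into the previous afternoon's nap.

One record per night, keyed by the morning's calendar date (``wake_date``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from typing import Sequence

from .config import AlgorithmConfig
from .events import NonUsageEpisode, RawEvent, preprocess_events

__all__ = [
    "SleepRecord",
    "SleepSeries",
    "midpoint_of",
    "make_sleep_record",
    "night_window",
    "scan_window",
    "label_dummy_boundaries",
    "detect_sleep",
    "detect_series",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SleepRecord:
    """One night's inferred sleep, keyed by the morning's date."""

    wake_date: date
    onset: datetime
    wake: datetime
    midpoint: datetime
    tst_s: int
    onset_extended: bool = False  # onset resumed to before the window start
    wake_extended: bool = False  # wake resumed to after the window end
    source: str = "app"  # app | self_report
    n_candidates: int = 0
    tie: bool = False

    def __post_init__(self) -> None:
        if self.onset >= self.wake:
            raise ValueError("sleep record requires onset < wake")
        if self.tst_s != int((self.wake - self.onset).total_seconds()):
            raise ValueError("tst_s inconsistent with onset/wake")


@dataclass
class SleepSeries:
    """Ordered multi-night record collection for one participant."""

    participant_id: str
    records: list[SleepRecord] = field(default_factory=list)
    missing_nights: list[date] = field(default_factory=list)

    def __post_init__(self) -> None:
        dates = [r.wake_date for r in self.records]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("records must have strictly increasing wake_dates")

    def by_wake_date(self) -> dict[date, SleepRecord]:
        return {r.wake_date: r for r in self.records}


def midpoint_of(onset: datetime, wake: datetime) -> datetime:
    """Clock time halfway through sleep, on the whole-second grid.

    The half-duration is floored to whole seconds, so a 2-second sleep has
    its midpoint 1 second after onset and an odd duration rounds to the
    earlier second.
    """
    if onset >= wake:
        raise ValueError("midpoint requires onset < wake")
    total = int((wake - onset).total_seconds())
    return onset + timedelta(seconds=total // 2)


def make_sleep_record(
    onset: datetime,
    wake: datetime,
    wake_date: date,
    source: str = "app",
    **extra,
) -> SleepRecord:
    """Build a record with midpoint and TST derived from the boundaries."""
    tst = int((wake - onset).total_seconds())
    return SleepRecord(
        wake_date=wake_date,
        onset=onset,
        wake=wake,
        midpoint=midpoint_of(onset, wake),
        tst_s=tst,
        source=source,
        **extra,
    )


def night_window(night: date, cfg: AlgorithmConfig) -> tuple[datetime, datetime]:
    """The sleep-search window for the night starting on the evening of `night`."""
    w0 = datetime.combine(night, cfg.window_start)
    end_day = night + timedelta(days=1) if cfg.window_end <= cfg.window_start else night
    return w0, datetime.combine(end_day, cfg.window_end)


def scan_window(night: date, cfg: AlgorithmConfig) -> tuple[datetime, datetime]:
    """Bounds on candidate episodes (and boundary resumption) for one night."""
    s0 = datetime.combine(night, cfg.scan_start)
    end_day = night + timedelta(days=1) if cfg.scan_end <= cfg.scan_start else night
    return s0, datetime.combine(end_day, cfg.scan_end)


def label_dummy_boundaries(
    episodes: Sequence[NonUsageEpisode], night: date, cfg: AlgorithmConfig | None = None
) -> list[NonUsageEpisode]:
    """Clip episodes to the nightly window, remembering the original boundaries.

    An episode whose screen-off precedes the window start gets a dummy start
    at 22:00 (original kept); symmetrically a late screen-on gets a dummy
    end at 10:00.  Episodes not overlapping the window are dropped.
    """
    cfg = cfg or AlgorithmConfig()
    w0, w1 = night_window(night, cfg)
    labeled: list[NonUsageEpisode] = []
    for ep in episodes:
        if ep.end <= w0 or ep.start >= w1:
            continue
        new = ep
        if ep.start < w0:
            new = replace(new, start=w0, start_is_dummy=True, original_start=ep.original_start)
        if ep.end > w1:
            new = replace(new, end=w1, end_is_dummy=True, original_end=ep.original_end)
        labeled.append(new)
    return labeled


def detect_sleep(
    episodes: Sequence[NonUsageEpisode],
    night: date,
    cfg: AlgorithmConfig | None = None,
) -> SleepRecord | None:
    """Pick the maximal (dummy-labeled) episode and resume its true boundaries.

    ``episodes`` must already be labeled by :func:`label_dummy_boundaries`.
    Ties in clipped duration go to the earliest-starting episode (logged and
    flagged on the record).  Returns ``None`` for a missing night.
    """
    cfg = cfg or AlgorithmConfig()
    if not episodes:
        return None
    best = max(episodes, key=lambda e: (e.duration_s, -e.start.timestamp()))
    n_max = sum(1 for e in episodes if e.duration_s == best.duration_s)
    if n_max > 1:
        logger.info(
            "night %s: %d equal maximal episodes; keeping the earliest", night, n_max
        )
    onset = best.original_start if best.start_is_dummy else best.start
    wake = best.original_end if best.end_is_dummy else best.end
    record = make_sleep_record(
        onset=onset,
        wake=wake,
        wake_date=night + timedelta(days=1),
        onset_extended=bool(best.start_is_dummy and onset < best.start),
        wake_extended=bool(best.end_is_dummy and wake > best.end),
        n_candidates=len(episodes),
        tie=n_max > 1,
    )
    if record.tst_s < cfg.min_sleep_floor_s:
        logger.warning(
            "night %s: detected sleep of %.1f h is below the %.1f h floor",
            night,
            record.tst_s / 3600,
            cfg.min_sleep_floor_s / 3600,
        )
    return record


def _clamp_to_scan(
    episodes: Sequence[NonUsageEpisode], s0: datetime, s1: datetime
) -> list[NonUsageEpisode]:
    """Restrict episodes (and their resumable originals) to one scan window."""
    out: list[NonUsageEpisode] = []
    for ep in episodes:
        if ep.end <= s0 or ep.start >= s1:
            continue
        out.append(
            NonUsageEpisode(
                start=max(ep.start, s0),
                end=min(ep.end, s1),
                original_start=max(ep.original_start, s0),
                original_end=min(ep.original_end, s1),
            )
        )
    return out


def detect_series(
    events: Sequence[RawEvent],
    participant_id: str,
    cfg: AlgorithmConfig | None = None,
) -> SleepSeries:
    """Run the full pipeline over a multi-day log: one record per night.

    Nights are indexed by wake date; the span's first and last calendar days
    are excluded by default (field logs are incomplete on install/uninstall
    days).  Nights with no usable non-usage episode are reported in
    ``missing_nights`` rather than interpolated.
    """
    cfg = cfg or AlgorithmConfig()
    if not events:
        logger.warning("participant %s: empty event log", participant_id)
        return SleepSeries(participant_id=participant_id)
    gaps, _ = preprocess_events(events, cfg)
    first_day = min(ev.timestamp for ev in events).date()
    last_day = max(ev.timestamp for ev in events).date()
    wake_dates: list[date] = []
    d = first_day + timedelta(days=1)
    while d <= last_day:
        wake_dates.append(d)
        d += timedelta(days=1)
    if cfg.exclude_first_last_days and wake_dates and wake_dates[-1] == last_day:
        wake_dates = wake_dates[:-1]
    records: list[SleepRecord] = []
    missing: list[date] = []
    for wake_date in wake_dates:
        night = wake_date - timedelta(days=1)
        s0, s1 = scan_window(night, cfg)
        candidates = _clamp_to_scan(gaps, s0, s1)
        labeled = label_dummy_boundaries(candidates, night, cfg)
        record = detect_sleep(labeled, night, cfg)
        if record is None:
            missing.append(wake_date)
        else:
            records.append(record)
    return SleepSeries(
        participant_id=participant_id, records=records, missing_nights=missing
    )
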