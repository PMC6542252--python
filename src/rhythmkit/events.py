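"""Event-log parsing and episode construction.

The raw material is a per-participant stream of three event types recorded
at 1-second resolution: ``screen_on``, ``screen_off`` and ``notification``
(the latter tagged with an app identifier).  From it we build

* *usage episodes* — screen-on to the successive screen-off;
* a proactive/reactive label per usage episode: an episode is **reactive**
  when some notification arrived within a short lookback (default 60 s)
  before screen-on, i.e. the user plausibly picked the phone up in response;
  otherwise it is **proactive**;
* *non-usage episodes* — the gaps between consecutive *proactive* episodes.
  Reactive episodes are invisible here: a brief externally-triggered check
  at night must not split the surrounding sleep candidate.

Before classification, notification "floods" are removed: for any app that
posts more than ``flood_threshold`` notifications on one calendar day
(default 500), all of that app's notifications on that day are dropped, so
that a constantly-buzzing app cannot relabel genuinely proactive use as
reactive.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import math
from bisect import bisect_left
from collections import Counter
from dataclasses import dataclass, replace
from datetime import datetime, timedelta, timezone as _tz
from pathlib import Path
from typing import IO, Iterable, Sequence
from zoneinfo import ZoneInfo

from .config import AlgorithmConfig
from .exceptions import EventLogError

__all__ = [
    "RawEvent",
    "UsageEpisode",
    "NonUsageEpisode",
    "EVENT_TYPES",
    "sort_events",
    "parse_event_log",
    "filter_notification_floods",
    "build_usage_episodes",
    "classify_proactive",
    "classify_episodes",
    "build_nonusage_episodes",
    "preprocess_events",
]

logger = logging.getLogger(__name__)

EVENT_TYPES = frozenset({"screen_on", "screen_off", "notification"})

# Tie-break rank for simultaneous events: a zero-gap off/on pair at the same
# second must still order off < on so it yields an empty, discarded gap.
_TIE_RANK = {"screen_off": 0, "notification": 1, "screen_on": 2}


@dataclass(frozen=True)
class RawEvent:
    """One timestamped device event (whole-second resolution)."""

    timestamp: datetime
    event_type: str
    app_id: str | None = None

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event_type {self.event_type!r}")
        if self.event_type == "notification" and not self.app_id:
            raise ValueError("notification events require a non-empty app_id")


@dataclass(frozen=True)
class UsageEpisode:
    """Screen-on to the successive screen-off; ``proactive`` set by classification."""

    on_time: datetime
    off_time: datetime
    proactive: bool | None = None

    def __post_init__(self) -> None:
        if self.on_time >= self.off_time:
            raise ValueError("usage episode requires on_time < off_time")

    @property
    def duration_s(self) -> int:
        return int((self.off_time - self.on_time).total_seconds())


@dataclass(frozen=True)
class NonUsageEpisode:
    """Gap from a (proactive) screen-off to the next (proactive) screen-on.

    ``start``/``end`` may be replaced by dummy window boundaries during
    sleep detection; the pre-replacement values are kept in ``original_*``
    so the winning episode's true boundaries can be resumed.
    """

    start: datetime
    end: datetime
    start_is_dummy: bool = False
    end_is_dummy: bool = False
    original_start: datetime | None = None
    original_end: datetime | None = None

    def __post_init__(self) -> None:
        if self.original_start is None:
            object.__setattr__(self, "original_start", self.start)
        if self.original_end is None:
            object.__setattr__(self, "original_end", self.end)
        if self.start >= self.end:
            raise ValueError("non-usage episode requires start < end")
        if self.start_is_dummy and self.original_start > self.start:
            raise ValueError("dummy start must not precede the original screen-off")
        if self.end_is_dummy and self.original_end < self.end:
            raise ValueError("dummy end must not follow the original screen-on")

    @property
    def duration_s(self) -> int:
        return int((self.end - self.start).total_seconds())


def _sort_key(ev: RawEvent) -> tuple[datetime, int]:
    return (ev.timestamp, _TIE_RANK[ev.event_type])


def sort_events(events: Iterable[RawEvent]) -> list[RawEvent]:
    """Stable sort by timestamp with the off < notification < on tiebreak."""
    return sorted(events, key=_sort_key)


def _parse_timestamp(raw: object, tz: str | None) -> datetime:
    """ISO-8601 string or epoch seconds -> naive local datetime, whole seconds."""
    if isinstance(raw, (int, float)) and not isinstance(raw, bool):
        if not math.isfinite(raw):
            raise ValueError(f"non-finite timestamp {raw!r}")
        zone = ZoneInfo(tz) if tz else _tz.utc
        dt = datetime.fromtimestamp(float(raw), tz=zone)
        return dt.replace(tzinfo=None, microsecond=0)
    text = str(raw).strip()
    if not text:
        raise ValueError("empty timestamp")
    try:
        value = float(text)
    except ValueError:
        pass
    else:
        return _parse_timestamp(value, tz)
    dt = datetime.fromisoformat(text.replace("Z", "+00:00"))
    if dt.tzinfo is not None:
        zone = ZoneInfo(tz) if tz else _tz.utc
        dt = dt.astimezone(zone).replace(tzinfo=None)
    return dt.replace(microsecond=0)


def _event_from_record(record: dict, tz: str | None) -> RawEvent:
    if "timestamp" not in record or record["timestamp"] in (None, ""):
        raise ValueError("missing timestamp")
    if "event_type" not in record or not record["event_type"]:
        raise ValueError("missing event_type")
    ts = _parse_timestamp(record["timestamp"], tz)
    etype = str(record["event_type"]).strip()
    if etype not in EVENT_TYPES:
        raise ValueError(f"unknown event_type {etype!r}")
    app_id = record.get("app_id") or None
    if etype == "notification" and app_id is None:
        raise ValueError("notification without app_id")
    if etype != "notification":
        app_id = None
    return RawEvent(ts, etype, app_id)


def parse_event_log(
    source: str | Path | IO[str],
    fmt: str = "csv",
    strict: bool = False,
    tz: str | None = None,
) -> list[RawEvent]:
    """Parse a CSV or JSON-lines event log into sorted :class:`RawEvent`s.

    Malformed rows are reported with their line numbers: logged and skipped
    by default, fatal (:class:`EventLogError`) when ``strict`` is true.
    """
    if fmt not in ("csv", "jsonl"):
        raise ValueError(f"unknown event-log format {fmt!r}")
    close = False
    if isinstance(source, (str, Path)):
        try:
            stream: IO[str] = open(source, "r", newline="")
        except OSError as exc:
            raise EventLogError(f"cannot read event log {source}: {exc}") from exc
        close = True
    else:
        stream = source
    events: list[RawEvent] = []
    problems: list[tuple[int, str]] = []
    try:
        if fmt == "csv":
            reader = csv.DictReader(stream)
            for lineno, row in enumerate(reader, start=2):  # line 1 = header
                try:
                    events.append(_event_from_record(row, tz))
                except (ValueError, KeyError) as exc:
                    problems.append((lineno, str(exc)))
        else:
            for lineno, line in enumerate(stream, start=1):
                if not line.strip():
                    continue
                try:
                    events.append(_event_from_record(json.loads(line), tz))
                except (ValueError, KeyError) as exc:
                    problems.append((lineno, str(exc)))
    finally:
        if close:
            stream.close()
    if problems:
        for lineno, msg in problems:
            logger.warning("malformed event record at line %d: %s", lineno, msg)
        if strict:
            detail = "; ".join(f"line {n}: {m}" for n, m in problems[:10])
            raise EventLogError(
                f"{len(problems)} malformed event record(s): {detail}", problems
            )
    if not events:
        logger.warning("event log is empty")
    return sort_events(events)


def filter_notification_floods(
    events: Sequence[RawEvent], cfg: AlgorithmConfig | None = None
) -> list[RawEvent]:
    """Drop all notifications of any (app, calendar day) exceeding the flood threshold.

    Pure filter: screen events pass through untouched, ordering is preserved,
    and applying it twice equals applying it once.
    """
    cfg = cfg or AlgorithmConfig()
    counts: Counter[tuple[str, object]] = Counter()
    for ev in events:
        if ev.event_type == "notification":
            counts[(ev.app_id, ev.timestamp.date())] += 1
    flooded = {key for key, n in counts.items() if n > cfg.flood_threshold}
    if not flooded:
        return list(events)
    kept = [
        ev
        for ev in events
        if ev.event_type != "notification"
        or (ev.app_id, ev.timestamp.date()) not in flooded
    ]
    removed = len(events) - len(kept)
    logger.info(
        "flood filter removed %d notifications from %d (app, day) groups",
        removed,
        len(flooded),
    )
    return kept


def build_usage_episodes(events: Sequence[RawEvent]) -> list[UsageEpisode]:
    """Pair each screen-on with the next screen-off.

    Glitch repairs (all logged): a second screen-on before any screen-off
    restarts the episode at the later on; a screen-off with no open episode
    is ignored; a trailing unmatched screen-on is discarded.  Zero-duration
    pairs (same-second on/off) are dropped.
    """
    episodes: list[UsageEpisode] = []
    pending_on: datetime | None = None
    repairs = 0
    for ev in events:
        if ev.event_type == "screen_on":
            if pending_on is not None:
                repairs += 1
                logger.warning(
                    "consecutive screen_on at %s; restarting episode", ev.timestamp
                )
            pending_on = ev.timestamp
        elif ev.event_type == "screen_off":
            if pending_on is None:
                repairs += 1
                logger.warning(
                    "screen_off at %s with no open episode; ignored", ev.timestamp
                )
            elif ev.timestamp > pending_on:
                episodes.append(UsageEpisode(pending_on, ev.timestamp))
                pending_on = None
            else:
                repairs += 1
                logger.warning(
                    "zero-duration episode at %s dropped", ev.timestamp
                )
                pending_on = None
    if pending_on is not None:
        repairs += 1
        logger.warning("trailing unmatched screen_on at %s discarded", pending_on)
    if repairs:
        logger.info("usage-episode construction made %d repairs", repairs)
    return episodes


def classify_proactive(
    episode: UsageEpisode,
    notification_times: Sequence[datetime],
    cfg: AlgorithmConfig | None = None,
) -> bool:
    """True (proactive) iff no notification falls in ``[on - lookback, on)``.

    ``notification_times`` must be sorted and already flood-filtered.  The
    interval is half-open: a notification exactly ``lookback`` seconds before
    screen-on makes the episode reactive; one at the same second as screen-on
    does not (it did not precede the screen-on).
    """
    cfg = cfg or AlgorithmConfig()
    lo = episode.on_time - timedelta(seconds=cfg.reactive_lookback_s)
    i = bisect_left(notification_times, lo)
    j = bisect_left(notification_times, episode.on_time)
    return i == j


def classify_episodes(
    episodes: Sequence[UsageEpisode],
    events: Sequence[RawEvent],
    cfg: AlgorithmConfig | None = None,
) -> list[UsageEpisode]:
    """Attach proactive/reactive labels using the (flood-filtered) notifications."""
    notif_times = sorted(
        ev.timestamp for ev in events if ev.event_type == "notification"
    )
    return [
        replace(ep, proactive=classify_proactive(ep, notif_times, cfg))
        for ep in episodes
    ]


def build_nonusage_episodes(
    proactive_episodes: Sequence[UsageEpisode],
) -> list[NonUsageEpisode]:
    """Gaps between consecutive proactive episodes.

    Input episodes must be classified; reactive ones are dropped here, so a
    reactive nocturnal check never starts or ends a non-usage episode.
    Fewer than two proactive episodes yield an empty list (a missing night
    for the caller).  Zero-length gaps (same-second off/on) are discarded.
    """
    kept = []
    for ep in proactive_episodes:
        if ep.proactive is None:
            raise ValueError("episodes must be classified before gap construction")
        if ep.proactive:
            kept.append(ep)
    gaps: list[NonUsageEpisode] = []
    for prev, nxt in zip(kept, kept[1:]):
        if nxt.on_time > prev.off_time:
            gaps.append(NonUsageEpisode(start=prev.off_time, end=nxt.on_time))
    return gaps


def preprocess_events(
    events: Sequence[RawEvent], cfg: AlgorithmConfig | None = None
) -> tuple[list[NonUsageEpisode], list[UsageEpisode]]:
    """Full event-model pipeline: sort, flood-filter, pair, classify, gap.

    Returns the non-usage episodes (candidates for sleep detection) and the
    classified usage episodes.
    """
    cfg = cfg or AlgorithmConfig()
    ordered = sort_events(events)
    filtered = filter_notification_floods(ordered, cfg)
    usage = build_usage_episodes(filtered)
    usage = classify_episodes(usage, filtered, cfg)
    return build_nonusage_episodes(usage), usage
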