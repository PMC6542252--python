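"""Synthetic smartphone event-log cohorts with known true sleep.

The generator emulates the behavioral assumptions behind screen-event sleep
detection: each participant has a chronotype (a baseline sleep midpoint and
duration), nights drawn around it with a weekend phase delay, waking hours
filled with phone sessions as a renewal process, per-app notification
streams including one "flooding" app, optional nocturnal *reactive* checks
(a notification followed seconds later by a brief screen-on), and a nightly
self-report derived from the true sleep interval through fixed biases plus
Gaussian noise.

Default parameters describe a late-chronotype student cohort: 28
participants over 32 days, mean midpoint 04:54 and mean sleep 6.92 h,
about 5.7 h of daily screen time, and self-reports whose onset is 4 min
earlier and wake 10.4 min later than the device record.

Randomness is split into independent named substreams (sleep, sessions,
notifications, flood, checks, self-report) seeded per participant, so
switching one process on or off leaves every other draw untouched — the
basis of the paired-seed invisibility tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Iterable, Sequence

import numpy as np

from .config import AlgorithmConfig
from .events import RawEvent, sort_events
from .exceptions import SimulationError
from .sleep import SleepSeries, make_sleep_record

__all__ = [
    "SimParams",
    "GroundTruthNight",
    "ParticipantSim",
    "CohortSim",
    "simulate_participant",
    "simulate_cohort",
]

_CHECK_APP = "im.messenger"
_FLOOD_APP = "promo.flood"

# True boundaries are kept inside the detectable range (after the previous
# afternoon, before the next noon) with margins for the anchor sessions.
_ONSET_MIN_S = -4 * 3600 - 1800  # 19:30 the evening before the wake date
_ONSET_MAX_S = 4 * 3600  # 04:00
_WAKE_MIN_S = 6 * 3600  # 06:00
_WAKE_MAX_S = 11 * 3600 + 1800  # 11:30


@dataclass(frozen=True)
class SimParams:
    """Cohort-level simulation settings.  Times of day as ``datetime.time``."""

    n_participants: int = 28
    n_days: int = 32
    start_date: date = date(2018, 2, 5)  # a Monday
    midpoint_mean: time = time(4, 54)
    midpoint_sd_min: float = 45.0  # night-to-night
    participant_midpoint_sd_min: float = 90.0  # between-participant chronotype spread
    tst_mean_h: float = 6.92
    tst_sd_min: float = 60.0
    participant_tst_sd_min: float = 45.0
    weekend_shift_min: float = 30.0  # ground-truth social jetlag
    pre_sleep_gap_min: float = 0.0  # last phone use ends this long before true onset
    post_wake_gap_min: float = 0.0  # first phone use starts this long after true wake
    daytime_session_rate_per_h: float = 4.0
    session_duration_s: float = 300.0  # mean of exponential session lengths
    nocturnal_check_prob: float = 0.25  # reactive mid-sleep check per night
    n_apps: int = 5
    notification_rate_per_app: float = 20.0  # per day
    flood_app_rate: float = 600.0  # per day; 0 disables the flooding app
    self_report_onset_bias_min: float = -4.0
    self_report_wake_bias_min: float = 10.4
    self_report_noise_sd_min: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1 or self.n_days < 2:
            raise SimulationError("need >= 1 participant and >= 2 days")
        for name in (
            "midpoint_sd_min",
            "participant_midpoint_sd_min",
            "tst_sd_min",
            "participant_tst_sd_min",
            "pre_sleep_gap_min",
            "post_wake_gap_min",
            "daytime_session_rate_per_h",
            "session_duration_s",
            "notification_rate_per_app",
            "flood_app_rate",
            "self_report_noise_sd_min",
        ):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if not 0.0 <= self.nocturnal_check_prob <= 1.0:
            raise SimulationError("nocturnal_check_prob must be in [0, 1]")
        if not 1.0 <= self.tst_mean_h < 20.0:
            raise SimulationError("tst_mean_h must leave room for waking hours")
        if self.daytime_session_rate_per_h <= 0:
            raise SimulationError("daytime_session_rate_per_h must be > 0")

    def replace(self, **overrides) -> "SimParams":
        return dataclasses.replace(self, **overrides)

    @classmethod
    def from_dict(cls, data: dict) -> "SimParams":
        """Build from a plain mapping (e.g. YAML), coercing date/time strings."""
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SimulationError(f"unknown simulator parameters: {sorted(unknown)}")
        coerced = dict(data)
        if isinstance(coerced.get("start_date"), str):
            coerced["start_date"] = date.fromisoformat(coerced["start_date"])
        if isinstance(coerced.get("midpoint_mean"), str):
            coerced["midpoint_mean"] = time.fromisoformat(coerced["midpoint_mean"])
        return cls(**coerced)

    @classmethod
    def noise_free(cls, **overrides) -> "SimParams":
        """Study conditions minus every process that can perturb detection.

        No notifications (so every session is proactive), no flooding app,
        no nocturnal checks, no self-report bias or noise, zero pre/post
        gaps: detection recovers ground truth exactly, by construction.
        """
        base = cls(
            nocturnal_check_prob=0.0,
            notification_rate_per_app=0.0,
            flood_app_rate=0.0,
            pre_sleep_gap_min=0.0,
            post_wake_gap_min=0.0,
            self_report_onset_bias_min=0.0,
            self_report_wake_bias_min=0.0,
            self_report_noise_sd_min=0.0,
        )
        return base.replace(**overrides)

    @classmethod
    def bias_recovery(cls, **overrides) -> "SimParams":
        """Parameter-recovery scenario for the self-report bias/noise model.

        Detection-perturbing processes are off (as in :meth:`noise_free`)
        so the device record equals truth, while the self-report keeps its
        default biases and noise; recovered paired differences then estimate
        exactly the configured biases, and the app-self midpoint correlation
        follows the analytic attenuation of the configured noise SD.
        """
        base = cls(
            notification_rate_per_app=0.0,
            flood_app_rate=0.0,
            pre_sleep_gap_min=0.0,
            post_wake_gap_min=0.0,
        )
        return base.replace(**overrides)


@dataclass(frozen=True)
class GroundTruthNight:
    """True sleep interval for one participant-night, plus its self-report."""

    participant_id: str
    wake_date: date
    onset: datetime
    wake: datetime
    self_onset: datetime
    self_wake: datetime

    @property
    def tst_s(self) -> int:
        return int((self.wake - self.onset).total_seconds())


@dataclass
class ParticipantSim:
    participant_id: str
    events: list[RawEvent]
    truth: list[GroundTruthNight]

    def truth_series(self, wake_dates: Iterable[date] | None = None) -> SleepSeries:
        keep = None if wake_dates is None else set(wake_dates)
        records = [
            make_sleep_record(n.onset, n.wake, n.wake_date, source="truth")
            for n in self.truth
            if keep is None or n.wake_date in keep
        ]
        return SleepSeries(self.participant_id, records)

    def self_report_series(
        self, wake_dates: Iterable[date] | None = None
    ) -> SleepSeries:
        keep = None if wake_dates is None else set(wake_dates)
        records = [
            make_sleep_record(
                n.self_onset, n.self_wake, n.wake_date, source="self_report"
            )
            for n in self.truth
            if keep is None or n.wake_date in keep
        ]
        return SleepSeries(self.participant_id, records)


@dataclass
class CohortSim:
    params: SimParams
    participants: list[ParticipantSim] = field(default_factory=list)


def _round_s(dt: datetime) -> datetime:
    return dt.replace(microsecond=0)


def _draw_nights(
    params: SimParams, rng: np.random.Generator, n_nights: int
) -> list[tuple[datetime, datetime]]:
    """True (onset, wake) per night index i; wake date = start + (i) days.

    Index 0 is a virtual pre-study night whose wake starts the first day's
    usage; indices 1..n_nights are the recorded nights.
    """
    mid_mean_s = (
        params.midpoint_mean.hour * 3600
        + params.midpoint_mean.minute * 60
        + params.midpoint_mean.second
    )
    base_mid = mid_mean_s + rng.normal() * params.participant_midpoint_sd_min * 60
    base_tst = params.tst_mean_h * 3600 + rng.normal() * params.participant_tst_sd_min * 60
    jitter = rng.normal(size=(n_nights + 1, 2))
    nights: list[tuple[datetime, datetime]] = []
    for i in range(n_nights + 1):
        wake_date = params.start_date + timedelta(days=i)
        mid = base_mid + jitter[i, 0] * params.midpoint_sd_min * 60
        if wake_date.weekday() >= 5:
            mid += params.weekend_shift_min * 60
        tst = base_tst + jitter[i, 1] * params.tst_sd_min * 60
        onset_s = float(np.clip(mid - tst / 2, _ONSET_MIN_S, _ONSET_MAX_S))
        wake_s = float(np.clip(mid + tst / 2, _WAKE_MIN_S, _WAKE_MAX_S))
        ref = datetime.combine(wake_date, time(0))
        onset = ref + timedelta(seconds=round(onset_s))
        wake = ref + timedelta(seconds=round(wake_s))
        if nights and onset <= nights[-1][1] + timedelta(minutes=10):
            raise SimulationError(
                f"night waking {wake_date} overlaps the previous night"
            )
        nights.append((onset, wake))
    return nights


def _session_events(
    params: SimParams,
    rng: np.random.Generator,
    nights: Sequence[tuple[datetime, datetime]],
    log_end: datetime,
) -> list[RawEvent]:
    """Fill every waking window with sessions: anchors at both ends plus a
    renewal stream between them."""

    def dur() -> timedelta:
        return timedelta(seconds=int(np.clip(rng.exponential(params.session_duration_s), 5, 3600)))

    def gap() -> timedelta:
        g = rng.exponential(3600.0 / params.daytime_session_rate_per_h)
        return timedelta(seconds=max(1, round(g)))

    pre_gap = timedelta(seconds=round(params.pre_sleep_gap_min * 60))
    post_gap = timedelta(seconds=round(params.post_wake_gap_min * 60))
    events: list[RawEvent] = []

    def add_session(on: datetime, off: datetime) -> None:
        if off > on:
            events.append(RawEvent(_round_s(on), "screen_on"))
            events.append(RawEvent(_round_s(off), "screen_off"))

    for i, (_, wake) in enumerate(nights):
        window_start = wake + post_gap
        next_onset = nights[i + 1][0] if i + 1 < len(nights) else None
        window_end = (next_onset - pre_gap) if next_onset is not None else log_end
        if window_end <= window_start:
            continue
        # Morning anchor: first use exactly post_gap after waking.
        morning_off = min(window_start + dur(), window_end)
        add_session(window_start, morning_off)
        # Bedtime anchor: last use ends exactly pre_gap before the next onset.
        if next_onset is not None:
            bed_on = max(window_end - dur(), morning_off + timedelta(seconds=1))
            cursor_limit = bed_on - timedelta(seconds=60)
        else:
            bed_on = None
            cursor_limit = window_end
        t = morning_off
        while True:
            s = t + gap()
            e = s + dur()
            if e >= cursor_limit:
                break
            add_session(s, e)
            t = e
        if bed_on is not None and window_end > bed_on:
            add_session(bed_on, window_end)
    return events


def _notification_events(
    params: SimParams, rng: np.random.Generator, log_start: datetime, total_days: int
) -> list[RawEvent]:
    events: list[RawEvent] = []
    horizon = total_days * 86400
    for j in range(params.n_apps):
        n = rng.poisson(params.notification_rate_per_app * total_days)
        offsets = np.sort(rng.uniform(0, horizon, size=n))
        app = f"app.{j:02d}"
        for off in offsets:
            events.append(
                RawEvent(log_start + timedelta(seconds=int(off)), "notification", app)
            )
    return events


def _flood_events(
    params: SimParams, rng: np.random.Generator, log_start: datetime, total_days: int
) -> list[RawEvent]:
    if params.flood_app_rate <= 0:
        return []
    events: list[RawEvent] = []
    for d in range(total_days):
        # Always above the 500/day exclusion threshold, by construction.
        n = max(501, int(rng.poisson(params.flood_app_rate)))
        offsets = np.sort(rng.uniform(0, 86400, size=n))
        day_start = log_start + timedelta(days=d)
        for off in offsets:
            events.append(
                RawEvent(
                    day_start + timedelta(seconds=int(off)), "notification", _FLOOD_APP
                )
            )
    return events


def _check_events(
    params: SimParams,
    rng: np.random.Generator,
    nights: Sequence[tuple[datetime, datetime]],
) -> list[RawEvent]:
    """Reactive nocturnal checks: notification, screen-on 10-50 s later, brief use."""
    events: list[RawEvent] = []
    for onset, wake in nights:
        if rng.uniform() >= params.nocturnal_check_prob:
            continue
        lo = onset + timedelta(minutes=30)
        hi = wake - timedelta(minutes=30)
        if hi <= lo:
            continue
        t = lo + timedelta(seconds=int(rng.uniform(0, (hi - lo).total_seconds())))
        delta = int(rng.uniform(10, 51))
        use = int(rng.uniform(30, 121))
        events.append(RawEvent(t, "notification", _CHECK_APP))
        events.append(RawEvent(t + timedelta(seconds=delta), "screen_on"))
        events.append(RawEvent(t + timedelta(seconds=delta + use), "screen_off"))
    return events


def simulate_participant(
    params: SimParams, participant_index: int
) -> ParticipantSim:
    """Generate one participant's event log and ground truth.

    Deterministic in ``(params.seed, participant_index)`` alone, so a
    participant's draws do not depend on cohort size or generation order.
    """
    params.validate()
    pid = f"p{participant_index:02d}"
    ss = np.random.SeedSequence(entropy=params.seed, spawn_key=(participant_index,))
    rngs = [np.random.default_rng(s) for s in ss.spawn(6)]
    rng_sleep, rng_sessions, rng_notif, rng_flood, rng_checks, rng_sr = rngs

    n_nights = params.n_days - 1  # wakes on days 1 .. n_days-1
    nights = _draw_nights(params, rng_sleep, n_nights)
    log_start = datetime.combine(params.start_date, time(0))
    log_end = log_start + timedelta(days=params.n_days) - timedelta(seconds=1)

    events = _session_events(params, rng_sessions, nights, log_end)
    events += _notification_events(params, rng_notif, log_start, params.n_days)
    events += _flood_events(params, rng_flood, log_start, params.n_days)
    events += _check_events(params, rng_checks, nights[1:])

    sr_noise = rng_sr.normal(size=(n_nights, 2))
    truth: list[GroundTruthNight] = []
    for i, (onset, wake) in enumerate(nights[1:]):
        self_onset = onset + timedelta(
            seconds=round(
                params.self_report_onset_bias_min * 60
                + sr_noise[i, 0] * params.self_report_noise_sd_min * 60
            )
        )
        self_wake = wake + timedelta(
            seconds=round(
                params.self_report_wake_bias_min * 60
                + sr_noise[i, 1] * params.self_report_noise_sd_min * 60
            )
        )
        if self_wake <= self_onset:
            self_wake = self_onset + timedelta(minutes=10)
        truth.append(
            GroundTruthNight(
                participant_id=pid,
                wake_date=wake.date(),
                onset=onset,
                wake=wake,
                self_onset=self_onset,
                self_wake=self_wake,
            )
        )
    return ParticipantSim(pid, sort_events(events), truth)


def simulate_cohort(params: SimParams) -> CohortSim:
    """Generate the full cohort (default: 28 participants x 32 days)."""
    params.validate()
    cohort = CohortSim(params=params)
    for idx in range(params.n_participants):
        cohort.participants.append(simulate_participant(params, idx))
    return cohort
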