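"""Agreement and circadian statistics.

Night-level agreement between two sleep records (typically app-detected vs
self-reported) is summarized by the **overlap ratio**:

    overlap_ratio = |a ∩ b| / ((|a| + |b|) / 2) × 100%

i.e. the intersection of the two sleep intervals over the mean of their
lengths.  Cohort-level comparisons use paired t tests on per-participant
means (n participants, df = n − 1), Pearson correlation of sleep midpoints
(pooled across all nights and/or one coefficient per study day), and
**social jetlag** — the absolute difference between mean weekend-night and
mean weeknight sleep midpoints, in minutes.

All indicator arithmetic is done on an "elapsed seconds since midnight"
scale anchored at 00:00 of the record's wake date, so an onset before
midnight is negative and continuity across midnight is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sleep import SleepRecord, SleepSeries

__all__ = [
    "NightPair",
    "PairedTestResult",
    "CorrelationResult",
    "AgreementReport",
    "INDICATORS",
    "indicator_seconds",
    "overlap_ratio",
    "overlap_ratio_records",
    "build_night_pairs",
    "pairs_to_frame",
    "paired_indicator_differences",
    "paired_differences_from_frame",
    "midpoint_correlation",
    "per_day_correlation",
    "social_jetlag",
    "social_jetlag_comparison",
    "sleep_efficiency",
    "compare_weeknight_weekend_overlap",
    "agreement_report",
    "is_weekend_night",
]

logger = logging.getLogger(__name__)

INDICATORS = ("onset", "wake", "midpoint", "tst")


def is_weekend_night(record: SleepRecord, basis: str = "wake_date") -> bool:
    """Weekend night = Sat/Sun morning (``wake_date``) or Sat/Sun evening (``onset_date``)."""
    if basis == "wake_date":
        return record.wake_date.weekday() >= 5
    if basis == "onset_date":
        return record.onset.date().weekday() >= 5
    raise ValueError("basis must be 'wake_date' or 'onset_date'")


@dataclass(frozen=True)
class NightPair:
    """A matched app-detected / self-reported night for one participant."""

    participant_id: str
    wake_date: date
    app: SleepRecord
    self_report: SleepRecord
    is_weekend_night: bool

    def __post_init__(self) -> None:
        if self.app.wake_date != self.self_report.wake_date:
            raise ValueError("paired records must share wake_date")


@dataclass(frozen=True)
class PairedTestResult:
    """Two-tailed paired t test on app − self differences."""

    mean_diff: float
    t: float | None
    p: float | None
    df: int
    n: int
    degenerate: bool = False  # zero variance of differences


@dataclass(frozen=True)
class CorrelationResult:
    r: float | None
    n: int
    note: str | None = None


def indicator_seconds(record: SleepRecord) -> dict[str, float]:
    """Onset/wake/midpoint as seconds since the wake date's midnight; TST in s.

    Onsets before midnight come out negative (e.g. 23:00 the evening before
    the wake date is −3600), keeping the scale continuous across midnight.
    """
    ref = datetime.combine(record.wake_date, time(0))
    return {
        "onset": (record.onset - ref).total_seconds(),
        "wake": (record.wake - ref).total_seconds(),
        "midpoint": (record.midpoint - ref).total_seconds(),
        "tst": float(record.tst_s),
    }


def overlap_ratio(
    a: tuple[datetime, datetime], b: tuple[datetime, datetime]
) -> float:
    """Intersection over mean length, in percent; 0 for disjoint intervals."""
    a0, a1 = a
    b0, b1 = b
    if a0 >= a1 or b0 >= b1:
        raise ValueError("overlap ratio requires non-degenerate intervals")
    inter = (min(a1, b1) - max(a0, b0)).total_seconds()
    inter = max(inter, 0.0)
    mean_len = ((a1 - a0) + (b1 - b0)).total_seconds() / 2.0
    return 100.0 * inter / mean_len


def overlap_ratio_records(app: SleepRecord, self_report: SleepRecord) -> float:
    return overlap_ratio((app.onset, app.wake), (self_report.onset, self_report.wake))


def build_night_pairs(
    app_series: SleepSeries,
    self_series: SleepSeries,
    weekend_basis: str = "wake_date",
) -> list[NightPair]:
    """Match records night-by-night on wake date; unmatched nights are logged."""
    app_by_date = app_series.by_wake_date()
    self_by_date = self_series.by_wake_date()
    shared = sorted(set(app_by_date) & set(self_by_date))
    unmatched = (len(app_by_date) - len(shared)) + (len(self_by_date) - len(shared))
    if unmatched:
        logger.info(
            "participant %s: %d unmatched nights dropped from pairing",
            app_series.participant_id,
            unmatched,
        )
    return [
        NightPair(
            participant_id=app_series.participant_id,
            wake_date=d,
            app=app_by_date[d],
            self_report=self_by_date[d],
            is_weekend_night=is_weekend_night(app_by_date[d], weekend_basis),
        )
        for d in shared
    ]


def pairs_to_frame(pairs: Sequence[NightPair]) -> pd.DataFrame:
    """Flatten pairs into one row per night with float-second indicators."""
    rows = []
    for p in pairs:
        row: dict[str, object] = {
            "participant_id": p.participant_id,
            "wake_date": p.wake_date,
            "is_weekend_night": p.is_weekend_night,
            "overlap_pct": overlap_ratio_records(p.app, p.self_report),
        }
        for prefix, rec in (("app", p.app), ("self", p.self_report)):
            for name, value in indicator_seconds(rec).items():
                row[f"{prefix}_{name}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


def _paired_t(app: np.ndarray, self_: np.ndarray) -> PairedTestResult:
    diff = np.asarray(app, dtype=float) - np.asarray(self_, dtype=float)
    n = diff.size
    if n < 2:
        raise ValueError("paired test requires at least 2 pairs")
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        # Degenerate: identical differences. All-zero -> t = 0, p = 1;
        # constant nonzero shift -> t undefined rather than +/-inf.
        if mean == 0.0:
            return PairedTestResult(0.0, 0.0, 1.0, n - 1, n, degenerate=True)
        return PairedTestResult(mean, None, None, n - 1, n, degenerate=True)
    t, p = stats.ttest_rel(app, self_)
    return PairedTestResult(mean, float(t), float(p), n - 1, n)


def paired_differences_from_frame(
    frame: pd.DataFrame, unit: Literal["participant", "night"] = "participant"
) -> dict[str, PairedTestResult]:
    """Paired app − self tests for each indicator from a pairs frame.

    ``unit="participant"`` first averages each participant's nights, then
    pairs the per-participant means (df = participants − 1), the standard
    design for multi-night cohorts; ``"night"`` pools all nights.
    """
    results: dict[str, PairedTestResult] = {}
    if unit == "participant":
        grouped = frame.groupby("participant_id", sort=True)[
            [f"{p}_{i}" for p in ("app", "self") for i in INDICATORS]
        ].mean()
    else:
        grouped = frame
    for ind in INDICATORS:
        results[ind] = _paired_t(
            grouped[f"app_{ind}"].to_numpy(), grouped[f"self_{ind}"].to_numpy()
        )
    return results


def paired_indicator_differences(
    pairs: Sequence[NightPair], unit: Literal["participant", "night"] = "participant"
) -> dict[str, PairedTestResult]:
    """Mean app − self differences (seconds) with paired t, per indicator."""
    if len(pairs) < 2:
        raise ValueError("paired differences require at least 2 pairs")
    return paired_differences_from_frame(pairs_to_frame(pairs), unit=unit)


def _pearson(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    n = x.size
    if n < 3:
        return CorrelationResult(None, n, "fewer than 3 pairs")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return CorrelationResult(None, n, "zero variance")
    r, _ = stats.pearsonr(x, y)
    return CorrelationResult(float(r), n)


def midpoint_correlation(pairs: Sequence[NightPair]) -> CorrelationResult:
    """Pooled Pearson r between app and self-report midpoints over all nights."""
    frame = pairs_to_frame(pairs)
    return _pearson(
        frame["app_midpoint"].to_numpy(), frame["self_midpoint"].to_numpy()
    )


def per_day_correlation(pairs: Sequence[NightPair]) -> pd.DataFrame:
    """One midpoint correlation per wake date, across participants."""
    frame = pairs_to_frame(pairs)
    rows = []
    for wake_date, grp in frame.groupby("wake_date", sort=True):
        res = _pearson(grp["app_midpoint"].to_numpy(), grp["self_midpoint"].to_numpy())
        rows.append(
            {"wake_date": wake_date, "r": res.r, "n": res.n, "note": res.note}
        )
    return pd.DataFrame(rows)


def social_jetlag(series: SleepSeries, weekend_basis: str = "wake_date") -> float | None:
    """|mean weekend midpoint − mean weeknight midpoint| in minutes.

    Midpoints are on the since-midnight scale of each night's wake date.
    Returns ``None`` when the series lacks one of the two night classes.
    The absolute value makes the statistic invariant to which class is
    called "weekend".
    """
    weekend, weekday = [], []
    for rec in series.records:
        sec = indicator_seconds(rec)["midpoint"]
        (weekend if is_weekend_night(rec, weekend_basis) else weekday).append(sec)
    if not weekend or not weekday:
        return None
    return abs(float(np.mean(weekend)) - float(np.mean(weekday))) / 60.0


def social_jetlag_comparison(
    app_series: Sequence[SleepSeries],
    self_series: Sequence[SleepSeries],
    weekend_basis: str = "wake_date",
) -> tuple[float, float, PairedTestResult]:
    """Cohort app vs self social jetlag: (mean app, mean self, paired t), minutes.

    Participants lacking a night class in either source are excluded pairwise.
    """
    app_vals, self_vals = [], []
    for a, s in zip(app_series, self_series):
        ja = social_jetlag(a, weekend_basis)
        js = social_jetlag(s, weekend_basis)
        if ja is not None and js is not None:
            app_vals.append(ja)
            self_vals.append(js)
    if len(app_vals) < 2:
        raise ValueError("social-jetlag comparison requires >= 2 participants")
    test = _paired_t(np.array(app_vals), np.array(self_vals))
    return float(np.mean(app_vals)), float(np.mean(self_vals)), test


def sleep_efficiency(tst_app: float, tst_self: float) -> tuple[float, bool]:
    """App TST over self-reported TST (time in bed proxy); flag ratios above 1."""
    if tst_app <= 0 or tst_self <= 0:
        raise ValueError("sleep efficiency requires positive TSTs")
    ratio = tst_app / tst_self
    return ratio, ratio > 1.0


def compare_weeknight_weekend_overlap(
    pairs: Sequence[NightPair],
) -> PairedTestResult:
    """Paired t of per-participant mean overlap ratio, weeknights vs weekends."""
    frame = pairs_to_frame(pairs)
    per_part = frame.pivot_table(
        index="participant_id",
        columns="is_weekend_night",
        values="overlap_pct",
        aggfunc="mean",
    )
    if True not in per_part.columns or False not in per_part.columns:
        raise ValueError("need both weeknights and weekend nights")
    complete = per_part.dropna()
    if len(complete) < 2:
        raise ValueError(
            "weeknight/weekend comparison requires >= 2 participants with both classes"
        )
    return _paired_t(complete[False].to_numpy(), complete[True].to_numpy())


@dataclass
class AgreementReport:
    """Cohort agreement between app-detected and self-reported sleep."""

    n_participants: int
    n_pairs: int
    mean_overlap_pct: float
    paired_differences: dict[str, PairedTestResult]
    overall_midpoint_r: CorrelationResult
    per_day_midpoint_r: pd.DataFrame
    social_jetlag_app_min: float
    social_jetlag_self_min: float
    social_jetlag_test: PairedTestResult
    weekend_overlap_test: PairedTestResult | None
    sleep_efficiency: float
    efficiency_above_one: bool
    per_night: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        def _test(t: PairedTestResult) -> dict:
            return {
                "mean_diff": t.mean_diff,
                "t": t.t,
                "p": t.p,
                "df": t.df,
                "n": t.n,
                "degenerate": t.degenerate,
            }

        return {
            "n_participants": self.n_participants,
            "n_pairs": self.n_pairs,
            "mean_overlap_pct": self.mean_overlap_pct,
            "paired_differences_s": {
                k: _test(v) for k, v in self.paired_differences.items()
            },
            "overall_midpoint_r": self.overall_midpoint_r.r,
            "overall_midpoint_n": self.overall_midpoint_r.n,
            "per_day_midpoint_r": [
                {
                    "wake_date": str(row.wake_date),
                    "r": None if pd.isna(row.r) else row.r,
                    "n": int(row.n),
                }
                for row in self.per_day_midpoint_r.itertuples()
            ],
            "social_jetlag_min": {
                "app": self.social_jetlag_app_min,
                "self": self.social_jetlag_self_min,
                "test": _test(self.social_jetlag_test),
            },
            "weekend_overlap_test": (
                None if self.weekend_overlap_test is None else _test(self.weekend_overlap_test)
            ),
            "sleep_efficiency": self.sleep_efficiency,
            "efficiency_above_one": self.efficiency_above_one,
        }


def agreement_report(
    app_series: Sequence[SleepSeries],
    self_series: Sequence[SleepSeries],
    weekend_basis: str = "wake_date",
) -> AgreementReport:
    """Full cohort validation: overlap, paired differences, correlations, jetlag.

    ``app_series`` and ``self_series`` must be aligned per participant; only
    nights present in both sources enter the statistics.
    """
    if len(app_series) != len(self_series):
        raise ValueError("app and self-report series must align per participant")
    all_pairs: list[NightPair] = []
    for a, s in zip(app_series, self_series):
        all_pairs.extend(build_night_pairs(a, s, weekend_basis))
    if len(all_pairs) < 2:
        raise ValueError("agreement report requires >= 2 matched nights")
    frame = pairs_to_frame(all_pairs)
    diffs = paired_differences_from_frame(frame)
    overall_r = midpoint_correlation(all_pairs)
    per_day = per_day_correlation(all_pairs)
    jl_app, jl_self, jl_test = social_jetlag_comparison(
        app_series, self_series, weekend_basis
    )
    try:
        weekend_test: PairedTestResult | None = compare_weeknight_weekend_overlap(
            all_pairs
        )
    except ValueError as exc:
        logger.info("weeknight/weekend overlap comparison unavailable: %s", exc)
        weekend_test = None
    eff, above = sleep_efficiency(
        float(frame["app_tst"].mean()), float(frame["self_tst"].mean())
    )
    return AgreementReport(
        n_participants=frame["participant_id"].nunique(),
        n_pairs=len(all_pairs),
        mean_overlap_pct=float(frame["overlap_pct"].mean()),
        paired_differences=diffs,
        overall_midpoint_r=overall_r,
        per_day_midpoint_r=per_day,
        social_jetlag_app_min=jl_app,
        social_jetlag_self_min=jl_self,
        social_jetlag_test=jl_test,
        weekend_overlap_test=weekend_test,
        sleep_efficiency=eff,
        efficiency_above_one=above,
        per_night=frame,
    )
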