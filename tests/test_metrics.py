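"""Overlap ratio, paired differences, correlations, social jetlag, efficiency."""

from __future__ import annotations

from datetime import date, datetime, time, timedelta

import numpy as np
import pandas as pd
import pytest

from rhythmkit.metrics import (
    CorrelationResult,
    NightPair,
    build_night_pairs,
    compare_weeknight_weekend_overlap,
    indicator_seconds,
    midpoint_correlation,
    overlap_ratio,
    paired_differences_from_frame,
    paired_indicator_differences,
    pairs_to_frame,
    per_day_correlation,
    sleep_efficiency,
    social_jetlag,
    social_jetlag_comparison,
)
from rhythmkit.sleep import SleepSeries, make_sleep_record


def rec(wake_date, onset, wake, source="app"):
    return make_sleep_record(onset, wake, wake_date, source=source)


def night(d):  # wake date of night index d, starting Tue 2018-02-06
    return date(2018, 2, 6) + timedelta(days=d)


def mk_series(pid, nights, source="app"):
    """nights: list of (wake_date, onset, wake)."""
    return SleepSeries(
        pid, [rec(w, o, k, source) for w, o, k in nights]
    )


class TestOverlapRatio:
    def test_worked_example_is_90_percent(self):
        d0, d1 = datetime(2018, 2, 5), datetime(2018, 2, 6)
        app = (d0.replace(hour=23, minute=36), d1.replace(hour=6, minute=49))
        self_ = (d0.replace(hour=23, minute=0), d1.replace(hour=6, minute=0))
        assert round(overlap_ratio(app, self_), 1) == 90.0

    def test_identical_intervals_give_100(self):
        a = (datetime(2018, 2, 5, 23), datetime(2018, 2, 6, 7))
        assert overlap_ratio(a, a) == 100.0

    def test_disjoint_intervals_give_0(self):
        a = (datetime(2018, 2, 5, 22), datetime(2018, 2, 5, 23))
        b = (datetime(2018, 2, 6, 1), datetime(2018, 2, 6, 2))
        assert overlap_ratio(a, b) == 0.0

    def test_degenerate_interval_rejected(self):
        t = datetime(2018, 2, 5, 23)
        with pytest.raises(ValueError):
            overlap_ratio((t, t), (t, t + timedelta(hours=1)))

    def test_symmetry_bounds_and_translation_decay(self):
        rng = np.random.default_rng(13)
        base = datetime(2018, 2, 5)
        for _ in range(300):
            a0 = base + timedelta(seconds=int(rng.integers(0, 86400)))
            a1 = a0 + timedelta(seconds=int(rng.integers(60, 36000)))
            b0 = base + timedelta(seconds=int(rng.integers(0, 86400)))
            b1 = b0 + timedelta(seconds=int(rng.integers(60, 36000)))
            r = overlap_ratio((a0, a1), (b0, b1))
            assert r == pytest.approx(overlap_ratio((b0, b1), (a0, a1)))
            assert 0.0 <= r <= 100.0
            assert (r == 100.0) == ((a0, a1) == (b0, b1))
        # weakly decreasing as one interval slides away
        a = (base.replace(hour=23), base.replace(hour=23) + timedelta(hours=8))
        prev = 100.0
        for shift_min in range(0, 600, 15):
            b = (a[0] + timedelta(minutes=shift_min), a[1] + timedelta(minutes=shift_min))
            r = overlap_ratio(a, b)
            assert r <= prev + 1e-9
            prev = r


class TestIndicatorScale:
    def test_onset_before_midnight_is_negative(self):
        r = rec(night(0), datetime(2018, 2, 5, 23), datetime(2018, 2, 6, 6))
        s = indicator_seconds(r)
        assert s["onset"] == -3600.0
        assert s["wake"] == 6 * 3600.0
        assert s["tst"] == 7 * 3600.0

    def test_mean_midpoint_identity(self):
        """mean(midpoint) == (mean(onset) + mean(wake)) / 2 on one scale."""
        rng = np.random.default_rng(3)
        rows = []
        for d in range(40):
            onset = datetime.combine(night(d), time(0)) + timedelta(
                seconds=int(rng.integers(-7200, 7200))
            )
            wake = onset + timedelta(seconds=int(rng.integers(5 * 3600, 9 * 3600)))
            rows.append(indicator_seconds(rec(night(d), onset, wake)))
        onset_m = np.mean([r["onset"] for r in rows])
        wake_m = np.mean([r["wake"] for r in rows])
        mid_m = np.mean([r["midpoint"] for r in rows])
        # up to the 1-second midpoint rounding per night
        assert mid_m == pytest.approx((onset_m + wake_m) / 2, abs=0.5)


def _pairs_with_offset(n_participants, nights_per, onset_off_s, wake_off_s, seed=0):
    rng = np.random.default_rng(seed)
    pairs = []
    for p in range(n_participants):
        for d in range(nights_per):
            wd = night(d)
            onset = datetime.combine(wd, time(1)) + timedelta(
                seconds=int(rng.integers(0, 3600))
            )
            wake = onset + timedelta(seconds=int(rng.integers(6 * 3600, 8 * 3600)))
            app = rec(wd, onset, wake)
            sr = rec(
                wd,
                onset + timedelta(seconds=onset_off_s),
                wake + timedelta(seconds=wake_off_s),
                source="self_report",
            )
            pairs.append(
                NightPair(f"p{p}", wd, app, sr, is_weekend_night=wd.weekday() >= 5)
            )
    return pairs


class TestPairedDifferences:
    def test_identical_records_give_zero_diff_t_zero(self):
        pairs = _pairs_with_offset(4, 5, 0, 0)
        res = paired_indicator_differences(pairs)
        for ind, r in res.items():
            assert r.mean_diff == 0.0 and r.t == 0.0 and r.p == 1.0 and r.degenerate

    def test_constant_offset_recovered_with_degenerate_t(self):
        pairs = _pairs_with_offset(5, 1, -100, -100)
        res = paired_indicator_differences(pairs, unit="night")
        # app - self = +100 for onset and wake; t undefined (zero variance)
        assert res["onset"].mean_diff == pytest.approx(100.0)
        assert res["wake"].mean_diff == pytest.approx(100.0)
        assert res["onset"].t is None and res["onset"].degenerate

    def test_printed_cohort_means_reproduce_reported_differences(self):
        """Mean app-self differences from published-style cohort means."""
        means = {
            "onset": (5202.53, 4959.64),
            "wake": (30104.20, 30727.93),
            "midpoint": (17653.27, 17843.74),
            "tst": (24901.67, 25768.30),
        }
        rows = []
        for k, delta in (("a", -100.0), ("b", 100.0)):
            row = {"participant_id": k}
            for ind, (app_m, self_m) in means.items():
                row[f"app_{ind}"] = app_m + delta
                row[f"self_{ind}"] = self_m + delta
            rows.append(row)
        res = paired_differences_from_frame(pd.DataFrame(rows))
        assert res["onset"].mean_diff == pytest.approx(242.89, abs=0.05)
        assert res["wake"].mean_diff == pytest.approx(-623.73, abs=0.05)
        assert res["tst"].mean_diff == pytest.approx(-866.63, abs=0.05)
        assert res["midpoint"].mean_diff == pytest.approx(-190.47, abs=0.05)

    def test_fewer_than_two_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_indicator_differences(_pairs_with_offset(1, 1, 0, 0))


class TestMidpointCorrelation:
    def test_equal_midpoints_give_r_1(self):
        res = midpoint_correlation(_pairs_with_offset(3, 10, 0, 0))
        assert res.r == pytest.approx(1.0)

    def test_constant_offset_gives_r_1(self):
        res = midpoint_correlation(_pairs_with_offset(3, 10, 600, 600))
        assert res.r == pytest.approx(1.0)

    def test_shift_invariance_of_r(self):
        pairs = _pairs_with_offset(4, 10, 300, -300, seed=5)
        base = midpoint_correlation(pairs).r
        shifted = [
            NightPair(
                p.participant_id,
                p.wake_date,
                rec(p.wake_date, p.app.onset + timedelta(hours=1), p.app.wake + timedelta(hours=1)),
                p.self_report,
                p.is_weekend_night,
            )
            for p in pairs
        ]
        assert midpoint_correlation(shifted).r == pytest.approx(base, abs=1e-9)

    def test_noise_attenuation_matches_closed_form(self):
        """r ~= sd(app) / sqrt(sd(app)^2 + sigma^2) under added midpoint noise."""
        rng = np.random.default_rng(42)
        sigma = 1200.0
        pairs = []
        for d in range(1000):
            wd = night(d % 30)
            onset = datetime.combine(wd, time(1)) + timedelta(
                seconds=int(rng.normal(0, 3600))
            )
            wake = onset + timedelta(hours=7)
            eps = rng.normal(0, sigma)
            pairs.append(
                NightPair(
                    f"p{d}",
                    wd,
                    rec(wd, onset, wake),
                    rec(wd, onset + timedelta(seconds=eps), wake + timedelta(seconds=eps)),
                    False,
                )
            )
        frame = pairs_to_frame(pairs)
        r = midpoint_correlation(pairs).r
        s_app = frame["app_midpoint"].std(ddof=1)
        predicted = s_app / np.hypot(s_app, sigma)
        assert r == pytest.approx(predicted, abs=0.02)

    def test_zero_variance_reported_missing_with_reason(self):
        pairs = []
        for d in range(5):
            wd = night(d)
            onset = datetime.combine(wd, time(1))
            a = rec(wd, onset, onset + timedelta(hours=7))
            pairs.append(NightPair("p0", wd, a, a, False))
        res = midpoint_correlation(pairs)
        assert res.r is None and "variance" in res.note

    def test_per_day_needs_three_pairs(self):
        pairs = _pairs_with_offset(2, 4, 0, 0)
        track = per_day_correlation(pairs)
        assert set(track["note"]) == {"fewer than 3 pairs"}
        assert len(track) == 4


class TestSocialJetlag:
    def _series(self, weekday_mid_h, weekend_mid_h):
        nights = []
        for d in range(14):
            wd = night(d)
            mid_h = weekend_mid_h if wd.weekday() >= 5 else weekday_mid_h
            onset = datetime.combine(wd, time(0)) + timedelta(hours=mid_h - 3.5)
            nights.append((wd, onset, onset + timedelta(hours=7)))
        return mk_series("p0", nights)

    def test_one_hour_weekend_delay_is_60_minutes(self):
        assert social_jetlag(self._series(4.0, 5.0)) == pytest.approx(60.0)

    def test_identical_schedule_gives_zero(self):
        assert social_jetlag(self._series(4.0, 4.0)) == 0.0

    def test_invariant_to_which_class_is_weekend(self):
        # delaying weekdays instead of weekends gives the same magnitude
        assert social_jetlag(self._series(5.0, 4.0)) == pytest.approx(60.0)

    def test_missing_class_returns_none(self):
        nights = [(night(d), datetime.combine(night(d), time(1)), datetime.combine(night(d), time(8))) for d in range(4)]
        weekdays_only = mk_series("p0", nights)  # Tue-Fri wake dates
        assert social_jetlag(weekdays_only) is None

    def test_cohort_comparison_paired(self):
        app = [self._series(4.0, 5.0), self._series(3.5, 4.5)]
        self_ = [self._series(4.0, 4.8), self._series(3.5, 4.3)]
        a, s, test = social_jetlag_comparison(app, self_)
        assert a == pytest.approx(60.0)
        assert s == pytest.approx(48.0)
        assert test.n == 2


class TestSleepEfficiency:
    def test_printed_means_give_0_966(self):
        ratio, above = sleep_efficiency(24901.67, 25768.30)
        assert ratio == pytest.approx(0.966, abs=0.0005)
        assert not above

    def test_equal_tst_gives_1(self):
        assert sleep_efficiency(25200, 25200) == (1.0, False)

    def test_app_longer_than_self_flagged(self):
        ratio, above = sleep_efficiency(8 * 3600, 7 * 3600)
        assert ratio == pytest.approx(8 / 7)
        assert above

    def test_zero_self_tst_rejected(self):
        with pytest.raises(ValueError):
            sleep_efficiency(100, 0)


class TestWeekendOverlapComparison:
    def test_identical_distributions_give_t_zero(self):
        # same 300 s shift and same 7 h TST every night -> identical overlap
        pairs = []
        for p in range(4):
            for d in range(14):
                wd = night(d)
                onset = datetime.combine(wd, time(1))
                wake = onset + timedelta(hours=7)
                pairs.append(
                    NightPair(
                        f"p{p}",
                        wd,
                        rec(wd, onset, wake),
                        rec(wd, onset + timedelta(seconds=300), wake + timedelta(seconds=300)),
                        wd.weekday() >= 5,
                    )
                )
        res = compare_weeknight_weekend_overlap(pairs)
        assert res.mean_diff == pytest.approx(0.0, abs=1e-9)
        assert res.t == 0.0 and res.degenerate

    def test_single_participant_rejected(self):
        pairs = _pairs_with_offset(1, 14, 300, 300)
        with pytest.raises(ValueError):
            compare_weeknight_weekend_overlap(pairs)

    def test_weekend_degradation_detected(self):
        rng = np.random.default_rng(9)
        pairs = []
        for p in range(12):
            for d in range(28):
                wd = night(d)
                onset = datetime.combine(wd, time(1))
                wake = onset + timedelta(hours=7)
                noise = 3600 if wd.weekday() >= 5 else 300
                shift = int(rng.normal(0, noise))
                pairs.append(
                    NightPair(
                        f"p{p}",
                        wd,
                        rec(wd, onset, wake),
                        rec(wd, onset + timedelta(seconds=shift), wake + timedelta(seconds=shift)),
                        wd.weekday() >= 5,
                    )
                )
        res = compare_weeknight_weekend_overlap(pairs)
        assert res.mean_diff > 0  # weeknights agree better
        assert res.p < 0.01


class TestBuildNightPairs:
    def test_intersection_only_and_weekend_tagging(self):
        app = mk_series(
            "p0",
            [(night(d), datetime.combine(night(d), time(1)), datetime.combine(night(d), time(8))) for d in range(6)],
        )
        self_ = mk_series(
            "p0",
            [(night(d), datetime.combine(night(d), time(1)), datetime.combine(night(d), time(8))) for d in range(2, 9)],
            source="self_report",
        )
        pairs = build_night_pairs(app, self_)
        assert [p.wake_date for p in pairs] == [night(d) for d in range(2, 6)]
        for p in pairs:
            assert p.is_weekend_night == (p.wake_date.weekday() >= 5)
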