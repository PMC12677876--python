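"""Extremal-window selection, QA, rest interval, summaries, sleep scoring."""

import numpy as np
import pytest

from actimood.actigraphy import (
    EpochSeries,
    daily_summary,
    find_extremal_windows,
    identify_rest_interval,
    score_sleep,
    select_windows,
    select_windows_greedy,
    validate_day,
    window_contrasts,
)
from actimood.errors import (
    InsufficientDataError,
    MalformedInputError,
    MissingFeatureError,
)

from helpers import brute_force_best_total

DAY = (420, 1320)


def series(counts, valid=None):
    return EpochSeries("p", "2022-01-01", counts, valid)


# ---------------------------------------------------------------------------
# window selection
# ---------------------------------------------------------------------------

class TestSelectWindows:
    def test_constant_series_earliest_starts(self):
        out = select_windows(np.full(1440, 3), interval=DAY, window=60, k=4)
        assert out == [(420, 180), (480, 180), (540, 180), (600, 180)]

    def test_ramp_picks_last_hours(self):
        x = np.zeros(1440, dtype=int)
        x[420:1320] = np.arange(900)
        out = select_windows(x, interval=DAY, window=60, k=4, mode="max")
        assert sorted(s for s, _ in out) == [1080, 1140, 1200, 1260]
        total = sum(t for _, t in out)
        oracle = brute_force_best_total(
            x, np.ones(1440, bool), 1100, 1320, 60, 2, "max"
        )
        # the last two hours alone must not beat the DP's four-window total
        assert total >= oracle

    @pytest.mark.parametrize("case", range(30))
    def test_matches_exhaustive_enumeration(self, case):
        rng = np.random.default_rng(900 + case)
        k = int(rng.integers(1, 4))
        window = int(rng.integers(2, 11))
        n = int(rng.integers(k * window + 2, 60 if k == 3 else 120))
        x = rng.integers(0, 200, n)
        valid = rng.random(n) > 0.08
        for mode in ("max", "min"):
            try:
                picks = select_windows(
                    x, valid, interval=(0, n), window=window, k=k, mode=mode
                )
            except InsufficientDataError:
                assert (
                    brute_force_best_total(x, valid, 0, n, window, k, mode)
                    is None
                )
                continue
            total = sum(t for _, t in picks)
            assert total == brute_force_best_total(
                x, valid, 0, n, window, k, mode
            )

    @pytest.mark.parametrize("seed", range(50))
    def test_max_min_duality(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 600, 1440)
        mn = select_windows(x, interval=DAY, mode="min")
        mx = select_windows(-x, interval=DAY, mode="max")
        assert [(s, -t) for s, t in mx] == mn

    def test_jointly_optimal_beats_random_placements(self, rng):
        x = rng.integers(0, 400, 1440)
        picks = select_windows(x, interval=DAY, window=60, k=4, mode="max")
        best = sum(t for _, t in picks)
        for _ in range(100):
            starts = np.sort(rng.choice(np.arange(420, 1261), 4, replace=False))
            if np.any(np.diff(starts) < 60):
                continue
            alt = sum(int(x[s: s + 60].sum()) for s in starts)
            assert alt <= best

    def test_invalid_epoch_excludes_window(self):
        x = np.full(1440, 10)
        valid = np.ones(1440, bool)
        valid[450] = False  # poisons every window covering minute 450
        picks = select_windows(x, valid, interval=DAY, window=60, k=4)
        for s, _ in picks:
            assert not (s <= 450 < s + 60)
        imput = select_windows(
            x, valid, interval=DAY, window=60, k=4, invalid_policy="impute_zero"
        )
        assert imput[0][1] == 600  # earliest clean window still sums fully

    def test_insufficient_valid_windows(self):
        valid = np.zeros(1440, bool)
        with pytest.raises(InsufficientDataError):
            select_windows(np.ones(1440, int), valid, interval=DAY, k=4)

    def test_greedy_never_beats_optimal(self, rng):
        for _ in range(20):
            x = rng.integers(0, 300, 1440)
            opt = sum(t for _, t in select_windows(x, interval=DAY, mode="max"))
            grd = sum(
                t for _, t in select_windows_greedy(x, interval=DAY, mode="max")
            )
            assert grd <= opt


class TestFindExtremalWindows:
    def test_rank_ordering_and_duality_on_series(self, rng):
        s = series(rng.integers(0, 500, 1440))
        maxw = find_extremal_windows(s, mode="max")
        minw = find_extremal_windows(s, mode="min")
        assert [w.rank for w in maxw] == [1, 2, 3, 4]
        totals_max = [w.total for w in maxw]
        totals_min = [w.total for w in minw]
        assert totals_max == sorted(totals_max, reverse=True)
        assert totals_min == sorted(totals_min)
        contrasts = window_contrasts(maxw, minw)
        assert all(c >= 0 for c in contrasts)

    def test_contrast_arithmetic(self):
        class W:  # minimal stand-in
            def __init__(self, t):
                self.total = t

        maxs = [W(400), W(300), W(200), W(100)]
        mins = [W(10), W(20), W(30), W(40)]
        assert window_contrasts(maxs, mins) == [390, 280, 170, 60]
        with pytest.raises(MissingFeatureError):
            window_contrasts(maxs, [])

    def test_constant_day_zero_contrasts(self):
        s = series(np.full(1440, 7))
        c = window_contrasts(
            find_extremal_windows(s, mode="max"),
            find_extremal_windows(s, mode="min"),
        )
        assert c == [0, 0, 0, 0]


# ---------------------------------------------------------------------------
# QA / rest interval
# ---------------------------------------------------------------------------

class TestRestInterval:
    def test_all_zero_whole_day(self):
        assert identify_rest_interval(series(np.zeros(1440))) == (0, 1440)

    def test_quiet_night_block_within_calendar_day(self):
        x = np.full(1440, 300)
        x[1380:] = 0     # 23:00-24:00
        x[:420] = 0      # 00:00-07:00
        start, end = identify_rest_interval(series(x))
        assert start == 0
        assert abs(end - 420) <= 6  # smoothing blurs the edge by <= half window

    def test_tie_goes_to_earlier_block(self):
        x = np.full(1440, 300)
        x[100:200] = 0
        x[400:500] = 0
        start, end = identify_rest_interval(series(x))
        # smoothing trims the edges, but the earlier of the two equal
        # blocks must be the one returned
        assert 95 <= start <= 106 and end - start >= 90

    def test_no_rest_epochs(self):
        assert identify_rest_interval(series(np.full(1440, 999))) == (0, 0)


class TestValidateDay:
    @pytest.mark.parametrize("n_invalid,expect_valid", [(59, True), (60, False)])
    def test_sleep_invalidation_boundary(self, n_invalid, expect_valid):
        valid = np.ones(1440, bool)
        valid[10: 10 + n_invalid] = False
        qa = validate_day(series(np.zeros(1440), valid), (0, 420))
        assert qa.sleep_valid is expect_valid

    def test_fully_valid_day(self):
        qa = validate_day(series(np.zeros(1440)), (0, 420))
        assert qa.sleep_valid and qa.day_usable

    def test_day_unusable_above_invalid_fraction(self):
        valid = np.ones(1440, bool)
        valid[420: 420 + 200] = False  # 200/900 > 20% of daytime
        qa = validate_day(series(np.zeros(1440), valid), (0, 420))
        assert not qa.day_usable

    def test_wrong_length_rejected(self):
        with pytest.raises(MalformedInputError):
            EpochSeries("p", "2022-01-01", np.zeros(100))


# ---------------------------------------------------------------------------
# summaries and sleep
# ---------------------------------------------------------------------------

class TestDailySummary:
    def test_constant_day(self):
        out = daily_summary(series(np.full(1440, 5)))
        assert out == {
            "total_ac": 7200.0, "avg_ac_per_min": 5.0,
            "avg_ac_per_epoch": 5.0, "std_ac": 0.0, "max_ac": 5.0,
        }

    def test_two_valid_epochs_population_std(self):
        counts = np.zeros(1440, dtype=int)
        counts[1] = 10
        valid = np.zeros(1440, bool)
        valid[0:2] = True
        out = daily_summary(series(counts, valid))
        assert out["avg_ac_per_min"] == 5.0
        assert out["std_ac"] == 5.0
        assert out["max_ac"] == 10.0

    def test_invalid_epochs_dropped_exactly(self, rng):
        counts = rng.integers(0, 100, 1440)
        valid = rng.random(1440) > 0.1
        out = daily_summary(series(counts, valid))
        kept = counts[valid].astype(float)
        assert out["total_ac"] == kept.sum()
        assert out["std_ac"] == pytest.approx(kept.std(ddof=0))

    def test_all_invalid_is_missing(self):
        with pytest.raises(MissingFeatureError):
            daily_summary(series(np.zeros(1440), np.zeros(1440, bool)))


class TestScoreSleep:
    def test_quiet_rest_interval(self):
        m = score_sleep(series(np.zeros(1440)), (0, 420))
        assert m.efficiency == 100.0 and m.waso == 0.0 and m.fragmentation == 0.0
        assert m.duration == 420.0 and m.sleep_time == 420.0

    def test_alternating_half_efficiency(self):
        counts = np.zeros(1440, dtype=int)
        counts[0:120:2] = 100  # wake epochs at even minutes
        m = score_sleep(series(counts), (0, 120))
        assert m.efficiency == 50.0
        assert m.sleep_time == 60.0

    def test_empty_rest_interval_missing(self):
        m = score_sleep(series(np.zeros(1440)), (0, 0))
        assert np.isnan(m.duration) and np.isnan(m.efficiency)
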