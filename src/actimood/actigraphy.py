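"""Daily actigraphy features from 1-minute epoch series.

The central routine selects, for each day, the ``k`` nonoverlapping
60-minute daytime windows whose summed activity counts are *jointly*
maximal (the peak windows Max1st-Max4th) or minimal (Min1st-Min4th),
by exact dynamic programming over sliding-window sums. Around it sit
quality control (off-wrist invalidation, rest-interval detection),
daily summary counts, Max-Min contrasts, and a simplified threshold
sleep scorer.

Window selection semantics (all configurable):

* windows may start at any minute, not only on clock hours;
* nonoverlap is enforced within a mode only (the max set and the min set
  may overlap each other);
* equal-total placements are broken toward the earliest start minute,
  then lexicographically, so outputs are bit-reproducible;
* a window containing any invalid epoch is ineligible under the default
  ``"exclude"`` policy (``"impute_zero"`` treats invalid epochs as zero);
* rank 1 is the largest total for peaks and the smallest for troughs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DAYTIME_WINDOW, FeatureConfig
from .errors import InsufficientDataError, MalformedInputError, MissingFeatureError

log = logging.getLogger(__name__)

MINUTES_PER_DAY = 1440
_NEG = -(1 << 50)  # sentinel for infeasible DP states (int64-safe)


@dataclass
class EpochSeries:
    """One patient-day of 1-minute activity counts with validity flags."""

    patient_id: str
    date: str
    counts: np.ndarray
    valid: np.ndarray = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.valid is None:
            self.valid = np.ones(len(self.counts), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.counts) != MINUTES_PER_DAY or len(self.valid) != MINUTES_PER_DAY:
            raise MalformedInputError(
                f"epoch series must have {MINUTES_PER_DAY} epochs, "
                f"got {len(self.counts)}"
            )
        if (self.counts < 0).any():
            raise MalformedInputError("activity counts must be nonnegative")


@dataclass(frozen=True)
class ExtremalWindow:
    start_minute: int
    length: int
    total: int
    rank: int
    mode: str  # "max" | "min"


@dataclass(frozen=True)
class QAResult:
    sleep_valid: bool
    day_usable: bool
    n_invalid_rest: int = 0
    frac_invalid_daytime: float = 0.0


@dataclass
class SleepMetrics:
    duration: float = np.nan      # rest-interval length, minutes
    efficiency: float = np.nan    # % of rest interval scored asleep
    waso: float = np.nan          # wake minutes after sleep onset
    sleep_time: float = np.nan    # minutes scored asleep
    pct_sleep: float = np.nan
    fragmentation: float = np.nan  # sleep->wake transitions per hour of sleep

    def as_dict(self) -> dict:
        return {
            "sleep_duration": self.duration,
            "sleep_efficiency": self.efficiency,
            "sleep_waso": self.waso,
            "sleep_time": self.sleep_time,
            "pct_sleep": self.pct_sleep,
            "sleep_fragmentation": self.fragmentation,
        }


# ---------------------------------------------------------------------------
# window selection engine
# ---------------------------------------------------------------------------

def select_windows(
    values,
    valid=None,
    *,
    interval=DAYTIME_WINDOW,
    window: int = 60,
    k: int = 4,
    mode: str = "max",
    invalid_policy: str = "exclude",
) -> list[tuple[int, int]]:
    """Jointly optimal k nonoverlapping fixed-length windows on a raw array.

    Returns ``[(start, total), ...]`` ordered by rank (descending totals for
    ``mode="max"``, ascending for ``"min"``). ``values`` may be any integer
    array (negativity allowed here; the :class:`EpochSeries` wrapper enforces
    nonnegative counts). Minimisation is maximisation on the negated array,
    which makes max/min duality hold exactly, tie-breaks included.
    """
    if mode not in ("max", "min"):
        raise ValueError(f"mode must be 'max' or 'min', got {mode!r}")
    x = np.asarray(values, dtype=np.int64)
    n = len(x)
    valid = np.ones(n, dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    lo, hi = int(interval[0]), int(interval[1])
    lo, hi = max(lo, 0), min(hi, n)
    if hi - lo < k * window:
        raise InsufficientDataError(
            f"interval of {hi - lo} epochs cannot hold {k} windows of {window}"
        )
    sign = 1 if mode == "max" else -1
    xw = sign * np.where(valid, x, 0) if invalid_policy == "impute_zero" else sign * x

    csum = np.concatenate(([0], np.cumsum(xw)))
    n_starts = hi - window - lo + 1
    starts = np.arange(lo, lo + n_starts)
    W = csum[starts + window] - csum[starts]

    if invalid_policy == "exclude":
        inv = np.concatenate(([0], np.cumsum(~valid)))
        eligible = (inv[starts + window] - inv[starts]) == 0
    else:
        eligible = np.ones(n_starts, dtype=bool)

    # dp[j][i] = best total using j windows with start indices >= i
    dp = np.zeros((k + 1, n_starts + 1), dtype=np.int64)
    cand = np.full((k + 1, n_starts), _NEG, dtype=np.int64)
    for j in range(1, k + 1):
        idx = np.minimum(np.arange(n_starts) + window, n_starts)
        nxt = dp[j - 1][idx]
        ok = eligible & (nxt > _NEG // 2)
        cand[j][ok] = W[ok] + nxt[ok]
        dp[j][:n_starts] = np.maximum.accumulate(cand[j][::-1])[::-1]
        dp[j][n_starts] = _NEG

    if dp[k][0] <= _NEG // 2:
        raise InsufficientDataError(
            f"no feasible placement of {k} nonoverlapping valid windows"
        )

    # earliest-start reconstruction (lexicographically smallest optimum)
    placements = []
    i = 0
    for j in range(k, 0, -1):
        while cand[j][i] != dp[j][i]:
            i += 1
        placements.append(i)
        i = min(i + window, n_starts)

    out = [(lo + p, int(sign * W[p])) for p in placements]
    reverse = mode == "max"
    out.sort(key=lambda st: (-st[1] if reverse else st[1], st[0]))
    return out


def select_windows_greedy(
    values, valid=None, *, interval=DAYTIME_WINDOW, window=60, k=4,
    mode="max", invalid_policy="exclude",
) -> list[tuple[int, int]]:
    """Greedy comparison variant: repeatedly take the single best remaining
    eligible window. Documents where greedy diverges from joint optimality."""
    x = np.asarray(values, dtype=np.int64)
    n = len(x)
    valid = np.ones(n, dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    lo, hi = max(int(interval[0]), 0), min(int(interval[1]), n)
    sign = 1 if mode == "max" else -1
    xw = sign * np.where(valid, x, 0) if invalid_policy == "impute_zero" else sign * x
    csum = np.concatenate(([0], np.cumsum(xw)))
    n_starts = hi - window - lo + 1
    starts = np.arange(lo, lo + n_starts)
    W = csum[starts + window] - csum[starts]
    if invalid_policy == "exclude":
        inv = np.concatenate(([0], np.cumsum(~valid)))
        eligible = (inv[starts + window] - inv[starts]) == 0
    else:
        eligible = np.ones(n_starts, dtype=bool)
    chosen = []
    blocked = np.zeros(n_starts, dtype=bool)
    for _ in range(k):
        avail = eligible & ~blocked
        if not avail.any():
            raise InsufficientDataError("greedy selection ran out of windows")
        masked = np.where(avail, W, _NEG)
        p = int(np.argmax(masked))  # argmax takes the earliest maximum
        chosen.append((lo + p, int(sign * W[p])))
        blocked[max(0, p - window + 1): p + window] = True
    reverse = mode == "max"
    chosen.sort(key=lambda st: (-st[1] if reverse else st[1], st[0]))
    return chosen


def find_extremal_windows(
    series: EpochSeries,
    k: int = 4,
    window: int = 60,
    daytime=DAYTIME_WINDOW,
    mode: str = "max",
    invalid_policy: str = "exclude",
    selection: str = "optimal",
) -> list[ExtremalWindow]:
    """The k nonoverlapping extremal 60-minute daytime windows of one day."""
    engine = select_windows if selection == "optimal" else select_windows_greedy
    picks = engine(
        series.counts, series.valid, interval=daytime, window=window, k=k,
        mode=mode, invalid_policy=invalid_policy,
    )
    return [
        ExtremalWindow(start_minute=s, length=window, total=t, rank=r + 1, mode=mode)
        for r, (s, t) in enumerate(picks)
    ]


def window_contrasts(max_windows, min_windows) -> list[int]:
    """MaxK - MinK for K = 1..k; missing inputs raise, never silently zero."""
    if not max_windows or not min_windows:
        raise MissingFeatureError("both max and min window sets are required")
    if len(max_windows) != len(min_windows):
        raise MissingFeatureError("max and min window sets differ in length")
    return [mx.total - mn.total for mx, mn in zip(max_windows, min_windows)]


# ---------------------------------------------------------------------------
# quality control and rest interval
# ---------------------------------------------------------------------------

def identify_rest_interval(
    series: EpochSeries,
    rest_threshold: float = 50.0,
    smooth_minutes: int = 10,
) -> tuple[int, int]:
    """Longest run of epochs whose smoothed activity sits below the rest
    threshold, as ``(start, end)`` minutes with ``end`` exclusive.

    Smoothing is a centred moving mean. Runs are evaluated within the
    calendar day (no midnight wrapping). Ties go to the earliest run; if no
    epoch is below threshold the empty interval ``(0, 0)`` is returned.
    """
    smoothed = (
        pd.Series(series.counts.astype(float))
        .rolling(smooth_minutes, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    below = smoothed < rest_threshold
    if not below.any():
        return (0, 0)
    # run-length encode the boolean mask
    edges = np.flatnonzero(np.diff(np.concatenate(([0], below.view(np.int8), [0]))))
    run_starts, run_ends = edges[::2], edges[1::2]
    lengths = run_ends - run_starts
    best = int(np.argmax(lengths))  # argmax -> earliest among equal lengths
    return (int(run_starts[best]), int(run_ends[best]))


def validate_day(
    series: EpochSeries,
    rest_interval: tuple[int, int],
    max_invalid_daytime_frac: float = 0.20,
    daytime=DAYTIME_WINDOW,
) -> QAResult:
    """QA flags: sleep is invalidated by >=60 invalid epochs inside the rest
    interval; the day is unusable when more than the configured fraction of
    daytime epochs is invalid."""
    s, e = rest_interval
    n_invalid_rest = int((~series.valid[s:e]).sum())
    lo, hi = daytime
    day_invalid = (~series.valid[lo:hi]).sum()
    frac = float(day_invalid) / max(hi - lo, 1)
    return QAResult(
        sleep_valid=n_invalid_rest < 60,
        day_usable=frac <= max_invalid_daytime_frac,
        n_invalid_rest=n_invalid_rest,
        frac_invalid_daytime=frac,
    )


# ---------------------------------------------------------------------------
# summaries and sleep scoring
# ---------------------------------------------------------------------------

def daily_summary(series: EpochSeries) -> dict:
    """Whole-day activity summaries over valid epochs only.

    ``std_ac`` is the population standard deviation (denominator n), chosen
    so small hand fixtures are exact. With 1-minute epochs, counts/minute and
    counts/epoch coincide; both are emitted because downstream consumers name
    them separately.
    """
    v = series.valid
    if not v.any():
        raise MissingFeatureError("all epochs invalid; no daily summary")
    c = series.counts[v].astype(float)
    return {
        "total_ac": float(c.sum()),
        "avg_ac_per_min": float(c.mean()),
        "avg_ac_per_epoch": float(c.mean()),
        "std_ac": float(c.std(ddof=0)),
        "max_ac": float(c.max()),
    }


def score_sleep(
    series: EpochSeries,
    rest_interval: tuple[int, int],
    wake_threshold: float = 40.0,
) -> SleepMetrics:
    """Simplified threshold sleep scorer over the rest interval.

    Epochs with counts below the wake threshold are scored asleep. This is a
    documented stand-in for the proprietary device scoring: duration is the
    rest-interval length, efficiency = 100*sleep/duration, WASO counts wake
    epochs after the first sleep epoch, fragmentation is sleep->wake
    transitions per hour of sleep. An empty rest interval yields all-missing.
    """
    s, e = rest_interval
    if e <= s:
        return SleepMetrics()
    counts = series.counts[s:e]
    asleep = counts < wake_threshold
    duration = float(e - s)
    sleep_time = float(asleep.sum())
    efficiency = 100.0 * sleep_time / duration
    if sleep_time == 0:
        return SleepMetrics(
            duration=duration, efficiency=0.0, waso=0.0,
            sleep_time=0.0, pct_sleep=0.0, fragmentation=np.nan,
        )
    onset = int(np.argmax(asleep))
    waso = float((~asleep[onset:]).sum())
    transitions = int(((asleep[:-1]) & (~asleep[1:])).sum())
    fragmentation = transitions / (sleep_time / 60.0)
    return SleepMetrics(
        duration=duration, efficiency=efficiency, waso=waso,
        sleep_time=sleep_time, pct_sleep=efficiency, fragmentation=fragmentation,
    )


# ---------------------------------------------------------------------------
# cohort-level driver
# ---------------------------------------------------------------------------

WINDOW_FEATURES = [f"max{i}" for i in range(1, 5)] + [f"min{i}" for i in range(1, 5)]


def epochs_to_series(epochs: pd.DataFrame):
    """Yield :class:`EpochSeries` per (patient, date) from an epochs table.

    Accepts either the compact internal schema (patient_id, date, minute,
    activity_count, off_wrist) or the external one with an ISO timestamp.
    """
    df = epochs
    if "minute" not in df.columns:
        ts = pd.to_datetime(df["timestamp"])
        df = df.assign(
            date=ts.dt.strftime("%Y-%m-%d"),
            minute=ts.dt.hour * 60 + ts.dt.minute,
        )
    for (pid, date), g in df.groupby(["patient_id", "date"], sort=True, observed=True):
        g = g.sort_values("minute")
        if len(g) != MINUTES_PER_DAY:
            raise MalformedInputError(
                f"{pid} {date}: expected {MINUTES_PER_DAY} epochs, got {len(g)}"
            )
        yield EpochSeries(
            patient_id=str(pid),
            date=str(date),
            counts=g["activity_count"].to_numpy(),
            valid=g["off_wrist"].to_numpy() == 0,
        )


def compute_daily_features(
    epochs: pd.DataFrame, config: FeatureConfig | None = None
) -> pd.DataFrame:
    """One row of daily features per patient-day.

    Days where the extremal windows cannot be placed (too much off-wrist
    time) keep their QA flags but carry missing feature values and are
    logged; downstream cohort filters decide their fate.
    """
    cfg = config or FeatureConfig()
    rows = []
    for series in epochs_to_series(epochs):
        rest = identify_rest_interval(
            series, cfg.rest_threshold, cfg.rest_smooth_minutes
        )
        qa = validate_day(
            series, rest, cfg.max_invalid_daytime_frac, cfg.daytime_window
        )
        row = {
            "patient_id": series.patient_id,
            "date": series.date,
            "sleep_valid": qa.sleep_valid,
            "day_usable": qa.day_usable,
            "features_ok": False,
        }
        try:
            maxw = find_extremal_windows(
                series, cfg.k_windows, cfg.window_minutes, cfg.daytime_window,
                "max", cfg.invalid_window_policy, cfg.selection,
            )
            minw = find_extremal_windows(
                series, cfg.k_windows, cfg.window_minutes, cfg.daytime_window,
                "min", cfg.invalid_window_policy, cfg.selection,
            )
            for w in maxw:
                row[f"max{w.rank}"] = w.total
                row[f"max{w.rank}_start"] = w.start_minute
            for w in minw:
                row[f"min{w.rank}"] = w.total
                row[f"min{w.rank}_start"] = w.start_minute
            for i, c in enumerate(window_contrasts(maxw, minw), start=1):
                row[f"contrast{i}"] = c
            row.update(daily_summary(series))
            row["features_ok"] = True
        except (InsufficientDataError, MissingFeatureError) as exc:
            log.info("day dropped: %s %s: %s", series.patient_id, series.date, exc)
        sleep = (
            score_sleep(series, rest, cfg.wake_threshold)
            if qa.sleep_valid
            else SleepMetrics()
        )
        row.update(sleep.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
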