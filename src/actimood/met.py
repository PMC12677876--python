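"""Daily Mood and Energy Thermometer (MET) variables, severity categories
and the cohort-filter cascade with an auditable exclusion ledger.

Ratings are stored signed (-10..+10). Positive- and negative-channel
variables are magnitudes over the ratings of one day: e.g. ``mood_neg_max``
is the largest magnitude among negative mood ratings that day (0 when no
negative rating occurred -- zeros are recorded values in this instrument,
which is also why an all-zero-reports exclusion rule exists). Signed
min/max/mean/range are taken over all of the day's ratings.

Severity bins extend the integer convention OK(<3) / mild(3-4) /
moderate(5-6) / severe(>6) to the reals via half-open intervals
[3,5), [5,7), [7,inf).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ActimoodError

log = logging.getLogger(__name__)

SEVERITY_LEVELS = ("OK", "mild", "moderate", "severe")

#: MET variables derived per day and channel.
MET_VARIABLES = [
    "pos_max", "pos_min", "neg_max", "neg_min", "min", "max", "mean", "range",
]


@dataclass
class MetDay:
    """The 16 derived mood/energy variables for one patient-day."""

    mood_pos_max: float = 0.0
    mood_pos_min: float = 0.0
    mood_neg_max: float = 0.0
    mood_neg_min: float = 0.0
    mood_min: float = 0.0
    mood_max: float = 0.0
    mood_mean: float = 0.0
    mood_range: float = 0.0
    energy_pos_max: float = 0.0
    energy_pos_min: float = 0.0
    energy_neg_max: float = 0.0
    energy_neg_min: float = 0.0
    energy_min: float = 0.0
    energy_max: float = 0.0
    energy_mean: float = 0.0
    energy_range: float = 0.0
    n_ratings: int = 0


def _channel_stats(ratings: list[float], prefix: str) -> dict:
    arr = np.asarray([r for r in ratings if not pd.isna(r)], dtype=float)
    if arr.size == 0:
        raise ActimoodError(f"no {prefix} ratings for the day")
    pos = np.abs(arr[arr > 0])
    neg = np.abs(arr[arr < 0])
    return {
        f"{prefix}_pos_max": float(pos.max()) if pos.size else 0.0,
        f"{prefix}_pos_min": float(pos.min()) if pos.size else 0.0,
        f"{prefix}_neg_max": float(neg.max()) if neg.size else 0.0,
        f"{prefix}_neg_min": float(neg.min()) if neg.size else 0.0,
        f"{prefix}_min": float(arr.min()),
        f"{prefix}_max": float(arr.max()),
        f"{prefix}_mean": float(arr.mean()),
        f"{prefix}_range": float(arr.max() - arr.min()),
    }


def daily_met_variables(mood_ratings, energy_ratings) -> MetDay:
    """Derive the 16 daily variables from the day's signed ratings.

    Raises :class:`ActimoodError` when either channel has no rating at all;
    such days are excluded downstream and counted in the ledger.
    """
    d = _channel_stats(list(mood_ratings), "mood")
    d.update(_channel_stats(list(energy_ratings), "energy"))
    n = sum(1 for r in list(mood_ratings) + list(energy_ratings) if not pd.isna(r))
    return MetDay(**d, n_ratings=n)


def categorize_severity(magnitude: float) -> str:
    """OK (<3), mild [3,5), moderate [5,7), severe (>=7)."""
    if pd.isna(magnitude):
        raise ActimoodError("cannot categorize a missing magnitude")
    if magnitude < 0:
        raise ActimoodError("severity is defined on magnitudes (>= 0)")
    if magnitude < 3:
        return "OK"
    if magnitude < 5:
        return "mild"
    if magnitude < 7:
        return "moderate"
    return "severe"


def compute_met_daily(met: pd.DataFrame) -> pd.DataFrame:
    """One row per patient-day with the 16 derived variables plus a severity
    category column per magnitude/range variable (suffix ``_class``)."""
    rows = []
    for (pid, date), g in met.groupby(["patient_id", "date"], sort=True):
        mood = g["mood_rating"].dropna().tolist()
        energy = g["energy_rating"].dropna().tolist()
        row = {"patient_id": pid, "date": date,
               "mood_present": bool(mood), "energy_present": bool(energy)}
        if mood and energy:
            md = daily_met_variables(mood, energy)
            row.update(vars(md))
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in ("mood_pos_max", "mood_pos_min", "mood_neg_max", "mood_neg_min",
                "mood_range", "energy_pos_max", "energy_pos_min",
                "energy_neg_max", "energy_neg_min", "energy_range"):
        if col in df.columns:
            df[f"{col}_class"] = df[col].map(
                lambda m: categorize_severity(m) if pd.notna(m) else np.nan
            )
    return df


# ---------------------------------------------------------------------------
# exclusion ledger and cohort filters
# ---------------------------------------------------------------------------

@dataclass
class ExclusionLedger:
    """Ordered record of the filter cascade; conserves patient counts."""

    initial: int
    steps: list = field(default_factory=list)  # (name, n_removed, n_remaining)

    def record(self, step_name: str, n_removed: int) -> int:
        remaining = self.n_remaining - int(n_removed)
        if remaining < 0:
            raise ActimoodError(
                f"ledger underflow at step {step_name!r}: cannot remove "
                f"{n_removed} from {self.n_remaining}"
            )
        self.steps.append((step_name, int(n_removed), remaining))
        return remaining

    @property
    def n_remaining(self) -> int:
        return self.steps[-1][2] if self.steps else self.initial

    def check_conservation(self) -> bool:
        return self.initial == self.n_remaining + sum(s[1] for s in self.steps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["step", "n_removed", "n_remaining"]
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"initial": self.initial,
                 "steps": [
                     {"step": s, "n_removed": r, "n_remaining": rem}
                     for s, r, rem in self.steps
                 ],
                 "final": self.n_remaining},
                fh, indent=2,
            )


def _longest_run(dates: pd.Series) -> pd.Index:
    """Index of the longest run of calendar-adjacent dates (earliest wins)."""
    d = pd.to_datetime(dates).sort_values()
    if d.empty:
        return d.index
    gaps = d.diff().dt.days.fillna(1).ne(1).cumsum()
    sizes = gaps.value_counts().sort_index()
    best = sizes.index[int(np.argmax(sizes.to_numpy()))]
    return d.index[gaps == best]


def apply_cohort_filters(
    patients: pd.DataFrame,
    met_daily: pd.DataFrame,
    daily_features: pd.DataFrame,
    min_days: int = 4,
    zero_frac_threshold: float = 0.70,
    drop_boundary_days: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, ExclusionLedger]:
    """Sequential patient-level filters, each recorded in the ledger.

    1. missing demographics;
    2. fewer than ``min_days`` consecutive usable actigraphy days
       (optionally trimming each patient's first/last recorded day, which
       stands in for partial admission/discharge days in real exports);
    3. fewer than ``min_days`` consecutive usable days with complete
       mood *and* energy ratings (the retained run);
    4. all-zero mood and energy reports on more than ``zero_frac_threshold``
       of the retained days (strict inequality).

    Returns the filtered patients, their retained patient-day table, and the
    ledger. The cascade is idempotent: re-running on its own output removes
    nobody.
    """
    ledger = ExclusionLedger(initial=len(patients))
    if patients.empty:
        log.warning("empty cohort passed to filters")
        return patients, met_daily.iloc[0:0], ledger

    demo_ok = patients[["group", "age_months", "gender"]].notna().all(axis=1)
    keep = patients[demo_ok].copy()
    ledger.record("missing_demographics", int((~demo_ok).sum()))

    feats = daily_features.copy()
    if drop_boundary_days:
        first_last = feats.groupby("patient_id")["date"].agg(["min", "max"])
        feats = feats.merge(first_last, on="patient_id")
        feats = feats[(feats["date"] != feats["min"]) & (feats["date"] != feats["max"])]
    usable = feats[feats["day_usable"] & feats["features_ok"]]

    met_ok = met_daily[
        met_daily.get("mood_present", True) & met_daily.get("energy_present", True)
    ]
    met_ok = met_ok[met_ok["mood_pos_max"].notna()]

    survivors, retained = [], []
    removed_act = removed_met = 0
    for pid in keep["patient_id"]:
        days = usable[usable["patient_id"] == pid]
        run = days.loc[_longest_run(days["date"])]
        if len(run) < min_days:
            removed_act += 1
            continue
        complete = run.merge(
            met_ok[["patient_id", "date"]], on=["patient_id", "date"]
        )
        crun_idx = _longest_run(complete["date"])
        if len(crun_idx) < min_days:
            removed_met += 1
            continue
        survivors.append((pid, complete.loc[crun_idx, "date"].tolist()))
    ledger.record("insufficient_actigraphy", removed_act)
    ledger.record("incomplete_met", removed_met)

    removed_zero = 0
    final_pids, final_days = [], []
    md = met_daily.set_index(["patient_id", "date"])
    for pid, dates in survivors:
        sub = md.loc[[(pid, d) for d in dates]]
        allzero = (
            (sub["mood_max"] == 0) & (sub["mood_min"] == 0)
            & (sub["energy_max"] == 0) & (sub["energy_min"] == 0)
        )
        if allzero.mean() > zero_frac_threshold:
            removed_zero += 1
            continue
        final_pids.append(pid)
        final_days += [(pid, d) for d in dates]
    ledger.record("excess_zero_met", removed_zero)

    patients_out = keep[keep["patient_id"].isin(final_pids)].reset_index(drop=True)
    day_index = pd.DataFrame(final_days, columns=["patient_id", "date"])
    days_out = day_index.merge(met_daily, on=["patient_id", "date"], how="left")
    assert ledger.check_conservation()
    return patients_out, days_out, ledger
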