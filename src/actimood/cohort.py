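"""Synthetic inpatient cohort generator.

Emulates the statistical structure the downstream analyses assume: four
diagnostic groups (default 54/42/34/79 patients), 4-20 days of 1-minute
wrist actigraphy per patient, circadian activity with superimposed bursts,
twice-daily signed mood/energy self-ratings on -10..+10, contiguous
off-wrist episodes, and a target ~31% prevalence of severe mood days.

Generative model (per patient, per day t):

* three AR(1) latents with common persistence ``mood_ar``:
  arousal ``a_t``, mood core ``m_t`` and an energy-specific residual ``e_t``;
* daily mood   = ``m_t - c_neg * max(a_t, 0)``
  daily energy = ``rho * mood + sqrt(1-rho^2) * e_t + c_pos * max(a_t, 0)``
  where ``c_neg``/``c_pos``/``rho`` are the group coupling coefficients;
* activity counts = truncated-at-zero circadian cosine + Poisson burst
  process + Gaussian noise, with burst rate and amplitude modulated by
  ``a_t`` -- so high-arousal days have larger extremal-window totals *and*
  (through the couplings) more extreme ratings;
* each rating = clip(round(gain * (latent + 0.5 * noise)), -10, 10).

The magnitude ``gain`` is calibrated by bisection at build time so that the
fraction of days with a mood rating of magnitude >= 7 hits the configured
prevalence target; with all coupling coefficients zero, ratings are
independent of the activity series and of each other by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as _date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import actigraphy
from .config import CouplingParams, GeneratorConfig
from .errors import ConfigurationError

MINUTES = np.arange(1440)
_PEAK_MINUTE = 900  # circadian activity peak at 15:00

#: Observed fraction of female patients per diagnostic group.
FEMALE_FRAC = {
    "ADHD_without_BD": 0.44,
    "BD_with_ADHD": 0.57,
    "BD_without_ADHD": 0.82,
    "OTHER": 0.75,
}


@dataclass
class PatientState:
    """Latent state carried across a patient's days."""

    patient_id: str
    group: str
    coupling: CouplingParams
    gain: float
    start_date: _date
    arousal: float = 0.0
    mood_chain: float = 0.0
    energy_chain: float = 0.0
    mood_latent: float = 0.0
    energy_latent: float = 0.0

    def init_latents(self, rng: np.random.Generator) -> None:
        """Draw the AR(1) chains from their stationary N(0,1) distribution."""
        self.arousal, self.mood_chain, self.energy_chain = rng.normal(size=3)

    def advance_day(self, rng: np.random.Generator) -> None:
        cp = self.coupling
        w = math.sqrt(1.0 - cp.mood_ar**2)
        self.arousal = cp.mood_ar * self.arousal + w * rng.normal()
        self.mood_chain = cp.mood_ar * self.mood_chain + w * rng.normal()
        self.energy_chain = cp.mood_ar * self.energy_chain + w * rng.normal()
        a_pos = max(self.arousal, 0.0)
        self.mood_latent = self.mood_chain - cp.neg_mood_activity_extreme * a_pos
        rho = cp.mood_energy_corr
        self.energy_latent = (
            rho * self.mood_latent
            + math.sqrt(max(0.0, 1.0 - rho**2)) * self.energy_chain
            + cp.pos_energy_activity * a_pos
        )


@dataclass
class Cohort:
    """In-memory synthetic cohort: the four tables plus generation metadata.

    ``epochs`` uses a compact schema (patient_id, date, minute,
    activity_count, off_wrist); :meth:`to_csv` writes the external ISO
    timestamp schema.
    """

    patients: pd.DataFrame
    epochs: pd.DataFrame
    met: pd.DataFrame
    sleep: pd.DataFrame
    severity_gain: float
    config: GeneratorConfig = None

    def to_csv(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        time_strs = np.array(
            [f"{m // 60:02d}:{m % 60:02d}:00" for m in range(1440)]
        )
        ep = self.epochs
        ts = (
            ep["date"].astype(str).to_numpy()
            + "T"
            + time_strs[ep["minute"].to_numpy()]
        )
        pd.DataFrame(
            {
                "patient_id": ep["patient_id"].astype(str),
                "timestamp": ts,
                "activity_count": ep["activity_count"],
                "off_wrist": ep["off_wrist"],
            }
        ).to_csv(outdir / "epochs.csv", index=False)
        self.met.to_csv(outdir / "met.csv", index=False)
        self.patients.to_csv(outdir / "patients.csv", index=False)
        self.sleep.to_csv(outdir / "sleep.csv", index=False)
        return {
            name: outdir / f"{name}.csv"
            for name in ("epochs", "met", "patients", "sleep")
        }


# ---------------------------------------------------------------------------
# day-level simulators
# ---------------------------------------------------------------------------

def circadian_baseline(cp: CouplingParams) -> np.ndarray:
    """Expected counts per minute: cosine with mesor/amplitude, 15:00 peak."""
    return cp.baseline_mesor + cp.baseline_amplitude * np.cos(
        2.0 * np.pi * (MINUTES - _PEAK_MINUTE) / 1440.0
    )


def inject_offwrist(
    valid: np.ndarray, rate: float, mean_minutes: float, rng: np.random.Generator
) -> np.ndarray:
    """Flag contiguous off-wrist blocks; Poisson(rate) episodes per day with
    exponential durations (so >=1 h invalidation cases occur)."""
    if rate <= 0:
        return valid
    for _ in range(rng.poisson(rate)):
        start = int(rng.integers(0, 1440))
        dur = max(1, int(round(rng.exponential(mean_minutes))))
        valid[start: start + dur] = False
    return valid


def simulate_day_activity(
    state: PatientState,
    day_index: int,
    rng: np.random.Generator,
    daytime=(420, 1320),
) -> actigraphy.EpochSeries:
    """One day of activity counts for the patient's current latent state.

    Counts are round(max(0, cosine baseline + bursts + Gaussian noise)); the
    burst process intensity and amplitude scale with latent arousal. With
    ``burst_rate=0`` and ``noise_sd=0`` the series equals the discretised
    cosine baseline exactly.
    """
    cp = state.coupling
    x = circadian_baseline(cp).copy()
    lo, hi = daytime
    hours = (hi - lo) / 60.0
    n_bursts = rng.poisson(cp.burst_rate * hours * math.exp(0.25 * state.arousal))
    amp_scale = cp.burst_amplitude_scale * math.exp(0.3 * state.arousal)
    for _ in range(n_bursts):
        start = int(rng.integers(lo, hi))
        dur = 1 + int(rng.geometric(1.0 / 8.0))
        x[start: min(start + dur, hi)] += rng.exponential(amp_scale)
    if cp.noise_sd > 0:
        x += rng.normal(0.0, cp.noise_sd, size=1440)
    counts = np.rint(np.clip(x, 0.0, None)).astype(np.int64)
    day = state.start_date + timedelta(days=day_index)
    return actigraphy.EpochSeries(
        patient_id=state.patient_id, date=day.isoformat(), counts=counts
    )


def simulate_met_ratings(
    state: PatientState,
    rng: np.random.Generator,
    rating_times=("08:00", "20:00"),
) -> list[tuple[str, int, int]]:
    """Signed integer ratings in [-10, +10] at the configured clock times.

    Each rating is the clipped, rounded latent value plus ordinal noise;
    morning and evening draw independent noise around the same daily latent.
    """
    out = []
    s = state.coupling.rating_noise_sd
    for t in rating_times:
        mood = latent_to_rating(state.gain, state.mood_latent, s * rng.normal())
        energy = latent_to_rating(state.gain, state.energy_latent, s * rng.normal())
        out.append((t, mood, energy))
    return out


def latent_to_rating(gain: float, latent: float, noise: float) -> int:
    """clip(round(gain * (latent + noise)), -10, 10) with ties away from
    zero, so a latent mapping exactly to 6.5 counts as 7."""
    v = gain * (latent + noise)
    r = math.floor(abs(v) + 0.5) * (1 if v >= 0 else -1)
    return int(min(10, max(-10, r)))


# ---------------------------------------------------------------------------
# prevalence calibration
# ---------------------------------------------------------------------------

def _latent_days(config: GeneratorConfig, rng, n_patients=300, n_days=8):
    """Latent mood values + rating noises for a calibration cohort drawn with
    the configured group mix (activity simulation skipped: severity depends
    only on mood ratings)."""
    total = sum(config.group_sizes.values())
    groups = []
    for g, n in config.group_sizes.items():
        groups += [g] * max(1, round(n_patients * n / total))
    lat = np.empty((len(groups), n_days))
    noise_sd = np.empty(len(groups))
    for i, g in enumerate(groups):
        cp = config.coupling[g]
        st = PatientState("c", g, cp, 1.0, _date(2000, 1, 1))
        st.init_latents(rng)
        for d in range(n_days):
            st.advance_day(rng)
            lat[i, d] = st.mood_latent
        noise_sd[i] = cp.rating_noise_sd
    noise = rng.normal(size=(len(groups), n_days, len(config.rating_times)))
    noise *= noise_sd[:, None, None]
    return lat, noise


def _severe_fraction(gain: float, lat: np.ndarray, noise: np.ndarray) -> float:
    vals = gain * (lat[:, :, None] + noise)
    ratings = np.clip(np.sign(vals) * np.floor(np.abs(vals) + 0.5), -10, 10)
    return float((np.abs(ratings).max(axis=2) >= 7).mean())


def calibrate_severity_gain(
    config: GeneratorConfig, rng: np.random.Generator, tol: float = 1e-3
) -> float:
    """Bisection on the latent magnitude gain so the severe-day fraction hits
    ``severe_prevalence_target``. The fraction is monotone non-decreasing in
    the gain (a pure magnitude inflation), so bisection is exact up to the
    Monte-Carlo resolution of the fixed calibration draws."""
    lat, noise = _latent_days(config, rng)
    target = config.severe_prevalence_target
    lo, hi = 0.05, 50.0
    if _severe_fraction(hi, lat, noise) < target:
        raise ConfigurationError("prevalence target unreachable at gain 50")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _severe_fraction(mid, lat, noise) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def generate_cohort(config: GeneratorConfig | None = None) -> Cohort:
    """Generate the full synthetic cohort; deterministic for a fixed seed.

    Randomness flows from one seeded :class:`numpy.random.SeedSequence`;
    per-patient substreams are spawned so any patient regenerates stably.
    """
    config = config or GeneratorConfig()
    config.validate()
    root = np.random.SeedSequence(config.seed)
    calib_ss, patients_ss = root.spawn(2)
    gain = config.severity_gain
    if gain is None:
        gain = calibrate_severity_gain(config, np.random.default_rng(calib_ss))

    order = [(g, i) for g in config.group_sizes for i in range(config.group_sizes[g])]
    streams = patients_ss.spawn(len(order))

    pat_rows, met_rows, sleep_rows = [], [], []
    ep_pid, ep_date, ep_counts, ep_valid = [], [], [], []
    dmin, dmax = config.days_per_patient
    for idx, ((group, _), ss) in enumerate(zip(order, streams)):
        rng = np.random.default_rng(ss)
        pid = f"P{idx:04d}"
        n_days = int(rng.integers(dmin, dmax + 1))
        start = _date(2022, 1, 1) + timedelta(days=int(rng.integers(0, 365)))
        age_months = int(rng.integers(156, 217))
        gender = "F" if rng.random() < FEMALE_FRAC.get(group, 0.5) else "M"
        pat_rows.append(
            {"patient_id": pid, "group": group, "age_months": age_months,
             "gender": gender}
        )
        state = PatientState(pid, group, config.coupling[group], gain, start)
        state.init_latents(rng)
        for d in range(n_days):
            state.advance_day(rng)
            series = simulate_day_activity(state, d, rng, config.daytime_window)
            valid = inject_offwrist(
                series.valid, config.offwrist_rate,
                config.offwrist_mean_minutes, rng,
            )
            ep_pid.append(idx)
            ep_date.append(series.date)
            ep_counts.append(series.counts)
            ep_valid.append(valid)
            for t, mood, energy in simulate_met_ratings(
                state, rng, config.rating_times
            ):
                m_miss = rng.random() < config.missing_rating_rate
                e_miss = rng.random() < config.missing_rating_rate
                if m_miss and e_miss:
                    continue
                met_rows.append(
                    {"patient_id": pid, "date": series.date, "time": t,
                     "mood_rating": np.nan if m_miss else mood,
                     "energy_rating": np.nan if e_miss else energy}
                )
            series.valid = valid
            rest = actigraphy.identify_rest_interval(series)
            sm = actigraphy.score_sleep(series, rest)
            sleep_rows.append(
                {"patient_id": pid, "date": series.date, **sm.as_dict()}
            )

    pat_df = pd.DataFrame(pat_rows)
    n_days_total = len(ep_date)
    pid_codes = np.repeat(np.array(ep_pid), 1440)
    epochs = pd.DataFrame(
        {
            "patient_id": pd.Categorical.from_codes(
                pid_codes, categories=pat_df["patient_id"].tolist()
            ),
            "date": np.repeat(np.array(ep_date), 1440),
            "minute": np.tile(MINUTES.astype(np.int16), n_days_total),
            "activity_count": np.concatenate(ep_counts).astype(np.int32),
            "off_wrist": (~np.concatenate(ep_valid)).astype(np.int8),
        }
    )
    met = pd.DataFrame(met_rows)
    sleep = pd.DataFrame(sleep_rows)
    return Cohort(
        patients=pat_df, epochs=epochs, met=met, sleep=sleep,
        severity_gain=gain, config=config,
    )


def read_cohort_csv(indir) -> Cohort:
    """Load a cohort previously written with :meth:`Cohort.to_csv`."""
    indir = Path(indir)
    ep = pd.read_csv(indir / "epochs.csv")
    ts = pd.to_datetime(ep["timestamp"])
    epochs = pd.DataFrame(
        {
            "patient_id": ep["patient_id"].astype(str),
            "date": ts.dt.strftime("%Y-%m-%d"),
            "minute": (ts.dt.hour * 60 + ts.dt.minute).astype(np.int16),
            "activity_count": ep["activity_count"].astype(np.int32),
            "off_wrist": ep["off_wrist"].astype(np.int8),
        }
    )
    return Cohort(
        patients=pd.read_csv(indir / "patients.csv"),
        epochs=epochs,
        met=pd.read_csv(indir / "met.csv"),
        sleep=pd.read_csv(indir / "sleep.csv"),
        severity_gain=float("nan"),
    )
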