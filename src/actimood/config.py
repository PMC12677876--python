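"""Configuration dataclasses for the simulation, feature and modelling stages.

Defaults encode the study design: four diagnostic groups of 54/42/34/79
adolescent inpatients, 1-minute actigraphy epochs, a 07:00-21:59 daytime
window, twice-daily mood/energy self-ratings on a signed -10..+10 scale,
a ~31% prevalence of severe mood days, and 5-fold/3-fold patient-grouped
cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import ConfigurationError

#: Canonical diagnostic group labels.
GROUPS = ("ADHD_without_BD", "BD_with_ADHD", "BD_without_ADHD", "OTHER")

#: Default number of patients per diagnostic group.
DEFAULT_GROUP_SIZES = {
    "ADHD_without_BD": 54,
    "BD_with_ADHD": 42,
    "BD_without_ADHD": 34,
    "OTHER": 79,
}

#: Daytime analysis window, minutes from midnight: [07:00, 22:00) i.e. 07:00-21:59.
DAYTIME_WINDOW = (420, 1320)


@dataclass(frozen=True)
class CouplingParams:
    """Group-specific generative couplings between latent arousal, activity,
    mood and energy.

    ``neg_mood_activity_extreme`` pushes daily mood toward the negative pole
    when latent arousal (which also drives activity bursts, hence extremal
    window totals) is high -- the signature reported for bipolar disorder
    without ADHD. ``pos_energy_activity`` raises positive energy with arousal
    -- the ADHD-without-BD signature. ``mood_energy_corr`` is the cross-loading
    of the energy latent on the mood latent; together with the ordinal rating
    noise (``rating_noise_sd``, latent units) its default is set so the
    *observed* correlation between daily maximum positive mood and energy
    comes out near the reported 0.78. All three are "coupling coefficients":
    with all of them zero, ratings are statistically independent of the
    activity series and of each other.
    """

    neg_mood_activity_extreme: float = 0.0
    pos_energy_activity: float = 0.0
    mood_energy_corr: float = 0.9
    rating_noise_sd: float = 0.3    # per-rating ordinal noise, latent units
    mood_ar: float = 0.9            # AR(1) day-to-day persistence of latents
    burst_rate: float = 6.0         # expected activity bursts per daytime hour
    burst_amplitude_scale: float = 400.0  # mean burst height, counts/epoch
    baseline_mesor: float = 100.0   # circadian cosine mesor, counts/epoch
    baseline_amplitude: float = 95.0
    noise_sd: float = 30.0          # per-epoch Gaussian noise, counts

    def validate(self) -> None:
        if self.burst_rate < 0:
            raise ConfigurationError("burst_rate must be >= 0")
        if not 0.0 <= self.mood_ar < 1.0:
            raise ConfigurationError("mood_ar must be in [0, 1)")
        if not -1.0 <= self.mood_energy_corr <= 1.0:
            raise ConfigurationError("mood_energy_corr must be in [-1, 1]")
        if self.baseline_mesor + self.baseline_amplitude < 0:
            raise ConfigurationError(
                "circadian baseline must have nonnegative expected peak"
            )

    def nulled(self) -> "CouplingParams":
        """Copy with every coupling coefficient zeroed (independence null)."""
        return replace(
            self,
            neg_mood_activity_extreme=0.0,
            pos_energy_activity=0.0,
            mood_energy_corr=0.0,
        )


def default_coupling() -> dict[str, CouplingParams]:
    """Per-group couplings realising the reported qualitative contrasts:
    tight negative-mood/activity coupling in BD without ADHD, strong
    positive-energy/activity coupling in ADHD without BD."""
    return {
        "ADHD_without_BD": CouplingParams(
            neg_mood_activity_extreme=0.2, pos_energy_activity=1.2
        ),
        "BD_with_ADHD": CouplingParams(
            neg_mood_activity_extreme=0.6, pos_energy_activity=0.4
        ),
        "BD_without_ADHD": CouplingParams(
            neg_mood_activity_extreme=1.2, pos_energy_activity=0.5
        ),
        "OTHER": CouplingParams(
            neg_mood_activity_extreme=0.4, pos_energy_activity=0.3
        ),
    }


def null_coupling() -> dict[str, CouplingParams]:
    """Per-group couplings with every coefficient zero: no label signal."""
    return {g: cp.nulled() for g, cp in default_coupling().items()}


@dataclass(frozen=True)
class GeneratorConfig:
    """Synthetic cohort generator settings; defaults mirror the study cohort."""

    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    days_per_patient: tuple = (4, 20)
    epoch_minutes: int = 1  # fixed by design
    daytime_window: tuple = DAYTIME_WINDOW
    coupling: dict = field(default_factory=default_coupling)
    severe_prevalence_target: float = 0.31
    severity_gain: float | None = None  # None -> calibrate by bisection
    offwrist_rate: float = 0.5          # expected off-wrist episodes per day
    offwrist_mean_minutes: float = 45.0
    rating_times: tuple = ("08:00", "20:00")
    missing_rating_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if not self.group_sizes:
            raise ConfigurationError("group_sizes must be nonempty")
        for g, n in self.group_sizes.items():
            if int(n) < 1:
                raise ConfigurationError(f"group size for {g!r} must be >= 1")
        lo, hi = self.days_per_patient
        if lo < 4:
            raise ConfigurationError(
                "days_per_patient lower bound must be >= 4 "
                "(the >=4 consecutive days inclusion rule)"
            )
        if hi < lo:
            raise ConfigurationError("days_per_patient range inverted")
        if not 0.0 < self.severe_prevalence_target < 1.0:
            raise ConfigurationError("severe_prevalence_target must be in (0,1)")
        if self.offwrist_rate < 0:
            raise ConfigurationError("offwrist_rate must be >= 0")
        if not self.coupling:
            raise ConfigurationError("coupling map must be nonempty")
        for g in self.group_sizes:
            if g not in self.coupling:
                raise ConfigurationError(f"no coupling parameters for group {g!r}")
            self.coupling[g].validate()
        if not 0.0 <= self.missing_rating_rate < 1.0:
            raise ConfigurationError("missing_rating_rate must be in [0,1)")


@dataclass(frozen=True)
class FeatureConfig:
    """Actigraphy feature-extraction settings."""

    k_windows: int = 4
    window_minutes: int = 60
    daytime_window: tuple = DAYTIME_WINDOW
    rest_threshold: float = 50.0   # counts: 10-min moving mean below -> rest
    rest_smooth_minutes: int = 10
    wake_threshold: float = 40.0   # counts/epoch at or above -> scored wake
    max_invalid_daytime_frac: float = 0.20
    invalid_window_policy: str = "exclude"  # or "impute_zero"
    selection: str = "optimal"      # or "greedy", kept for comparison


@dataclass(frozen=True)
class ClassifierConfig:
    """Leak-safe severity classification settings."""

    outer_folds: int = 5
    inner_folds: int = 3
    threshold_grid: tuple = (0.05, 0.95, 0.05)  # start, stop (inclusive), step
    threshold_objective: str = "accuracy"        # or "accuracy_f1"
    oversampling_neighbors: int = 5
    model_menu: tuple = (
        "logistic_regression",
        "gradient_boosted_trees",
        "random_forest",
        "extra_trees",
    )
    include_ensemble: bool = True
    seed: int = 0
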