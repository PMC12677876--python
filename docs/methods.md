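# Methods

## The analysis problem

Adolescents hospitalised for mood and behavioural disorders differ in how
their physical activity couples to their self-reported mood and energy:
bipolar disorder without ADHD shows tight coupling between extreme activity
fluctuations and negative affect, while ADHD without bipolar disorder links
high activity to positive energy. The package implements the full analysis
chain for this question — daily activity-extreme features from 1-minute
wrist actigraphy, daily mood/energy variables from twice-daily thermometer
self-ratings, categorical association statistics per diagnostic group, and
a leakage-safe classifier for same-day and next-day severe mood — together
with a synthetic cohort generator that stands in for the (non-shareable)
clinical data.

## Extremal window selection

The daily peak/trough features are the k = 4 nonoverlapping 60-minute
windows inside 07:00–21:59 whose summed counts are jointly maximal
(minimal). Selection is by exact dynamic programming over sliding-window
prefix sums: `dp[j][i]` is the best total using `j` windows with start
minutes ≥ `i`. Design choices, all configurable:

* **Joint optimality, not greedy.** Greedy selection of the single best
  remaining window can be suboptimal; a greedy variant is kept as a
  comparison utility and is tested never to beat the optimum.
* **Minute alignment.** Windows may start at any minute; hour alignment is
  dominated by sliding placement.
* **Nonoverlap within a mode only.** The max set and min set may overlap
  each other.
* **Ties.** Equal-total optima resolve to the earliest start minute, then
  lexicographically smallest placement — outputs are bit-reproducible.
  Minimisation is implemented as maximisation of the negated series, which
  makes max/min duality exact, tie-breaks included.
* **Invalid epochs.** A window containing any off-wrist epoch is ineligible
  (default) or invalid epochs count as zero (`impute_zero`).
* **Ranks.** Max1st is the largest total; Min1st the smallest. (Quartile
  numbering in the association stage is a separate concept: bin 1 = lowest
  quartile.)

## Quality control and sleep

The rest interval is the longest run of epochs whose 10-minute centred
moving-mean count is below 50 (ties → earliest; no midnight wrapping).
Sleep is invalidated by ≥ 60 invalid epochs inside the rest interval — the
boundary is tested at exactly 59 vs 60 — and a day is unusable when > 20%
of daytime epochs are invalid. The sleep scorer is a documented simplified
stand-in for the proprietary device algorithm: epochs below 40 counts are
asleep; efficiency = 100·sleep/duration; WASO counts wake epochs after
sleep onset; fragmentation = sleep→wake transitions per hour of sleep.
Thresholds are explicit configuration, not constants, because the vendor's
values are proprietary. `std_ac` uses the population denominator so small
fixtures are exact.

## Daily mood/energy variables and filters

Ratings are stored signed; positive/negative channel variables are
magnitudes over the day's ratings with the empty side reported as 0 (zeros
are recorded values on this instrument — which is also why patients whose
reports are all zero on more than 70% of days are excluded as clinically
uninformative). Severity bins extend the integer convention to the reals
via half-open intervals [3,5), [5,7), [7,∞), which removes the 4–5 gap
ambiguity. The filter cascade is patient-level, ordered, idempotent, and
recorded in a ledger whose conservation (initial = final + Σ removed) is
asserted on every run. "Consecutive" means calendar-adjacent usable days;
the longest run is retained. Boundary-day (admission/discharge) trimming is
off by default because synthetic days are complete; the flag exists for
real exports. "Incomplete" ratings are interpreted as whole-day missing
(either channel absent for the day).

## Association statistics

Kruskal–Wallis (tie-corrected, chi-square approximation) and pairwise
Mann–Whitney U (normal approximation with continuity and tie correction)
compare groups; the Bonferroni-corrected threshold defaults to .004 and is
an input, not derived, since the divisor that produced it is not uniquely
determined. Quartile binning runs `pandas.qcut` on rank-transformed values,
guaranteeing bin counts within 1 of each other under ties; fewer than four
distinct values is a degenerate error and the feature is dropped with a log
record. Chi-square uses no Yates correction; empty severity categories are
dropped before computing degrees of freedom. Cramér V carries no bias
correction. Binning is within diagnostic group by default (associations are
reported per group); pooled binning is a flag. IQRs use linear quantile
interpolation; SDs are sample SDs.

## Severity classification

Labels are mood-only (energy enters only as a predictor); the severe
threshold is magnitude ≥ 7, the upper edge of the "moderate" bin. Next-day
labels require calendar adjacency — rows at gaps or on a patient's last day
are dropped rather than imputed. The feature matrix is built from an
explicit allow-list (actigraphy, sleep, energy, demographics) and a guard
raises if any mood-derived column would enter it.

Validation is 5-fold patient-grouped cross-validation with an inner 3-fold
grouped loop for hyperparameter selection (small documented grids; ROC-AUC
criterion). Median imputation, standardisation, minority oversampling and
threshold tuning are all fit strictly inside training folds; per-fold
train/test patient sets are recorded in an audit object so the guards can
be asserted after the fact. Oversampling is SMOTE-style — a sampled
minority row plus a uniform convex step toward one of its k = 5 nearest
minority neighbours — implemented in-package and applied until classes
balance. The decision threshold sweeps 0.05–0.95 in steps of 0.05 on one
reserved grouped split of the training fold, maximising accuracy (F1 also
reported; an accuracy+F1 composite is a config switch); ties resolve toward
0.5 then to the lower threshold. Single-class test folds record AUCs as
missing rather than 0.5 so fold means are not biased. The soft-vote
ensemble is the unweighted mean of the member models' fold probabilities,
thresholded at the mean member threshold. Permutation importance is the
mean ROC-AUC drop from shuffling one feature within each frozen test fold,
averaged across folds and repeats.

## Synthetic cohort generator

The generator states a world with the cohort's structure: four groups of
54/42/34/79 patients, 4–20 complete days each, 1440 one-minute epochs per
day, two ratings per day (08:00, 20:00), ~31% severe-day prevalence, and
Poisson off-wrist episodes (0.5/day, exponential mean 45 min) so the ≥1-h
invalidation rule is exercised.

Per patient, three daily AR(1) latents (arousal, mood core, energy
residual) share persistence 0.9. Activity is a truncated circadian cosine
(mesor 100, amplitude 95 counts, 15:00 peak) plus a Poisson burst process
(6/daytime-hour, exponential amplitudes, mean 400 counts) whose rate and
amplitude scale with arousal, plus Gaussian epoch noise (SD 30). Group
coupling coefficients tie the latents together: `neg_mood_activity_extreme`
pushes mood negative on high-arousal (high-activity-extreme) days — largest
for BD without ADHD; `pos_energy_activity` raises positive energy with
arousal — largest for ADHD without BD; `mood_energy_corr` cross-loads
energy on mood. Ratings are clip(round(gain·(latent + ordinal noise))).
With every coupling coefficient zero, ratings are independent of the
activity series and of each other, which is what the null-calibration and
type-I tests rely on.

Three generator constants were set once from reported quantities rather
than invented: the latent mood–energy cross-loading (0.9) together with the
rating noise (SD 0.3 latent units) reproduces the observed ≈0.78
correlation between daily maximum positive mood and energy; the AR
persistence (0.9) reflects the reported small degradation from same-day to
next-day prediction; and the magnitude gain is calibrated at build time by
bisection against the 31% severe-day prevalence target. The gain is the
only monotone parametrisation for that calibration — an additive intercept
is not monotone when both rating poles count as severe — and prevalence is
tested to be monotone in it. Missing-rating frequency has no reported
value; the default is a nominal 2% per rating.

What the generator does **not** emulate: physiological accelerometry
detail, medication and ward-schedule effects, partial admission/discharge
days, informative (state-dependent) missingness, and any within-day
mood–activity dynamics (latents are daily). A green downstream test
therefore establishes that the pipeline recovers the stated structure, not
that it would perform identically on clinical data.

## Numerical and testing notes

* All randomness flows from one `SeedSequence`; per-patient substreams make
  patient regeneration stable; fixed seeds make the full experiment
  bit-reproducible.
* Window DP uses int64 prefix sums with an integer infeasibility sentinel,
  so optima and tie-breaks are exact, and is tested against exhaustive
  enumeration on ≥200 random fixtures plus 1000 max/min duality checks.
* Rank tests, chi-square and AUCs are checked against hand computations,
  exact enumeration (Mann–Whitney at n ≤ 8, tolerance 0.02) and the
  Mann–Whitney/ROC-AUC identity.
* Synthetic-recovery checks run at roughly half the study's patient count
  with a logistic-regression-only menu to fit a single-CPU budget; the
  thresholds (same-day AUC ≥ 0.75, null band 0.45–0.55, type-I fraction
  ≤ 2% at p < .004) are unchanged.
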