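# Methods

## The measurement problem

A patient's momentary self-reports (EMA) and a support person's
perceived-state reports about that patient (PeerMA) form two sparse,
irregularly sampled time series per construct. The package quantifies how
well the observer stream tracks the patient stream, treating the patient's
stream as the reference: the observer is modelled as an approximation to
the patient, never the reverse. Analysis is strictly daily — a report's
"day" is its local calendar date, and sub-day dynamics are not modelled.

## Prompt schedule and compliance accounting

Prompts are time-contingent per construct: hope weekly on Fridays at a
uniformly random time between 2 PM and 6 PM, sleep quality weekly on
Tuesday/Thursday/Sunday around 10 AM, fatigue weekly on Mondays (random
2–6 PM window), pain bi-weekly on Tuesdays around 2 PM, and depression
every 3 weeks on Wednesdays around 2 PM. Unattended prompts expire after
one hour and are logged as incomplete. Week indexing is
`k = floor((date − enrollment)/7)`; a period-p rule fires in weeks with
`k mod p = 0`, so the enrollment day itself is eligible. With a Monday
enrollment this yields exactly 164 expected prompts over 196 days; other
enrollment weekdays shift the count by at most ±3, which is why expected
counts printed without a calendar anchor are treated as given inputs rather
than recomputation targets.

Response rate is `round(100·(answered_app + answered_self)/expected)`,
rounded half-up — the convention that reproduces every checkable published
rate (161/164→98, 147/164→90, 69/140→49, 98/77→127). Voluntary
self-triggered reports count toward the numerator, so rates above 100% are
meaningful, not errors. Study totals are plain sums; dispersion uses the
sample (n−1) standard deviation.

## Preparation chain

* **Deduplication.** Within each (construct, day): drop incomplete records
  if a complete one exists, then drop the oldest of the remainder until one
  is left. The operation is idempotent.
* **Normalization.** Per person, each construct's raw slider values are
  min-max rescaled to [0, 1] (`per_construct` scope, the default — it lets
  every construct attain 0 and 1, consistent with published per-construct
  medians of exactly 0.00 and 1.00). An `all_constructs` scope pooling one
  person's values across constructs is selectable. A degenerate group (all
  values equal) maps to 0.5 — any constant is defensible; 0.5 is
  centre-unbiased — with a logged warning.
* **Alignment.** A dyad's common range starts at the patient's first
  report and ends at the earlier of the two last reports, maximizing the
  shared assessment set. This is a one-shot rule: re-aligning the trimmed
  streams can only shrink the range further (it never extends), and is a
  fixed point whenever the boundary reports survive the trim.
* **Imputation.** Missing days are filled by ridge regression on degree-2
  polynomial features of the day index, rescaled to [0, 1] for
  conditioning. The penalty weight defaults to 1.0 and applies to the
  slope and curvature coefficients only (the intercept is free), so a
  constant input yields a constant curve under any penalty, and penalty → ∞
  flattens the fit to the observed mean. Fitted values are clipped to
  [0, 1]; observed days keep their observed value verbatim, the pure fitted
  curve being exported separately for plotting. Fewer than 3 observed
  points under-determine the parabola: the library raises, and the pipeline
  falls back to a constant observed-mean series with a logged warning.

## Concordance layer

Similarity metrics (MAE, MSE, RMSE, R²) are computed on the full aligned
imputed curves, since both participants are then represented on the same
daily grid; R² treats the patient curve as ground truth and can be
arbitrarily negative for a poor observer. Mean-difference concordance bins
|mean(patient) − mean(peer)| at 5/10/15% with upper-inclusive, mutually
exclusive bins (the boundary case d = 0.10 belongs to "≤10%"); the
difference is rounded to 9 decimals first so binary-float artifacts cannot
move an exact boundary across a bin. 15% is the minimal-importance-
difference convention for patient-reported outcomes.

Dyad correlations default to pairing same-day *observed* assessments
(pairing the imputed curves is available as `imputed_daily`), because
correlating smoothed curves inflates n and autocorrelation; steps
correlations likewise pair observed report days with that day's step
count. Spearman's r_s uses average ranks for ties. The two-sided p-value
is computed by exact enumeration of all n! pairings when n ≤ 7 — at such
sizes the usual t approximation misstates p by large margins — and by the
t approximation otherwise. p-values are reported, never used for gating,
and no multiple-testing correction is applied.

Strength classification rounds r_s half-up to 2 decimals (decimal
arithmetic, so 0.335 → 0.34) and bins: ≥ 0.67 highly positive, 0.34–0.66
moderately positive, 0.00–0.33 weakly positive, and mirrored on the
negative side; exactly 0 counts as weakly positive by convention (the
published interval endpoints both nominally include 0.00). The published
interval bounds partition the line only at 2-decimal resolution, which is
why rounding precedes binning. Note one known quirk of the source tables
this package reproduces from: the published sleep-column summary counts
three correlations of 0.29/0.15/0.07 as moderately positive although the
stated intervals place them in weakly positive; this implementation follows
the stated intervals, so those two cells (and the overall
moderate/weak-positive totals they feed) intentionally differ, while every
percentage that is invariant to that assignment (total positive share,
highly-positive share, the full negative side) agrees.

## Synthetic dyads

The generator emulates the study conditions rather than any particular
dataset: 7 dyads over 140 days (the observed mean patient participation was
~143 days), patient/peer answer probabilities 0.63/0.74 (the observed mean
response rates), and a voluntary self-trigger rate of 0.25 reports/day
(between the observed patient ≈ 0.18/day and peer ≈ 0.33/day volumes).

* **Latent states.** Per construct, a mean-reverting Gaussian walk
  `x[t+1] = x[t] + ρ(μ − x[t]) + N(0, σ_v)`, clipped to [0, 1], with
  ρ = 0.1 and σ_v = 0.05 — bounded, slowly drifting trajectories whose
  autocorrelation matches clinical states that change over days, not
  minutes. Baselines per construct follow the observed per-construct mean
  levels (hope 0.60, sleep 0.68, fatigue 0.45, depression 0.34, pain 0.37).
* **Peer channel.** Perceived value =
  `clip(latent(day − τ) + b + N(0, σ))` with defaults b = 0.05, σ = 0.15,
  τ = 0 whole days; these produce curve-level MAEs in the 0.05–0.3 range
  typical of the published per-dyad similarity scores. Confidence is a
  clipped normal (mean 0.8, SD 0.15), independent of the error magnitude by
  default; a coupling option (confidence decreasing in |noise|) exists for
  sensitivity studies.
* **Compliance.** Bernoulli per prompt; unanswered prompts become
  incomplete records. Self-triggered reports arrive Poisson per day at
  uniformly random daytime instants and are always complete. Poisson
  arrivals are a declared modelling assumption, not an empirical
  distribution.
* **Wearables.** `steps = max(0, 6000 + Σ_c w_c·latent_c + N(0, 1000))`
  with w = +1500 (hope), +500 (sleep), −3000 (fatigue), −1500 (depression),
  −2000 (pain) — signs matching the direction of the observed
  steps-vs-construct correlations; sleep hours = 5 + 3.5·latent_sleep +
  noise. Active-minute splits are a crude derivation from steps; minute-
  level dynamics and delivery failures are not modelled.

What the generator deliberately does **not** emulate: non-stationary
dropout (participants leaving mid-study), notification-delivery failures,
response-style artifacts (anchoring, socially desirable responding), or
within-day state oscillation. Tests passing on synthetic dyads therefore
demonstrate correctness of the pipeline's arithmetic and its recovery of
known generative parameters — not validity of PeerMA as a clinical
instrument on real populations.

Everything is deterministic under (config, seed): per-stream sub-seeds are
derived from the master seed via a seed sequence, and all derived seeds
stay below 2³¹.

## Problem sizes and numerical choices

Tests and the acceptance script run the simulator at 56–364 days and 1–7
dyads — large enough for 3σ binomial and bias-recovery bounds to be
informative, small enough to keep the whole suite in seconds. Monte-Carlo
checks of the latent stationary mean use 10 000 days. The imputation
oracle is the closed-form penalized normal-equation solution
`(XᵀX + λ·diag(0,1,1))β = Xᵀy`; agreement is asserted to 1e-8. Spearman
agreement with a brute-force rank oracle is asserted to 1e-12 on all
tested n ≤ 7 inputs, and exact-permutation p within 0.02.

## Known limitations

* Expected prompt counts depend on the enrollment weekday; without a
  calendar anchor they are reproducible only to ±3 per 28 weeks.
* The published participant-day totals (1142/976) do not equal the sums of
  the published per-participant day columns (1013/748); day totals are
  reported but never asserted.
* The support persons' published mean response rate (74%) differs from the
  mean of the recomputed per-row rates (76%); only the patient-side mean
  (63%, which does agree) is asserted.
* Per-dyad similarity scores of the original raw streams cannot be
  recomputed (the streams were never deposited); that layer is exercised
  structurally through simulation only.
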