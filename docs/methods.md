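# Methods

## Detection model

Weekly series are indexed by session 0 (baseline) … 12; candidate
pregain sessions are *N* ∈ {2, …, 10}, so the baseline can serve as the
*N*−2 flanking score of the earliest candidate. Both interval endpoints
must be observed — criteria 1–2 are undefined otherwise; only the
flanking window scores may be missing. Each window needs at least
`min_present = 2` observed scores, which restricts the stability df to
{2, 3, 4}; the critical values are the upper 97.5 % Student-*t*
quantiles at three printed decimals (2.776 / 3.182 / 4.303), and for
non-default windows the quantile is computed directly. Window SDs are
Bessel-corrected. Two reading choices fixed here:

* inequalities follow the criteria as stated: `≥` for the magnitude
  criteria, strict `>` for stability;
* if both window SDs are zero (step functions), stability passes iff
  `mean_pre > mean_post` — the limit of the inequality as the pooled SD
  goes to 0.

If a patient has several gains, the earliest is primary. Windows of
adjacent gains may overlap; an interval is never emitted twice. A gain
is reversed when any later observed score reaches
`score_{N+1} + 0.5·magnitude`; a stable reversal additionally meets
sudden-loss criteria at some later interval (searched over all later
intervals, not only the candidate range). Sudden losses apply the same
criteria to the reflected series (`51 − score`), so the relative
criterion for a loss compares the rise against the reflected pregain
score; this is the only definition under which losses on a series equal
gains on its reflection, which the tests verify by running both code
paths.

Reported percentages round half-up to two decimals so that printed
counts map to unique printed percentages.

## Matching

The propensity model is a maximum-likelihood logistic regression of
gain status on ten baseline covariates (age, gender, months since
trauma, trauma type, comorbid depression, and baseline symptom,
depression, anxiety, appraisal and memory scores), with categorical
covariates as indicator contrasts; constant columns are dropped, rows
with missing covariates are excluded and reported, and perfect
separation falls back to a ridge-penalized fit with a warning. The
caliper is 0.25 × SD of the **linear** propensity (log-odds) — the
standard convention when a bare caliper width is quoted; a
probability-scale caliper is available via `caliper_scale`. Mahalanobis
distances use the pooled covariance of the covariates over the full
analyzed cohort (pseudo-inverse with a warning if singular). Matching is
greedy nearest-neighbour without replacement, gainers processed in
descending linear propensity (hardest to match first); exact distance
ties break by a seeded candidate order. Unmatched gainers are excluded
from matched analyses and listed in the run report.

## Longitudinal models

All mixed models are random-intercept linear models estimated by
maximum likelihood. Outcome models use categorical time (end of
treatment, follow-up), group, their interaction, and the baseline score
of the dependent variable as a covariate; patients missing a timepoint
contribute their remaining rows through the likelihood (no imputation).
Process models use the five scores at *N*−2 … *N*+2 with categorical
time × group; δ₁/δ₂/Δ₃ are linear contrasts of the fixed effects, so
Δ₃ = δ₁ − δ₂ holds identically. Contrast p-values use the normal
approximation to the contrast z (the df convention is not part of the
method definition). On degenerate data — zero residual variance, as in
noiseless simulations, or single-timepoint designs — the mixed fit
cannot converge and the estimator falls back to OLS on the identical
fixed-effects design; for balanced complete data the point estimates
coincide. Cohen's *d* divides the adjusted mean difference by the pooled
baseline SD and is reported as a magnitude (gainers better → positive
*d*); with a constant baseline it is reported as absent.

The adjusted SMD is `(δ₁ − δ₂) / s_p` with `s_p` pooled from the raw
interval difference-score SDs, and
`se = √((n₁+n₂)/(n₁n₂) + smd²/(2(n₁+n₂)))` — the standard large-sample
formula for a standardized two-group difference; a Hedges small-sample
correction is available and off by default. Fixed-effects pooling uses
inverse-variance weights, `se = 1/√Σw`, z-based 95 % CIs. No
heterogeneity statistics or random-effects models are provided, and no
multiple-testing correction is applied (α = .05 throughout).

## Synthetic cohorts

The generator emulates a routine trauma-clinic sample: age ~ truncated
Normal(38.9, 11.2) ≥ 18; 43 % female; months since trauma lognormal
(median 20); trauma types 60/20/11/9 % across interpersonal, accident,
harm-to-others and other; 51 % comorbid depression. Baseline symptom
severity is truncated Normal(34, 8.7) on [15, 45]: moderate-to-severe
presentations, kept off the scale floor and ceiling so embedded steps
are never erased by clipping. Symptom trajectories are
`baseline − slope·t − step + noise`, clipped to [0, 51] and rounded to
integer totals (questionnaire sums are integers); process scores stay
continuous. Parameters that matter, with defaults:

| parameter | default | rationale |
|---|---|---|
| `gain_fraction` | 0.31 | roughly one third of patients show a gain |
| `gain_magnitude_mean/sd` | 12.3 / 4.4 | typical observed gain size; magnitudes truncated at the 6.15 cutoff because an embedded event is by construction a true sudden gain |
| `trend_slope_mean/sd` | 1.2 / 0.4 points/week | gradual improvement consistent with a ~34 → ~19 course over 12 weeks; per-patient slopes are capped so the noiseless trajectory stays on-scale, preserving unambiguous ground truth |
| `noise_sd` | 2.5 points | week-to-week fluctuation; the instrument's true error variance is not published, so this is a modelling choice |
| `process_coupling` | 2.0 | maps the 0–51 symptom scale into the wider process ranges |
| `process_lead_sessions` | 1 | appraisal/memory change precedes the symptom step by one session — the temporal-precedence mechanism the around-gain analysis is designed to detect |
| `missing_rate`, `dropout_hazard` | 0.05, 0.02 | sporadic skipped sessions plus ~20 % cumulative dropout over 12 weeks |

A skipped session removes that week's scores on every measure; baseline
is never missing; after dropout all later sessions are missing and no
follow-up is collected. Follow-up scores for completers are the final
weekly score plus noise. One seed drives four documented substreams
(covariates, trajectories, missingness, follow-up), so cohorts are
bit-reproducible.

**What the generator does not emulate**: item-level questionnaire
structure, exponential or other smooth rapid-response shapes (gains are
pure steps, which gives unambiguous ground truth but makes detection
easier than for gradual-but-fast responders), informative missingness,
therapist/session content, and sample-specific instruments (one
depression/anxiety scale pair is simulated, not per-sample variants).
Passing tests therefore demonstrate correctness of the analysis
machinery under a known step-change process, not detector performance on
real trajectories.

Two simulation behaviours are worth knowing when interpreting outputs.
First, detection conditions on the gainer's own measurement noise, so
intervals adjacent to the gain carry a small regression-to-the-mean
bias (visible as slightly positive pooled SMDs in no-effect intervals);
the matched design does not remove it because controls are not selected
on their noise. The mechanism test is therefore directional: a
one-session process lead must produce a significant *negative* pooled
pregain effect, and without a lead such a negative effect almost never
occurs. Second, under the default noise the detector's per-patient
sensitivity is ≈ 0.7 (missed eligibility from missing scores, noise
undoing marginal steps), which is the realistic operating regime rather
than the noiseless ideal.

## Problem sizes used by the test suite

Simulation-based tests use cohorts of 200–500 patients, the mechanism
test 50 replicates of two 240-patient samples per arm, and the
acceptance script two samples of 248 and 234 patients — sizes at which
every stage's behaviour is stable while the whole suite stays fast.
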