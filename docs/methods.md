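# Methods

This note documents the models and procedures implemented in `actiscore`,
the assumptions behind them, and the numerical and design choices made
where the underlying method description leaves the design open.

## The epoch grid and the PSG collapse

PSG staging is visual and per 30-s epoch over the five AASM stages
W, N1, N2, N3, R; the actigraph stores one activity level per 2-min epoch.
All comparison happens on the 2-min grid.  Each non-overlapping block of
four 30-s stages, starting at lights-off, becomes one 2-min epoch:

1. two or more Stage W in the block → W_PSG;
2. otherwise S_PSG, sub-classified by the most frequent non-W stage;
3. frequency ties are broken by the priority R > N1 > N2 > N3.

Rule 3 is conventionally illustrated for two-way ties only; we apply the
same priority list to any tie (e.g. a block W/N1/N2/N3 collapses to
S_PSG/N1: the single W is discarded and the three-way tie falls to N1, the
highest-priority stage present).  The collapse is validated in the test
suite against a brute-force transcription of the three rules on all
5⁴ = 625 possible blocks.

Trailing stages that do not fill a block are dropped by default
(`trailing="error"` is available).  Nights longer than a configurable cap
(default 420 min, i.e. the first 7 h) are truncated before collapsing;
shorter nights are used whole.  Time in bed (TIB) is 2 min × the number of
collapsed epochs actually analysed.

Legacy stage tokens ("Stage 1/2/3+4/REM") are mapped to N1/N2/N3/R at read
time; the mapping lives in `epochs.LEGACY_STAGE_MAP`.

## Discriminant scoring

Every 2-min epoch is scored from the symmetric 10-min window
(x₋₂, x₋₁, x, x₊₁, x₊₂) of counts:

    z = a₋₂x₋₂ + a₋₁x₋₁ + a·x + a₊₁x₊₁ + a₊₂x₊₂,

no intercept; z ≥ threshold (default 1, compared with exact ≥, no epsilon)
is wake.  The shipped `CHILD_FS760` model carries the published
school-aged-children coefficients (0.108294, 0.147294, 0.230126, 0.099353,
0.059580) with threshold 1.

The first and last two epochs of a night lack full window context.  The
original device's behaviour at the boundary is not documented, so both
policies are provided and recorded in the output: `"zero"` (default;
missing neighbours contribute zero activity, deterministic, biases edges
toward sleep — conservative at lights-off, where subjects are typically
awake for several epochs anyway) and `"extend"` (replicate the nearest
observed count).

## Sleep parameters and the run-length rules

PSG: SL is 2 min × the index of the first S_PSG epoch; TST is 2 min × the
number of S_PSG epochs from onset to lights-on; WASO = TIB − (SL + TST);
SE = 100·TST/TIB.  A night with no sleep epoch carries a "no onset" flag
(SL/WASO/TST = nan, SE = 0).

Activity: sleep onset is the first epoch of the first run of at least
n_SL consecutive S_ACT epochs; WASO counts only maximal W_ACT runs of at
least n_WASO epochs strictly after onset (shorter wake bursts are treated
as sleep in the parameter arithmetic; the epoch labels themselves are
never rewritten, so validation metrics are unaffected); TST = TIB − SL −
WASO, making SL + WASO + TST = TIB an exact identity for both methods.

The qualifying-run condition is conventionally phrased "more than n
epochs".  We read it as ≥ n: under a strict > n reading the n = 1 rule
could never be satisfied by a single-epoch run, contradicting the n = 1
point of the published calibration curves.  The strict reading is
available via `strict_gt=True` (CLI `--strict-gt`).

The calibration search evaluates n = 1..10 (2–20 min).  For each n the
cohort mean of the activity parameter is compared with PSG by two-sided
paired t-test and ICC; n is feasible when p ≥ 0.05 (no significant
difference) and ICC ≥ 0.6, and among feasible n the one minimising the
absolute mean difference wins, smallest n on ties.  WASO is searched with
the onset rule fixed at the already-optimized n_SL.  The shipped defaults
are the published optima n_SL = 4, n_WASO = 5.  Subjects with no
qualifying onset at a given n are dropped pairwise for that n.

## Validation statistics

Sensitivity is the fraction of S_PSG epochs scored S_ACT (true sleep
detection), specificity the fraction of W_PSG epochs scored W_ACT.  The
per-stage agreement of a sleep substage is the fraction of its epochs
scored S_ACT; for W it is the fraction scored W_ACT, so overall agreement
is the epoch-count-weighted mean of the per-stage agreements (asserted as
an invariant).  Metrics are computed per subject and then averaged across
subjects (mean ± SD presentation); empty denominators (e.g. a night with
no W_PSG epoch) produce flagged missing values excluded from cohort means.

Method agreement across subjects uses the intraclass correlation.  No
particular ICC form is dictated by the design; we default to ICC(2,1) — two-way
random effects, absolute agreement, single measures — the standard choice
for method-comparison, which penalises systematic offsets; ICC(3,1)
(consistency) is available.  The computation is delegated to
`pingouin.intraclass_corr`; the test suite checks it against an
independent closed-form ANOVA mean-squares decomposition.  Degenerate
cases are defined explicitly: identical raters with between-subject
variance → (1.0, p = 0); no variance anywhere → undefined (nan, flagged).
Similarly, a paired t-test on identically-zero differences (0/0 in the
usual formula) is defined as t = 0, p = 1, so that perfectly concordant
cohorts are treated as "no significant difference" rather than undefined.

## Discriminant derivation

Training rows are the same 5-epoch windows used in scoring, one per 2-min
epoch pooled over all training subjects (no per-subject weighting),
labelled by the collapsed PSG class of the centre epoch (S = 0, W = 1).
The classifier is Fisher's linear discriminant: w ∝ Σ_pooled⁻¹(μ_W − μ_S)
with the equal-cost cut at the class-mean midpoint, c₀ = w·(μ_S + μ_W)/2.
How the original method arrives at a threshold of exactly 1 is not
specified; dividing w by c₀ places the boundary at w′·x = 1 without
changing any decision, and reproduces the qualitative features of the
published vector (all-positive coefficients, largest at the centre,
threshold 1).  A prior-weighted cut (log-prior offset along w) is
available; it makes the rule affine and the offset is folded into the
reported threshold.  Degenerate inputs fail loudly: a single-class pooled
set, coincident class means, or c₀ ≤ 0 raise `DegenerateDataError`; a
singular pooled covariance (possible with integer counts) triggers a
ridge-regularised refit with λ = 10⁻⁶·trace(Σ)/5 and a warning.

The split-sample design is a seeded subject-level random partition into
two near-equal groups (sizes differ by at most one), deterministic given
the seed.

## The simulator

The generator stands in for laboratory recordings and defines the
conditions under which the stack is exercised:

* **Hypnogram**: a first-order Markov chain over the five stages at 30-s
  steps, starting awake at lights-off, over a default 420-min (7-h) TIB.
  The default kernel was tuned once to the overnight regime the method
  assumes — cohort mean sleep efficiency near 90% (band 85–95%), sleep
  latency of roughly 8–10 min, WASO of roughly 30–40 min, and realistic
  stage proportions (N2 the modal stage, consolidated N3 early-night-like
  long runs, REM bouts of ~10 min).
* **Activity**: each 2-min epoch draws an integer count from a
  negative-binomial law (dispersion k = 2, variance m + m²/k) with a mean
  set by the epoch's dominant stage — the stage the collapse rule assigns
  to its four 30-s stages — rounded and clipped to the device range
  [0, 31].  Default child means (W 8, R 1.6, N1 0.8, N2 0.4, N3 0.2)
  exceed the adult means (6, 0.8, 0.4, 0.2, 0.1) in every stage, the
  child/adult contrast the method is sensitive to.  REM is set well above
  N1 so that the mean discriminant score per stage follows the activity
  ordering W > R > N1 > N2 > N3 even though N1 epochs, which border wake
  bouts, inherit activity from their neighbours through the 10-min window.
* **Quiet wakefulness**: with probability 0.3 an entire wake bout is
  "quiet" — the subject lies still and the bout's count mean drops to 0.8,
  near sleep level.  Quietness is drawn per bout, not per epoch, because
  motionless wakefulness persists for minutes at a time; this is the
  mechanism that caps actigraphic specificity (the shipped coefficients
  score simulated child cohorts at roughly 90% agreement, 92–97%
  sensitivity, 60–75% specificity — high sensitivity, low specificity, as
  actigraphy validation studies consistently report).
* **Reproducibility**: two independent RNG streams (stage chain, counts)
  are spawned from the master seed, so changing the activity model leaves
  the hypnogram trace untouched; cohort subjects use spawned per-subject
  seeds.

What the simulator does **not** model: apnea or movement-disorder events,
circadian drift across the night beyond what the homogeneous kernel
implies, first-night effects, within-epoch 30-s activity mixing (counts
depend only on the dominant stage), or any particular child/adult activity
magnitudes beyond the stated orderings.  Tests passing on simulated
cohorts therefore demonstrate the correctness of the pipeline's
*computations* and the qualitative regime of its statistics, not clinical
accuracy on real recordings.

## Problem sizes and numerics

The simulator-based tests and the acceptance analysis use 7-h nights
(210 epochs) and cohorts of up to 65 subjects — the scale of the original
validation design — which keeps every analysis to a few seconds.
Exhaustive oracles run over all 625 collapse windows and 1000 random
series per property.  Discriminant recovery is exercised at 10⁴ samples
per class.  Floating-point comparisons in scoring are exact dot products;
thresholds are compared with exact ≥; serialization round-trips scores to
better than 1e-9 (`repr`-based CSV writing).
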