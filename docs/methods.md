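# Methods

This note documents the models, defaults and design choices behind
`delaydetect`: what is simulated, what is estimated, how the statistics
are defined, and where the open choices were resolved.

## Adaptive threshold estimation (MLP)

Responses are modelled by a logistic psychometric function with a
false-alarm floor, `p(x) = a + (1−a)/(1+exp(−k(x−m)))`, with stimulus
level `x` in ms (keystroke–sound delay, or anisochrony displacement).
The engine maintains a fixed candidate grid — midpoints linearly spaced
over the task range, endpoints included, crossed with false-alarm rates
(0, .1, .2, .3, .4) — and accumulates each candidate's log-likelihood
incrementally over trials (3000 candidates × 36 trials is exact and cheap
in log space; probabilities are clamped to [1e−12, 1−1e−12] before the
log, with a warning when the clamp contradicts an observed response).

Parameters that matter:

* **slope `k`** — not part of the task protocol; a single shared value,
  default 0.1 per ms (10–90% span ≈ 44 ms), configurable per task. All
  reported thresholds are conditional on `k`; it is echoed into session
  manifests. Parameter recovery is insensitive to the exact value as long
  as observer and model share the family.
* **tracking probability `p_target`** — default 0.707, the conventional
  adaptive-tracking point; configurable (the engine accepts any target in
  `(a, 1)` and raises for targets at or below the candidate's false-alarm
  rate). The next stimulus is the closed-form inverse
  `x = m + ln((p−a)/(1−p))/k` of the current maximum-likelihood curve,
  clamped to the task range.
* **threshold readout** — the midpoint `m` of the final
  maximum-likelihood curve. For observers drawn from the logistic family
  this readout is unbiased (recovery within ~1% at midpoints 60–300 ms).
  For a *hard-step* responder the track hovers at the level where the
  model predicts `p_target`, so the midpoint readout sits
  `ln(p_target/(1−p_target))/k` (≈ 8.8 ms at the defaults) below the
  step; at `p_target = 0.5` the readout pins the step within grid
  resolution. This is a property of asymmetric tracking, not an estimator
  defect.
* **tie-breaking** — equal likelihoods resolve to the smallest midpoint,
  then the smallest false-alarm rate (the grid is ordered midpoint-major,
  so first-occurrence argmax implements this deterministically).

Catch trials are presented at 0 ms regardless of the adaptive suggestion
and their responses enter the likelihood; this is what identifies the
false-alarm dimension of the grid. Experimental blocks place 2 catch
trials uniformly in the first 12 positions and 4 in the next 24. Blocks
are independent: the likelihood state resets at every block, and each
block starts at the task maximum (600 ms delay / 200 ms displacement),
mirroring the training block; whether the original protocol carried the
training estimate over is unknown, and restarting at the maximum is the
conservative choice.

## Task structures

* **Anisochrony**: five 100-ms tones at a 350-ms IOI; displacement `d`
  delays only the fourth tone (third interval +d, fourth −d), so the
  fifth tone is always at 1400 ms and the total duration is conserved.
  `d` must stay below 350 ms; the adaptive grid caps it at 200 ms (57% of
  the IOI). The training description in the source protocol reads like a
  copy-over from the delay task; it is interpreted as a 200-ms
  displacement start level.
* **Synchronisation–continuation**: 4 lead-in snaps (300 ms IOI), 30
  metronome onsets (600 ms IOI), an 18000-ms silent continuation window
  (30 virtual beats) and an end marker. Sequences are symbolic onset
  timelines; no audio is rendered.
* **Session**: 4 practice trials (two at 0, two at the task maximum,
  order seeded-random; feedback is a no-op for simulated responders), a
  10-trial training block without catch trials, then three 36-trial
  experimental blocks — 122 trials in total.

## Quality control

* **Catch-error rule**: discard a block when more than 30% of its catch
  trials drew a "delayed" response (false alarms are the only definable
  catch error). 2/6 errors (33.3%) discards; 1/6 retains.
* **Convergence rule**: OLS slope of the **last 10 per-trial ML midpoint
  estimates** against trial index; discard when |slope| exceeds the task
  cutoff (2 ms/trial delay, 1.18 ms/trial anisochrony). The absolute
  value is used — a strongly decreasing estimate is also non-converged —
  and "exceeds" is strict (a slope exactly at the cutoff is retained,
  with a 1e−9 guard against floating-point noise). The regression runs on
  the running estimates, not the presented levels, because the rule is
  about convergence of the threshold estimate.
* **Aggregation**: mean final estimate over blocks passing both rules
  (the rules commute); participants with no surviving block are excluded.
  Natural log for the transform — any fixed base shifts test inputs only
  monotonically.

## Tapping statistics

Taps are paired to the nearest metronome onset within an exclusive
half-IOI window (a tap exactly midway is dropped); onsets claimed by more
than one tap are dropped entirely. Asynchrony = tap − onset (negative =
anticipation). The circular summary converts asynchronies to phases
`2π(async mod IOI)/IOI`; r is the mean resultant vector length and
z = atanh(r), with r clamped at 1−1e−9 so perfect synchrony stays finite
(flagged). For Gaussian asynchronies with SD σ_ms the wrapped-normal
closed form predicts `z ≈ atanh(exp(−(2πσ_ms/IOI)²/2))` — e.g. 2.26 at
σ = 19.9 ms, IOI 600 ms — which the implementation reproduces and the
tests check.

Continuation tapping: inter-tap intervals (ITIs) summarised by mean and
sample SD; tempo drift is the OLS slope of ITI (ms) on elapsed time
(seconds since the first continuation tap, measured at each interval's
start), giving ms/s; residual CV is the SD of detrended ITIs as a
percentage of the mean ITI. This residual-CV definition is the package's
own (published CV figures for comparable data are ambiguous about the
denominator and aggregation, and are not targeted). Per-block statistics
are computed first and then averaged across a participant's blocks.

## Synthetic cohorts

The generator emulates a three-group study (pianists, brass players,
non-musicians; default n = 18 each):

* **Thresholds** are log-normal. Musician-group moments (delay 102±65 ms)
  fix the log-scale base 4.455 and SD σ = 0.56 (common across groups; the
  per-group moment-matched SDs are 0.584 and 0.537, and a single value
  keeps the mediation structure exact at the cost of ±4% in the marginal
  SDs). Anisochrony moments are taken as 0.59× the delay moments
  (musicians ≈ 60±38 ms, non-musicians ≈ 106±61 ms), the ratio implied by
  the two convergence cutoffs being the same proportion of the average
  final threshold in each task.
* **Mediation**: a latent "timing precision" factor `t ~ N(δ_g, 1)` per
  participant carries *all* group differences in both threshold tasks:
  `log m = base + σ(w·t + √(1−w²)·ε)`. The non-musician latent offset
  δ = 0.594/(wσ) ≈ 1.49 reproduces the 102-vs-180 ms gap. The weight
  **w = 0.71** was calibrated by simulation against the pooled cross-task
  correlations (≈ .60 between the two log thresholds, ≈ −.5 with
  synchronisation accuracy) before any downstream rates were measured,
  and then frozen. `w = 0` removes all cross-task structure.
* **Tapping** parameters are Normal draws from the per-group means and
  between-participant SDs (asynchrony mean/SD, continuation ITI mean/SD,
  drift). Tapping imprecision (sd_async) additionally loads on the
  *centred* latent factor with the same weight, so synchronisation
  accuracy correlates with thresholds within groups while its group-level
  shift follows the published moments directly.
* **Observers** have true false-alarm rates drawn uniformly from
  [0, 0.25] (continuous, not restricted to grid values) and zero lapse
  rate by default. This yields block discard rates broadly comparable to
  the published ones (≈ 10–15% catch-error discards) and occasional
  participant exclusions.
* **Seeding**: all randomness derives from one root seed through named
  substreams (participant index × purpose), so cohorts are exactly
  reproducible.

What the generator does *not* emulate: learning or fatigue across blocks,
hardware latency and its variability, heavy-tailed tapping distributions
(the published non-musician vector-length cell exceeds the Gaussian
closed-form prediction from its own SD; the generator makes no attempt to
reproduce that cell), and demographic covariates. Passing tests therefore
show that the measurement and analysis machinery is correct under its own
stated assumptions, not that those assumptions exhaust real data.

## Group-level inference

Shapiro–Wilk screens normality of raw and log thresholds (the log
restores normality for log-normal cohorts, the rationale for analysing
log thresholds). The one-way between-participants ANOVA reports
generalised eta squared, which in this design reduces to
`SS_effect/(SS_effect+SS_error)`. Post-hocs use Tukey HSD; homogeneity
uses Levene's test with median centring. Pearson correlations report
df = n−2 and adjusted R² = 1−(1−r²)(n−1)/(n−2). The ANCOVA models the
log delay threshold with group, both covariates (log anisochrony
threshold, synchronisation vector length z) and the two group×covariate
interactions, with **Type-II** sums of squares — the conventional choice
when main effects are reported alongside non-significant interactions —
and reports those five term tests with its own degrees of freedom from
the stated model matrix. Standard tests are backed by scipy/statsmodels;
the ANOVA/ANCOVA decompositions are cross-checked in the test suite
against an independently coded brute-force sum-of-squares oracle.

## Problem sizes and determinism

The test suite and the acceptance script run everything at the scale the
analyses are designed for: 200 seeded blocks per parameter-recovery cell,
1,000 random instances for the likelihood-oracle equivalence, 10,000
seeded draws for the catch-schedule invariant, and 100 seeded cohorts
(54 participants each, two adaptive sessions and three tapping blocks per
participant) for the end-to-end power and mediation rates. A full cohort
simulates and analyses in about a second. Under the default conditions
the analytic power of the group ANOVA at n = 18/group is ≈ 0.90, so the
observed detection rate over 100 cohorts fluctuates around that value;
the ANCOVA renders the group effect non-significant in ≈ 85% of cohorts.

## Known limitations

* The candidate model has no lapse parameter; lapses exist only in the
  simulated observer (and default to zero).
* The convergence filter's original definition (running estimates vs
  presented levels; signed vs absolute slope) is not documented in the
  source protocol; both choices here are documented interpretations.
* Threshold truths are clipped one grid step inside the task range so the
  estimator's support covers them; extreme non-musician draws (>599 ms)
  are therefore slightly compressed.
* The ANCOVA's degrees of freedom follow the stated model matrix; no
  attempt is made to reverse-engineer alternative published df.
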