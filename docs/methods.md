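# Methods

This note documents the models, estimators and numerical choices behind
`countermand`, and what the synthetic-session generator does and does not
emulate.

## The task and the race model

The package analyses Go/NoGo-countermanding sessions.  Each trial presents
an instruction cue (go or no-go), then a trigger stimulus; on 25% of trials
a switch signal follows the trigger after a variable delay (the
switch-signal delay, SSD, uniform on 200–450 ms at 1 ms resolution) and
countermands the instructed response.  Four trial types result: *go*,
*no-go*, *switch-stop* (go instruction, switch = stop signal) and
*switch-go* (no-go instruction, switch = go signal).

Behavior is modelled as an independent race (Logan–Cowan): the go process
finishes at the would-be reaction time RT; the stop process finishes at
SSD + SSRT, where the stop-signal reaction time SSRT is the latent duration
of stopping.  A response is emitted iff RT < SSD + SSRT.  Two observable
signatures follow and are asserted by the tests: stop-failure RTs are the
fast tail of the go distribution (median below the go median), and the
probability of failing to stop rises with SSD (the inhibition function).

**SSRT estimation (quantile method).**  Per SSD bin (28 ms wide, tiled from
the smallest observed SSD): let p be the bin's failure probability and
n the number of correct-go RTs.  The quantile RT is the nearest-rank order
statistic at rank ⌈p·n⌉ of the ascending go RTs (no interpolation — this is
the convention that matches "the RT 35% up the ordered list"); the bin SSRT
is that RT minus the bin's representative SSD (midpoint by default, mean
observed SSD optionally).  The session SSRT averages the ≤ 6 bins with the
largest switch-stop counts; count ties prefer bins containing failures,
because a p = 0 bin has no defined quantile and cannot inform the mean
(such bins are retained in the table but flagged).  On the deterministic
stop simulator the estimator recovers the generative SSRT with a small
positive bias (≈ +5–8 ms at 600 trials, shrinking with session length);
the acceptance suite verifies |bias| ≤ 15 ms over 100 sessions.

**Preparation cost** is median(switch-go RT) − median(go RT), with
switch-go RTs measured from the switch signal (the effective go stimulus on
those trials), so the generative cost maps directly onto the index.

## Sliding-window ROC and divergence detection

Neural and EMG divergence analyses share one code path.  At each 1 ms step,
per-trial values (spike counts or mean rectified-EMG envelope) in a 60 ms
half-open window [t−30, t+30) are compared between two conditions by the
area under the ROC curve, computed exactly via midranks:
AUC = P(a > b) + ½·P(a = b) over all cross-condition pairs (the
Mann-Whitney identity; ties count one half).  The value is assigned to the
window center.

**Latency matching.**  Successful switch-stop trials are compared with the
go trials that *would* have been stopped: per shuffle, every correct go
trial receives a pseudo-SSD uniform on 200–450 ms; trials with
RT < SSD + SSRT are excluded for that shuffle; the pseudo-alignment time is
trigger + pseudo-SSD.  All retained trial-shuffle alignments are pooled
with equal weight into the go-condition distribution — this uses every
admissible alignment rather than a single draw.  Latency-matched go is the
positive (A) class everywhere, so a stop-related firing *increase* appears
as an AUC *decrease*.

**Control band.**  Significance is judged against the 500 ms control
period preceding the aligning event: band = control mean ± t₁₋α/₂,df · SD
with α = 0.01 two-tailed.  Two corrections deal with the autocorrelation of
1 ms-stepped values from a 60 ms window: the degrees of freedom come from
the number of non-overlapping windows in the span (df = span/window − 1,
e.g. 7 for 500/60), and Bessel's correction is applied at that effective
count (the naive sample SD over correlated steps is biased low by
√((n_eff−1)/n_eff)).  A zero-variance control period collapses the band
and is flagged degenerate.

**Cancellation time.**  The divergence (neural or muscle cancellation) time
is the first post-event window center whose AUC exits the band and stays on
that side for ≥ 20 ms of consecutive steps; the persistence requirement
suppresses single-step noise crossings, which the window overlap would
otherwise let last up to a window width.  A unit qualifies as involved in
the stop process iff its cancellation time precedes the SSRT (the causality
bound); the excursion direction separates Movement cells (AUC increase —
a pre-movement buildup truncated by stopping) from Switch-stop cells (AUC
decrease — a phasic stop response).  Under the null (identical Poisson
statistics in both conditions) the acceptance suite measures ≤ 2.5% of
independent post-switch windows outside the band and ≤ 2.5% of units
falsely qualifying.

**Bootstrap CI.**  The reliability of a detected time is quantified by
re-running the full chain (fresh pseudo-SSD shuffles → AUC → detection)
n_boot times and taking the 2.5–97.5 percentile interval; if detection
fails in more than half the replicates the CI is undefined and flagged.

## Classification axes

* **Stop vs Switch selectivity** (Switch-stop-pattern units only):
  switch-stop vs switch-go responses, each aligned on its own switch
  signal, in the common window [0, SSRT + 100 ms].  The unit is a *Stop*
  cell iff the maximum post-switch AUC deviation lies below the band *and*
  is part of a sustained below-band excursion (the same persistence rule as
  detection — a single-step dip at the common-response peak is noise);
  otherwise *Switch* (equal or larger switch-go response; attention or
  switching related).
* **Go/NoGo (proactive) set**: instruction-aligned go vs no-go spike
  counts over the instructed delay, test interval 100–1600 ms after the
  instruction (skipping the visual transient, ending before the earliest
  trigger), band from the 500 ms pre-instruction baseline.  The sustained
  requirement here is 100 ms: the construct is tonic delay activity, and
  the longer interval would otherwise accumulate window-scale noise
  excursions.
* **Torque and outcome responses**: event-aligned counts vs a
  circular-shift null (each trial's spikes rotated within the analysis
  span, preserving count and ISI structure), 1000 resamples at full scale.
  Only AUC *increases* count as responses: a decrease against a
  circular-shift null is confounded by pre-event activity that the shuffle
  smears across the span (e.g. the movement burst decaying into the
  error-signal window).  Torque responses must start within 200 ms of the
  impulse; outcome responses within 500 ms of reward/error.  Missing event
  types leave the flag untested rather than false.
* Labels are non-exclusive across axes (a Torque cell may also be a
  Movement cell); `stop_pattern` itself is single-valued.  The population
  summary cross-tabulates stop pattern × go/nogo with a Pearson chi-square
  independence test (no continuity correction) and reports descriptive
  chamber-coordinate summaries per label; no spatial statistic is computed.

## Eye-movement control

Spike counts in 50 ms windows stepped over −500…+1000 ms around the switch
are regressed on eye position and velocity
(f = b₀ + b₁x + b₂y + b₃ẋ + b₄ẏ + ε).  Eye traces are linearly resampled
to 1 kHz; velocity is computed by central differences and smoothed with a
50 ms boxcar.  A step is significant iff its R² exceeds the 99th percentile
of R² values under the ISI-shuffle null (inter-spike intervals permuted
within trial, first spike anchored — rate and ISI multiset preserved
exactly).  Frozen gaze flags the result degenerate.  Under the null ≈ 1% of
independent (50 ms-spaced) steps are flagged; for a position-coupled unit
the horizontal-position coefficient recovers the generative gain (b₁ is in
counts/degree per 50 ms window; multiply by 1000/50 for Hz/deg).  Point
estimates use the median over significant steps — the max-R² step alone is
upward-biased by selection.

## The synthetic-session generator

The generator's defaults are the study conditions: 600 trials/session, 50%
go instructions, 25% switch trials, SSDs uniform 200–450 ms at 1 ms,
deterministic stop finish time SSD + 160 ms, go RTs shifted-lognormal
(shift 250 ms, median 330 ms, σ = 0.25 log units → overall median 580 ms,
stop-failure rates ≈ 5–25% across the SSD range), preparation cost 60 ms.
Trial timing jitters follow the task structure (instruction 0.5 s;
target 0.7–1.3 s after instruction offset; trigger 0.5–1.5 s after target;
torque impulses on a third of trials, 200–500 ms after capture; rewards
0.7–1.3 s after movement or 1.3–1.9 s after successful withholding).

Spiking is an inhomogeneous Poisson process realised by exact thinning of a
piecewise-constant (1 ms) rate function composed from a cell archetype:
linear pre-movement ramps truncated 80 ms after the switch on successful
stops (movement), raised-cosine-edged phasic pulses after the switch
(switch-stop, onset 80 ms, duration 120 ms; switch-nonselective responds on
both switch types), tonic instruction-period offsets (go/nogo), and
short-latency torque (onset 40 ms) and reward-locked (onset 150 ms)
responses.  Baselines are 15–20 spikes/s, amplitudes 1.5–3× baseline by
default.  EMG envelopes are nonnegative 1 kHz traces: agonists ramp before
movement and relax ~60 ms after the switch on stops; antagonists burst
80–180 ms after the switch on stops.  Eye traces are 240 Hz saccadic
position signals; the position-coupled variant adds a unit with rate
baseline + gain·x(t), baseline chosen so the rate never clips.

**What the generator does not emulate** — and hence what passing tests do
not show about recorded data: context-dependent (non-independent) race
processes or SSRT variability (the stop finish time is deterministic by
default), RT sequential effects and session nonstationarity, non-Poisson
spiking (bursting, refractoriness beyond thinning, rate drift), correlated
noise across simultaneously recorded channels, EMG cross-talk and motion
artifacts, and any true anatomical structure (chamber coordinates are
label-conditioned Gaussian clouds used only to exercise the topography
bookkeeping).

## Problem sizes and reproducibility

Paper-scale defaults (1000 pseudo-SSD shuffles, 1000 bootstrap replicates,
1000 circular-shift resamples, 1 ms eye steps) are kept in
`PipelineConfig`.  The test suite and `scripts/acceptance.py` run the same
machinery at reduced resampling scale — 15 shuffles, 10 null resamples,
event-test conditions capped at 80 trials, 50 ms eye steps with 200 ISI
shuffles — which leaves every estimator unbiased and only widens Monte
Carlo noise; validation problem sizes are 100 sessions for SSRT recovery,
200 null units for calibration, 45 units for cancellation-time recovery and
20 units per archetype for label recovery.  All randomness flows from
explicit `numpy` generators seeded per run; the full pipeline is
byte-identical across runs with the same seed.

## Known limitations

* The quantile SSRT has a small positive finite-sample bias (convexity of
  the quantile function at low failure probabilities); it shrinks with
  session length and is well inside the ±15 ms validation band at 600
  trials.
* AUC noise variance is not constant over time when spike counts are small
  (tie density changes with rate), so the control band is only
  approximately calibrated during strong common responses; the persistence
  requirement absorbs most of the residual anticonservatism.
* The bootstrap CI covers latency-matching variability only; it does not
  resample trials.
* With the deterministic stop process, latency-matched go activity is an
  idealisation; graded stop-finish variability would blur the cancellation
  boundary and is available only through configuration extensions.
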