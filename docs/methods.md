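# Methods

This note documents the models, parameter choices and numerical decisions
behind `hybridbci`, and what the synthetic-data experiments do and do not
demonstrate.

## The synthetic participant

Real recordings for this class of system come from small, heterogeneous
patient groups and are not publicly deposited, so the package generates its
own: every signal property the decoders rely on is produced by an explicit,
seeded model with ground-truth annotations.

**EEG.**  Five channels (F3, T3, C3, Cz, P3) at 1 kHz.  C3 carries the
sensorimotor rhythm: a sinusoid at the participant's `smr_center_freq`
(default 11 Hz) whose RMS envelope is `smr_amplitude` (default 5 µV) at rest
and `smr_amplitude × (1 − erd_depth)` during motor-imagery epochs, with
200 ms linear ramps at epoch edges to limit spectral splatter.  Every
channel adds independent Gaussian noise with a 1/f amplitude spectrum above
1 Hz (flat below, so variance stays finite), RMS `noise_level` (default
2 µV), plus a shared common-mode component at half that RMS — the part the
surface Laplacian exists to remove.  This is deliberately a *minimal* model:
no volume conduction, no head geometry, no blink/EMG artifacts, no
non-stationarities beyond the programmed ERD.  Tests passing on it show the
decoding chain is correct and well-calibrated for its operating regime, not
that it would perform identically on patient EEG.

**EOG.**  Two channels at 1 kHz with the same pink-noise background.  An
oculoversion is a smoothed step (sigmoid rise 50 ms, plateau 1 s, sigmoid
return) split antisymmetrically across EOGL/EOGR so the bipolar derivation
peaks at ±`hov_amplitude` (default 200 µV, rightward positive).  The return
to center is itself an opposite-direction gaze movement; after band-pass
filtering it crosses the detection threshold and produces a mirror event
roughly one second after each saccade.  This is physiologic, and the
shared-control machine absorbs it: by the time the return sweep arrives the
machine is in an automatic-motion state where oculoversion inputs are
ignored.

**Behavior.**  Reaction latencies from cue to intent onset are log-normal
(nonnegative, right-skewed) with per-condition (device × mode) mean and SD;
with probability `pre_activation_prob` the intent instead *precedes* the cue
by an exponential lead (capped just under the scheduling margin).  Condition
defaults (means 1.0–2.0 s, SD 0.8 s, anticipation probabilities 0.15–0.35,
leads 0.9–2.0 s) are assumptions chosen to emulate the qualitative pattern
of faster, more anticipatory control with a wearable device than with an
external arm; they are not estimates of any measured population.

**Task sessions.**  Each repetition schedules the five sub-task intents in
order (gaze; right HOV; sustained ERD; right HOV; sustained ERD).  Cues are
placed a 3 s margin after the nominal completion of the previous sub-task so
that every intent — including anticipations — lands while the machine is in
the state that consumes it.  Sustained-ERD epochs last the device open/close
time plus 2 s.  During task execution the ERD depth defaults to
`min(1, 1.5 × erd_depth)`: the calibration threshold is the *average*
elicited ERD, so an epoch at exactly calibration depth would sit on the
threshold and the hand would advance with a ~50% duty cycle.  Deepening the
committed, feedback-supported imagery during actual control is what lets the
motion run nearly uninterrupted — consistent with open/close overshoots of
only a few percent.

## The ERD decoder

* **Spectral estimate:** Burg autoregressive fit of order 100 per 500 ms
  window, hopped every 40 ms (≥ order+1 samples per window at 1 kHz;
  responsive updates).  The one-sided AR spectrum is integrated over the FOI
  by the trapezoidal rule on a 0.1 Hz grid.  The recursion stops early when
  the prediction error collapses numerically (near-noiseless tones).
* **Operating regime:** at the default signal-to-noise ratio the band-power
  estimate is unbiased within a few percent against an FFT periodogram.  At
  very high SNR the AR spectral line becomes narrower than the integration
  grid and band power is under-read with heavy-tailed variance — a known
  property of AR line spectra.  All calibration statistics average over
  hundreds of windows, and ERD% is a power *ratio*, which cancels most of
  the residual bias; tests therefore exercise the decoder at realistic noise
  rather than on mathematically noiseless tones.
* **Center-frequency selection** (the selection rule itself is not part of
  the published interface description and had to be chosen): candidates at
  0.1 Hz steps over the search band are scored by the rest-vs-imagery power
  contrast in a narrow ±0.3 Hz band.  The full ±1.5 Hz FOI contrast cannot
  pinpoint the rhythm — it is maximized off-center whenever the weaker
  imagery line leaks past the band edge.  Selection is declared degenerate
  when the best contrast is shallower than −25%, well below chance minima
  (~−15% across ~50 candidates on short runs) and well above the contrast of
  the weakest study-range rhythm (~−50%).
* **RV and threshold:** RV is the mean FOI power over windows fully inside
  rest intervals; the threshold averages per-trial mean ERD% (not pooled
  windows) over imagery epochs.  Calibrations with mean elicited ERD above
  −5% are flagged non-informative.
* **Online detection:** causal band-pass + Laplacian, activation opens after
  ERD% holds at/below threshold for a 200 ms dwell (5 windows), onset
  reported at the first qualifying window center.  For ground-truth scoring,
  the expected onset lag is (T/P − ½) × window, where T is the threshold and
  P the epoch's plateau ERD; at default parameters this is ≈ 0.15 s.

## The HOV decoder

Threshold = 70% of the mean absolute peak of the zero-phase band-passed
bipolar signal within 2 s of each paced movement.  The band-pass (0.1–5 Hz)
attenuates a 1 s plateau to ~85% of the raw step, but calibration and
detection measure the same filtered quantity, so the 70% operating point is
preserved exactly.  Detection fires at the first threshold crossing of the
causal stream (≈ 0.1 s after intent onset: filter delay plus rise time),
direction from sign, one event per 1 s refractory period.  The refractory
default and the instantaneous-amplitude criterion are design choices; no
area/duration criterion is applied.

## The shared-control machine

Pure, tick-driven (10 ms), no hidden randomness: replays on identical inputs
are bit-identical.  Automatic reach/transport/return segments default to 5 s
placeholders (robot motion times are device-specific and not modeled).
Completion timestamps fall on the *end* of the completing tick, so a grasp
driven by continuously active ERD measures exactly the mechanism time
(1.5 s / 1.2 s) rather than one tick short.  The veto (left HOV) is accepted
from object selection until a reach is triggered; left HOV anywhere else is
ignored.  Each repetition gets a fresh machine, so a stalled trial is marked
incomplete without cascading.

## Metrics and statistics

Exactly one of TTI / Pre-TTI exists per successful initialization; the
activation window for a sub-task opens at the previous sub-task's completion
(earlier activations carry no intent for it).  In asynchronous mode no
visual cue exists; the scheduled reference annotation — the simulated
equivalent of the moment the sub-task became available — serves as the
timing reference, so both modes are measured against comparable anchors.
Quantiles use linear interpolation between order statistics; fluency is tied
to the median and reliability to the 75th percentile.

The group pipeline reduces each participant to a per-condition median (a
paired-test unit the pooled per-trial data cannot provide), screens with
Shapiro–Wilk, tests the omnibus hypothesis with a Friedman statistic
computed from average ranks with tie correction (allowing the two-condition
case; it matches the standard library implementation for three or more), and
follows up with two-sided pairwise Wilcoxon signed-rank tests using Pratt's
zero treatment — zeros ranked, then dropped from the signed sums — with an
exact enumeration null for up to 12 nonzero differences and a zero- and
tie-corrected normal approximation beyond.  Holm–Bonferroni corrects each
metric's pairwise family; missing sessions are deleted listwise for the
omnibus test and pairwise for the post-hocs.  Under a simulated exchangeable
null the gated pipeline's family-wise error stays at the nominal level
(checked at ≤ 7% for α = 0.05 over 1000 replicates).

## Problem sizes and reproducibility

The full study design (10 participants × 2 devices × 2 modes × 2 tasks ×
10 repetitions, 42-trial calibrations) is the configuration default.  The
test suite and example analyses run scaled-down versions — 10–12 calibration
trials of 3 s with 2.5 s intervals, 2–10 repetitions, 1–3 participants,
shortened automatic-motion segments — sizes chosen to keep every statistical
check well-powered while the whole suite completes in about a minute.  All
randomness flows from explicit seeds (a study's master seed spawns
per-participant and per-session seeds), and `run_study` writes its outputs
byte-reproducibly, with a manifest listing every file and its hash.

## Known limitations

* The generator's stationary rhythm-plus-noise model contains none of the
  artifacts, drifts or spatial structure of real EEG/EOG; decoder operating
  points measured here are upper bounds on real-world performance.
* Signal files are written as headered CSV (with an events sidecar); EDF is
  supported for import only, via the optional `mne` dependency.
* The vision system, robot kinematics and device mechatronics are outside
  the pipeline; devices are represented solely by their timing constants.
* One detection threshold serves both hand-opening and hand-closing imagery,
  and thresholds stay frozen for a whole session (no adaptation).
* The search band for the rhythm is a parameter (default 8–13 Hz) rather
  than a fixed physiological claim.
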