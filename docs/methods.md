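# Methods

## Stimulus model

All geometry lives on a one-dimensional signed axis in degrees of visual
angle, cross at the origin, positive toward the circle's starting side; the
2-D screen view (millimetres at a 1.2 m viewing distance) is derived by the
exact tangent conversion `mm = 1000·d·tan(θ)` and is never used internally.
Degrees are canonical because published mm↔degree figures for this class of
setup are frequently rounded inconsistently; the angular specification is
the one that determines retinal events.

A trial is five events on the trial clock: appearance (t = 0), motion onset
(after `pre_motion_duration`, default 1 s), change onset (after
`pre_change_duration` at `pre_change_speed`, defaults 1 s at 4 °/s),
occlusion (`occlusion_delay` after the change), and TTC.  Position is
continuous and piecewise linear; it is exactly zero at TTC and remains
defined after occlusion (the notional motion continues).  TTC is defined as
centre-on-centre alignment of circle and cross: "complete overlap" of a
4°-wide circle on a 4°-wide cross is centre alignment.

The 18-condition table (speeds 3/4/5 °/s × occlusion delays
0.3/0.5/0.7/0.9/1.0/1.5 s) follows analytically: eccentricity at occlusion
`E_c − v·t_occ` (reported to 1 decimal), remaining time `(E_c − v·t_occ)/v`
(2 decimals), peripheral monitoring time `max(0, t_occ − 0.3)` assuming a
300 ms saccade latency.  A conservation identity —
`time_to_ttc·v + v·t_occ = E_c` — holds for every geometrically valid
design and is property-tested.

**Quasi-randomization.** The long-occlusion layout has 40 trials per
speed × occlusion cell (240 total); the short-occlusion layout has 30 per
perturbation cell plus 10 per occlusion for the catch speed (280 total).
The order constraint is that the same speed never occurs more than three
times consecutively.  A uniformly shuffled 240/280-trial sequence violates
this constraint with probability close to one (the expected number of
runs > 3 is far above 1), so rejection sampling of whole shuffles does not
terminate; the generator instead builds the sequence greedily — each next
trial drawn among the speeds that do not extend a run beyond three,
weighted by remaining counts — and restarts on the rare dead end.  The
result is still a permutation of the declared cell multiset, deterministic
per seed.

## Synthetic observer

The simulator emulates what a ~200 Hz video eye tracker would record from a
compliant observer, with every latent event labelled so the downstream
pipeline can be validated by parameter recovery.  It is *not* a
physiological model; it contains exactly the structure the detection and
scoring stages are sensitive to.

* **Pursuit**: the eye covers `pursuit_gain` (default 0.95) of the target's
  displacement from pursuit onset (`pursuit_onset_latency`, 0.15 s after
  motion onset), i.e. a slowly growing positional lag, ~1.3° worst case —
  inside the 3° validity rule, as for a compliant human.
* **Saccades**: raised-cosine velocity profile; peak speed is
  `main_sequence_slope · amplitude` (default 30 /s per degree, the linear
  main-sequence regime for these 8–10° saccades), which fixes the duration
  at `2/slope` ≈ 67 ms.  The profile integrates in closed form, so the
  commanded amplitude is exact.  Landing scatter `landing_noise_sd`
  (0.4°) stays well inside the 3° cross window.
* **Detection**: a perturbation is missed with `saccade_miss_rate` (0.05);
  a catch trial draws a false alarm with `false_alarm_rate` (0.02);
  detection latency is Gaussian (`detection_latency_mean` 0.3 s,
  `detection_latency_sd` 0.05 s, floored at 50 ms).  In the saccade task the
  response is a saccade to the cross at the detection time; in the pursuit
  task it is a `perturbation_response` button press, pursuit continuing
  through occlusion (the extrapolated target).
* **TTC press**: at `change_onset + E_c/(v·ttc_bias_gain) + N(0,
  ttc_response_sd)`.  Gain 1 is unbiased; gain > 1 (perceived speed too
  fast) presses early, gain < 1 late.  This reproduces direction-of-error
  orderings without claiming human effect sizes.
* **Noise**: gaze noise is low-pass-filtered white noise
  (`noise_bandwidth_hz`, default 3 Hz), amplitude 0.2° during fixation and
  0.1° during pursuit — within a video tracker's ~0.5° accuracy.  The
  bandwidth matters: unfiltered white noise of the same amplitude at 200 Hz
  would imply velocity excursions of tens of °/s, which no eye produces;
  3 Hz gives drift-like fixational velocities of a few °/s.  The noise
  process is generated with padding so its own filter transient never
  reaches the recording, and amplitude transitions between fixation and
  pursuit are ramped over 100 ms (a step in noise amplitude would inject a
  spurious velocity transient exactly at pursuit onset).
* **Invalid trials**: with `invalid_trial_rate` the trial acquires a slow
  linear drift (≈ 4.5° by occlusion, always below the saccade threshold)
  breaking the 3° rule during pursuit.  Blinks are not modelled — the
  validity rule, not blink reconstruction, is the stage under test.

Sampling is uniform at `sample_rate` (default 200 Hz, the 5 ms gaze-vector
update typical of such rigs; the camera frame rate of 220 Hz is selectable
— downstream windows are specified in time, not samples).  Rates too low to
put two samples inside a saccade are rejected.  Every (participant, trial)
draws an independent child seed; identical seeds give bit-identical
cohorts.

## Event detection

Velocity is estimated by central differences, then each component is
filtered with a second-order Butterworth low-pass at 60 Hz applied forward
and backward (`filtfilt`): unit DC gain and zero phase, so event times are
not biased in either direction.  Saccades are maximal runs of 2-D speed
above a fixed 22 °/s threshold; runs separated by less than `merge_gap`
(20 ms) are merged first, then runs shorter than `min_duration` (10 ms)
are discarded — merging first keeps noise-split saccades whose fragments
jointly exceed the minimum.  Onset/offset are the first/last
supra-threshold samples; the adaptive onset/offset refinements of
data-driven algorithms are deliberately not used, keeping the detector the
plain fixed-threshold variant.  `min_duration` and `merge_gap` are
pragmatic anti-noise additions, both configurable.  Samples within 25 ms of
either end of a recording are flagged invalid (zero-phase filter start-up
transients and one-sided differentiation make them unreliable) and cannot
initiate detections.  Pursuit statistics exclude 16 ms before each onset
and 70 ms after each offset.

A fixed-threshold detector necessarily fires a few milliseconds after the
true kinematic onset — the profile needs ~5–8 ms to reach 22 °/s — so
pipeline-measured response times carry that small positive offset; the
median onset error on default-noise trials is ~7 ms.

## Scoring

Validity: gaze must stay within 3° of the circle during the visible pursuit
phase (motion onset to the first qualifying saccade or to occlusion,
peri-saccadic samples excluded) and, in the saccade task, within 3° of the
cross from saccade landing to the TTC press; comparisons are strict (an
excursion of exactly 3.0° is still valid).  In the pursuit task validity is
enforced through occlusion, not through TTC — after occlusion there is no
visible target to track.

A *qualifying* saccade is one whose endpoint lands within 3° of the cross —
the paradigm's only stated spatial threshold, reused rather than inventing
a second one.  Correctness is the truth table: perturbation ∧ qualifying
response ↔ correct; catch ∧ no response ↔ correct.  Anticipatory responses
(before change onset) make the trial incorrect: a response-time measure
defined relative to change onset presupposes post-change initiation.
Response time is the first qualifying saccade onset (or button press) minus
change onset, defined only on correct perturbation trials.  TTC error is
`press − TTC` (signed); relative TTC is `100·(press − change_onset)/(TTC −
change_onset)`, an affine function of press time anchored at 0 % (change
onset) and 100 % (contact).  Catch trials are scored for TTC exactly like
perturbation trials — pursuit plus press defines the prediction there too.

Aggregation produces participant × speed × occlusion cells (n valid, n
correct, percent correct, mean *and* median RT and TTC error — medians for
plotting conventions, means for testing) and excludes any participant with
fewer than `min_valid_trials` (10) valid trials in any cell of the full
factorial grid.

## Statistics

The repeated-measures ANOVA uses the classical univariate decomposition on
per-participant cell means (replicates are averaged first, the standard
aggregation), each effect tested against its own subject-interaction error
stratum.  Greenhouse–Geisser ε is computed per effect from `M = C'SC` (S
the between-subject covariance of the cell scores, C an orthonormal
contrast basis of the effect space): `ε = tr(M)²/(d·tr(M²))`, bounded in
[1/d, 1] and exactly 1 for two-level factors.  Corrected p values use the F
distribution with both dfs scaled by ε.  The correction policy is
configurable — `always` (default, conservative), `never`, or
`when_violated` (Mauchly's test at 0.05); "always" is the default because
conditional correction inherits the pretest's error rates.  Effect sizes
are partial η² = SS_effect/(SS_effect + SS_error).  When SS_effect is
exactly zero, F is reported as 0 with p = 1 (the 0/0 ratio has no
information).

Pairwise contrasts are paired t tests on subject × level means with Holm
step-down adjustment by default; Bonferroni is also provided since both
conventions circulate for this design, and the choice is a reported option
rather than a hidden default.  The exploratory regression fits OLS of
relative TTC timing on response time per condition, refusing degenerate
predictors.

Implementation is validated three ways in the test suite: the F = t²
paired-t equivalence on two-level factors (to 1e-10), a brute-force
projection-matrix GLM decomposition built from explicit dummy design
matrices, and pingouin's `rm_anova` as an independent package cross-check.
Type-I-error calibration uses sphericity-compliant i.i.d. Gaussian null
data and the *uncorrected* test (the GG-corrected test is conservative by
design, so its size is not expected to centre on α).

## Problem sizes and determinism

Recovery checks run at sizes chosen to give tight binomial/normal error
bars while keeping the whole suite quick on a laptop: 200 trials for
detection recovery, a 12-participant × 240-trial cohort for parameter
recovery (participant latency means drawn from N(300, 50) ms, so the 2-SEM
band on the recovered mean reflects genuine between-subject spread), and
1000 replicates of a 6-subject 3 × 2 table for the null-calibration check.
Every stochastic path is driven by a single seed through spawned child
generators; reruns are bit-identical.

## What passing tests do and do not show

The generator's defaults describe a compliant, mildly noisy observer; the
pipeline demonstrably recovers that observer's parameters (latencies,
rates, biases) from raw traces.  That validates the *analysis chain*, not
human behaviour: real data add blinks, catch-up saccades during pursuit,
asymmetric latency distributions, head-motion artefacts and
calibration drift, none of which are modelled.  Published human effect
sizes (speed-condition differences, the pursuit-over-saccade advantage)
are therefore out of scope as numeric targets; the simulator supports
ordering-level exploration only (e.g. via `ttc_bias_gain`).
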