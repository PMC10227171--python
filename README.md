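# ocupred

Simulation and analysis of **pursuit / predictive-saccade time-to-contact
experiments** — the cricket-inspired class of prediction-motion paradigms used
to study whether saccading ahead of a moving target and monitoring it
peripherally helps, or hurts, the prediction of when it will arrive.

## The paradigm

A circle appears at eccentricity E₀ = 14° from a fixation cross, starts
moving toward it at 4 °/s, and one second later either slows to 3 °/s,
speeds up to 5 °/s, or continues unchanged (the catch condition).  At the
change onset the circle is E_c = 10° from the cross; some delay t_occ after
the perturbation it is occluded but notionally keeps moving, reaching the
cross at the **time to contact**

    TTC = change_onset + E_c / v,

so the eccentricity at occlusion is `E_c − v·t_occ` and the remaining time
is `(E_c − v·t_occ) / v`.  Observers either saccade to the cross on
detecting the perturbation and monitor the circle peripherally (saccade
task) or keep pursuing it and press a button (pursuit task); in both cases
they press a button at the predicted contact time.

`ocupred` provides, as tested library code:

* **stimulus** — analytic trial kinematics, the 18-condition
  speed × occlusion table, and quasi-randomized factorial designs
  (240-trial and 280-trial layouts, never more than three consecutive
  trials of the same speed);
* **synthetic_gaze** — a seeded observer/apparatus simulator (200 Hz,
  pursuit gain ≈ 0.95, detection latency ≈ 300 ms, main-sequence saccades
  with a raised-cosine velocity profile, drift-based invalid trials) with
  ground-truth labels for every event;
* **gaze_events** — the standard oculomotor signal chain: central-difference
  differentiation, zero-phase 60 Hz low-pass, fixed 22 °/s velocity-threshold
  saccade detection, 16/70 ms peri-saccadic exclusion, gaze–target distances;
* **trial_scoring** — 3° gaze-distance validity, perturbation/response
  correctness, saccadic and button response times, signed and relative TTC
  prediction error, participant exclusion below 10 valid trials per cell;
* **stats** — `RepeatedMeasuresANOVA(...).fit()` with Greenhouse–Geisser
  correction (ε from the contrast covariance), Mauchly's test, partial η²,
  Holm/Bonferroni pairwise contrasts, and the RT ↔ TTC regression;
* **cli** — a CSV-based command line (`ocupred design|simulate|detect|
  score|analyze|stimulus-table|run-all`).

## Worked example

```python
import ocupred as o

design = o.generate_design(2, seed=7)                  # 280-trial short-occlusion layout
params = [o.OculomotorParams() for _ in range(12)]     # 12 default observers
cohort = o.simulate_cohort(design, params, seed=7)     # 12 x 280 gaze recordings
scores = o.score_cohort(cohort)                        # detection + scoring per trial
table  = o.aggregate(scores)                           # participant x cell summary
res = o.RepeatedMeasuresANOVA.from_score_table(table, "mean_relative_ttc").fit()
print(res.summary())
```

prints (elided):

```
Repeated-measures ANOVA: mean_relative_ttc ~ speed * occlusion_delay  (n = 12 subjects, GG policy = always)

                       ss_effect  ss_error  df_num  df_den      F  p_unc  eps_gg  ...   p_gg  partial_eta_sq
speed                     2.0010   45.9504       2      22 0.4790 0.6257  0.8883  ... 0.6044          0.0417
occlusion_delay           1.1386   62.7704       3      33 0.1995 0.8960  0.7040  ... 0.8317          0.0178
speed:occlusion_delay     4.0021  186.3701       6      66 0.2362 0.9631  0.5621  ... 0.8903          0.0210
```

The simulated observers press, on average, at 100.1 % of the change-onset →
TTC interval (unbiased, `ttc_bias_gain = 1`), so no speed or occlusion
effect is expected — and none is found: all F < 1.  Per-cell summaries in
`table.table` show ~96 % correct and mean saccadic RTs around 0.30 s, the
generator's detection-latency mean.  Setting `ttc_bias_gain` above 1 makes
perceived post-change speed too fast and presses too early; below 1, too
late — which is how ordering predictions (not human effect sizes) can be
explored.

The same chain from a shell:

```bash
ocupred run-all --experiment 2 --participants 12 --seed 7 --outdir out/
ocupred stimulus-table        # the 18-condition analytic table
```

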