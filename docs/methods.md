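# Methods

`rtmsim` is a software twin of a remind-to-move (RTM) sensory-cueing
wristwatch for post-stroke upper-limb rehabilitation, embedded in a
synthetic two-arm dosing-trial simulator with the matching nonparametric
outcome pipeline. No real patient data enter the package anywhere; every
input is either a device parameter, a documented behavioral assumption, or
synthetic.

## Device model (firmware twin)

Both device variants tick on the accelerometer's 2-s recording epoch; all
durations are rounded to whole epochs because the device cannot observe
anything finer.

**Open loop.** A vibration cue (196 Hz motor, 2-s on / 2-s off pattern)
fires every `open_interval` = 10 min on a fixed grid anchored at session
start: the first cue fires at t = 10 min and acknowledgment does not
re-anchor the schedule. If the grid expires while a previous cue is still
vibrating, the scheduled cue is absorbed into the ongoing vibration rather
than logged as a second overlapping event. An alternative dialect
(`open_loop_anchor="ack"`), in which the interval restarts at
acknowledgment, is available behind a config switch; it is not the default
because a fixed schedule is the plain reading of a cue "set to occur at
10-min intervals".

**Closed loop.** An inactivity countdown (`countdown` = 2 min for
lower-functioning wearers, FTHUE 3–4; 5 min for FTHUE ≥ 5) arms at session
start — the session opening counts as the start of a no-movement interval —
and reloads whenever the device detects movement of the hemiparetic arm in
an epoch. At zero the cue fires. While a cue awaits acknowledgment the
countdown is suspended and restarts from the full preset at the button
press; this avoids back-to-back cues when the wearer is slow to respond.
Movement never auto-acknowledges a cue: the button is the only stop
condition. Presets are held constant per subject for the whole trial.

Acknowledgments are processed on the tick grid (a press scheduled inside an
epoch takes effect at that epoch's boundary; a zero-delay press within the
firing tick), while the logged `ack_s` is the scheduled press time itself,
so logged reaction times are not quantized. A cue never acknowledged by
session end is logged with an absent `ack_s` and excluded from the mean
reaction time. The vibration on/off phases are configuration metadata with
no feedback effect beyond the awaiting-acknowledgment state.

## Sensing model

Acceleration is sampled at 5 Hz per axis and aggregated over 2-s epochs
(10 samples). The *activity count* of an epoch and axis is the number of
its 9 within-epoch consecutive-sample differences whose absolute value
exceeds a per-axis threshold; an epoch is "moved" when any axis counts.
The physical units and threshold of the real counter are not published;
the default of 1 device unit is an explicit placeholder, carried in every
log header, and results that depend on absolute counts should be read as
device-unit quantities. The daily movement frequency is the sum of counts
across X, Y and Z over the 3-hr wearing window (a vector-magnitude counting
variant is available behind `axis_mode="magnitude"`). Trial-level outcomes
are the 14-day mean of daily counts and the gain score
mean(days 12–14) − mean(days 1–3). Days with fewer than 90% of expected
epochs are flagged incomplete and never silently rescaled.

## Behavior generator

The synthetic participant is calibrated to three stated population-level
quantities: the affected arm rests for ≈ 50% of waking time; affected/
unaffected activity-count ratios are ≈ 1/3 (lower functioning) and ≈ 2/3
(higher functioning); each cue prompts, with probability `p_respond`, five
sets of tasks repeated five times (25 movement bouts).

*Micro-structure.* Spontaneous movement is a two-state (rest/active) Markov
chain on the 2-s epoch grid — the discretization of an alternating-renewal
bout process with exponential sojourns. The exit rate is set by the mean
bout duration (`bout_mean_s`, default 60 s: activity periods on the
time-scale of a task, long enough that multi-minute rests occur and the
closed-loop countdown actually fires at a realistic rate); the enter rate
is solved so the stationary rest probability equals `rest_fraction`
exactly. While active, each of an epoch's 27 sample differences (9 per
axis) crosses threshold independently with an intensity probability;
the affected arm's intensity is `affected_ratio` × the unaffected arm's,
which makes the expected count ratio equal the profile ratio exactly (the
binomial mean is linear in its probability). The unaffected-arm reference
shares the rest/active structure at full intensity with no device, decay or
habit dynamics. A "moved" intent epoch whose draws all land sub-threshold
(probability (1−p)^27, ≈ 0.2% at the lower-functioning default) is logged
unmoved — the device flag follows the counts, as in hardware. Walking/gait
epochs are never generated; the outcome definition excludes walking
activity by construction.

*Dynamics.* The spontaneous bout rate is multiplied by a motivation decay
2^(−(day−1)/halflife) (default half-life 7 days: interest fades over the
first week) and, under closed-loop exposure only, by a habit factor
(1 + habit_gain)^(day−1) (default 0.03/day) representing avoidance
conditioning — moving more prevents the aversive cue, and the practiced
response consolidates. Both are overridable profile parameters, not claims
about measured human rates; a shared-habit variant for sensitivity analysis
is a one-line profile change (set the same `habit_gain` and compare arms
with identical engines). Acknowledge-button latencies are lognormal
(median 2 s, σ = 0.5; median 0 means instant). Cue responses co-simulate
with the engine: a response queues 25 repetitions of
2 epochs movement + 1 epoch pause (≈ 2.5 min of exercise), during which the
spontaneous process is suspended; a cue arriving mid-block is acknowledged
but does not queue a second block.

*Raw traces.* When requested, the generator renders its crossing mask into
an exact 5 Hz stream: each crossing is a ±(2 × threshold) step with
alternating sign, non-crossings are flat, so epoch-izing the stream
reproduces the generated counts bit-exactly. Sample synthesis consumes no
randomness; runs are identical with or without it.

*What the generator does not emulate.* Circadian structure, day-to-day
autocorrelation beyond the deterministic decay/habit trends, heavy-tailed
rest periods, posture and gravity artifacts, tremor, compliance failure
other than `p_respond`, and any item-level content of the clinical
instruments. Passing calibration tests therefore shows the pipeline is
faithful to the stated behavioral targets, not that it predicts real
wearers.

## Trial simulator

Sixteen subjects (8 per arm by default), half per functioning stratum, are
allocated by seeded permuted-block (block size 2) randomization within
strata, so arms differ by at most one subject per stratum. Each subject
wears their arm's engine 3 hr/day for 14 days in co-simulation. Clinical
scores (abstract stand-ins for FMA-UE total/upper/hand, ARAT, MAL-AOU,
MAL-QOM) come from a synthetic linear latent-mediator model: score gain =
baseline-SD × `effect_per_1k` × (kinematic gain / 1000 counts) + Gaussian
noise, evaluated at posttest, and at 4-week follow-up scaled by a per-arm
retention parameter (default 1.0 closed-loop, 0.5 open-loop, reflecting
habit persistence vs schedule dependence; both overridable). Follow-up
kinematics are not simulated — the device is only worn during the
intervention. Scores are left unclipped abstract scales. A master seed
fixes the pool, allocation, all 224 co-simulated days and all score noise;
the outcome table reproduces byte-identically.

## Statistics

All tests use mid-ranks on ties and two-sided p-values; α = 0.05 with no
multiplicity correction by default (matching per-test reporting; a Holm
adjustment is available and flagged as the conservative option).

* **Friedman** across the three timepoints per group and measure, with the
  tie-corrected statistic Q = (k−1) Σ_j (R_j − n(k+1)/2)² /
  Σ_ij (r_ij − (k+1)/2)² and χ²_{k−1} p. Constant rows are mid-ranked, not
  dropped; an all-constant matrix is reported degenerate with p = 1. An
  exact-enumeration oracle (`friedman_exact_p`, all (k!)^n row
  permutations) backs the tests; at n = 5, k = 3 the worst-case gap between
  the χ² and exact survival functions, computed by full enumeration, is
  ≈ 0.143, and that computed bound is the tolerance the suite asserts.
* **Wilcoxon signed-rank** for first-3 vs last-3-day mean movement
  frequency per group: zeros dropped, exact sign-pattern p when there are
  no ties and n ≤ 25, otherwise the normal approximation with tie-corrected
  variance; a single usable pair (or none) is flagged degenerate.
* **Quade rank ANCOVA** for between-group gain-score differences with age,
  onset-to-treatment (months) and FTHUE level (as its integer value) as
  covariates: response and covariates ranked over all N subjects ignoring
  group, response ranks regressed on covariate ranks by least squares with
  intercept, one-way ANOVA F on the residuals, df = (g−1, N−g). With zero
  covariates this reduces exactly to a one-way ANOVA on response ranks
  (asserted in the suite). Zero-variance and rank-collinear covariates are
  dropped with warnings. If the covariates explain the response ranks
  exactly, total residual variation is floating-point noise
  (≤ 1e-8 × N on the rank scale) and the test reports F = 0, p = 1,
  degenerate, rather than a 0/0 noise ratio.

Validation is dual-route throughout: the implementations are checked
against scipy's Friedman/Wilcoxon on the overlapping cases, against exact
enumeration for small n, and against a 10,000-draw group-label permutation
oracle for the Quade F at N = 16. A 1,000-replicate null simulation at
N = 16 confirms the Quade type-I error sits within Monte-Carlo error of
0.05.

## Problem sizes and determinism

Default simulations run one 3-hr session per day (5,400 epochs, 54,000
samples/axis). Calibration quantities are estimated over 100 independent
simulated days; the closed-vs-open mechanism comparison uses 200 seeded
replicate pairs of full 14-day exposures; trial-level null checks in the
suite use shortened sessions (0.25–0.5 hr) with the same code paths. Every
random draw descends from an explicit seed; nothing reads the wall clock.

## Known limitations

The movement threshold, bout process, motivation and habit parameters are
assumptions, not estimates; clinical scores are abstract; the trial's real
individual-level results are not reproduced (participant data are not
public). The χ² Friedman p is coarse below n ≈ 8. Cue-triggered exercise
always follows the fixed 25-repetition template; task difficulty is never
modulated mid-trial.
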