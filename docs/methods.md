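# Methods

## The task and its closed loop

Participants (or simulated agents) draw circles they cannot see; the only
feedback is a binary reward after each trial, based on the circle's size.
One session runs 80 main-phase trials.  The loop per trial is:

1. a pen trajectory is recorded (time, x, y in cm, 60 Hz);
2. geometry reduces it to a radius (and aspect ratio, center, path length);
3. the engine computes the relative radius error
   `e = max(r/T, T/r) − 1` against the current target radius `T` —
   zero at the target, identical for a halved and a doubled radius;
4. reward is granted iff `e` is strictly smaller than the adaptive
   threshold (below);
5. the learner updates its intended radius using only that binary outcome.

The first five trials are scored against a fixed 4.3 cm target; from
trial 6 on the target is twice the mean drawn radius of those five
trials, so every participant must roughly double their spontaneous
circle size.  Drawn radii, not intended ones, set the target.

## Adaptive reward criterion

The threshold is the fifth-largest of the past ten relative errors — an
order statistic close to the running median, so for a stationary error
stream the reward probability is `P(new < 6th smallest of 10 i.i.d.) =
6/11 ≈ 0.545`, holding success near one half independent of skill.
Bootstrap choices the original description leaves open, fixed here:

* **Window filling (trials with n < 10 past errors):** threshold is the
  `ceil(n/2)`-th largest of the available errors, which keeps the
  implied reward probability near one half from trial 2 on.
* **Cold start (trial 1):** reward iff `e < 1`, i.e. the drawn radius is
  within a factor two of the target.  Arbitrary but fixed; it affects
  one trial.
* **Target switch (trial 6):** the criterion-window entries for trials
  1–5 are recomputed against the new target so the staircase compares
  like with like.  The recorded trials keep the target and error the
  participant actually experienced.  The alternative (keep the old
  window errors) is selectable via
  `recompute_errors_on_target_switch=False`; in simulation it changes
  the cohort median success frequency by about 0.02.
* **Ties:** an error exactly equal to the threshold is not rewarded
  ("smaller than" is strict).

A structural property worth knowing: 6/11 > 1/2 is the *floor* for a
stationary performer, and any sustained improvement trend raises the
realized rate further because each new error is compared against a
lagging window.  Empirically, human cohorts sit slightly *below* 1/2,
which indicates nonstationary, wandering error levels rather than
stationary or monotonically improving ones; see "Known limitations".

## Trajectory geometry

* **Center**: mean of the per-axis min and max positions.
* **Resampling**: the path is resampled to 50 points at arc lengths
  `s_i = i·L/50`, `i = 0..49` (half-open, so a closed curve's coincident
  start/end point is not double-weighted), by linear interpolation along
  the sampled polyline.  This removes any influence of the speed
  profile.
* **Radius**: mean Euclidean distance of the 50 resampled points to the
  center.
* **Aspect ratio**: over orientations θ in [0°, 90°) in 1° steps, the
  ratio of the projected extents along θ and θ+90° whose |log| is
  largest.  Computed on the resampled points so drawing speed cannot
  bias it; 1° resolution bounds the discretization error of the folded
  ratio at about 2·tan(0.5°) ≈ 2 %.
* **Circularity gate**: non-circular iff aspect ratio outside [0.1, 10]
  or path length < 2 × start-to-end distance.  Degenerate trajectories
  (no spatial extent) raise `DegenerateTrajectoryError`; session-level
  callers should record such trials as non-circular rather than abort.

## Synthetic participants

The generator is a minimal reward-based learner operating in log-radius
space (size errors in this task are multiplicative):

```
x_{t+1} = (1 − ρ)·x_t + ρ·x_rew + ε_t,   ε_t ~ N(0, σ_fail or σ_succ)
```

where `x` is the intended log radius, `x_rew` the intended log radius of
the most recent rewarded trial, `ρ` the retention, and the innovation SD
depends on the previous trial's reward.  The executed radius adds motor
noise: `r = exp(x + N(0, σ_motor))`.  Reference parameters:
`ρ = 0.9, σ_fail = 0.15, σ_succ = 0.05, σ_motor = 0.05`, baseline radius
2.5 cm.  Named sets `default_child` (baseline 2.8 cm, σ_motor 0.08,
σ_fail 0.20, σ_succ 0.08, ρ 0.85) and `default_adult` (baseline 2.3 cm,
reference SDs) encode the empirical pattern that children draw larger
and are more variable than adults.

Rendering (`execute_trial`) turns each intended radius into a pen path
with the nuisance features real drawings have: log-normal axis-ratio
jitter (SD 0.05), center scatter (SD 0.5 cm) around a tablet-centered
mean, random orientation and start phase, a 4° closure gap, and a
sinusoidal angular-speed modulation (depth 0.3) over 120 samples at
60 Hz (≈ 2 s per circle, the typical drawing time).  These values are
the package's own realism choices; analysis results are insensitive to
them by construction (the geometry stage is speed- and
rotation-invariant), which the tests verify.  `render=False` skips
rendering and scores the executed radius directly — statistically
equivalent for radius-based metrics and used for large Monte-Carlo runs.

Reproducibility: one master seed spawns per-agent independent substreams
via `numpy.random.SeedSequence(master_seed).spawn(n_agents)`.

What the generator does *not* emulate: systematic pull back toward a
preferred circle size, drifting attention or fatigue, within-trial
dynamics (tremor, corners), pen pressure, or any age continuum.
Passing simulation-based tests therefore shows the pipeline's
correctness and the direction of its effects, not that the agent
reproduces human learning curves quantitatively.

## Outcome measures

* **Baseline radius**: mean drawn radius of main-phase trials 1–5 (the
  same trials that set the target; no separate baseline block exists).
* **Fraction learned**: mean radius of the last ten trials / baseline
  − 1; equals 0 at baseline performance and 1 at the target.
* **Trial-to-trial ratio**: `max(r_{t+1}/r_{t−1}, r_{t−1}/r_{t+1})`
  (≥ 1, halving ≡ doubling), conditioned on the reward at trial t;
  spanning t−1 to t+1 avoids the truncation bias that conditioning on a
  rewarded trial t would put on `r_t` itself.  Boundary trials (t = 1,
  t = N) have no ratio.  Variability is the per-participant median of
  each condition; an empty condition yields NaN.
* **Task-irrelevant changes**: same pairing for the aspect ratio (folded
  ratio) and the circle center (Euclidean displacement, cm) — movement
  dimensions that never affect reward.
* **Exclusion**: a participant is excluded iff strictly more than 20 %
  of trials are non-circular.  For included participants every trial
  contributes to the metrics, non-circular ones included.  Success
  frequency counts rewarded trials over all 80 main-phase trials,
  including the five scored against the initial target.

## Statistics

Rank tests are normal approximations with average ranks for ties, the
matching tie-corrected variances, exact-zero differences dropped before
signed-ranking, and a 0.5 continuity correction — the appropriate regime
for group sizes of roughly 30–70, reported as z plus a one- or two-sided
p.  The test suite checks the statistics against exhaustive enumeration
(all sign assignments, all pair counts) for n ≤ 8 and the approximation
against exact enumeration p-values.

* Fraction learned vs zero: one-sided Wilcoxon signed-rank per group.
* Variability after failure vs after success: one-sided paired
  signed-rank on the per-participant condition medians.
* Child-adult comparisons: one-sided Mann-Whitney U.
* Development: OLS of fraction learned on age with all adults grouped at
  18, so the slope measures childhood-to-adulthood change only.
* Motivation: Likert items scored as the mean of the two most strongly
  correlated items (selected by the Pearson item-item matrix);
  Cronbach's alpha as `k/(k−1)·(1 − Σvar_i/var_total)` with sample
  variances; groups compared by a two-sided Pearson chi-square over the
  observed score levels (two-item means can take half-point levels),
  df = levels − 1.
* Developmental curves: Gaussian-kernel weighted means over log age,
  kernel SD log(1.1), evaluated by default at each log-transformed
  integer year observed.

## Calibration checks and problem sizes

The simulation-based checks in the test suite use: 100 cohorts × 30
agents for the exploration signature (σ_fail > σ_succ must yield a
larger median ratio after failure in ≥ 95 % of cohorts; observed
100/100); 200 cohorts × 30 agents for the paired test's type-I error
(observed 0.08, within 3 MC SE of 0.05); and ≥ 10⁵ criterion trials in
independent chains for the 6/11 order-statistic law.  Monte-Carlo
standard errors for the criterion check are estimated across independent
chains, not per trial, because consecutive rewards share nine window
entries and are autocorrelated.  These cohort simulations run
radius-only; the calibration run of 100 fully rendered reference agents
takes a few seconds.

**The reward-independent null.**  For the type-I check the control agent
sets σ_fail = σ_succ *and* ρ = 0: retention toward the last rewarded
radius is itself reward-gated behavior, so a generative null for "reward
does not modulate variability" must sever both reward-dependent paths.
With ρ = 0 the intended radius is a pure random walk, reward has no
causal route into behavior, and — because the adaptive criterion holds
success near 50 % — the reward-conditioned step distributions are
mirror-symmetric and fold to the same law, making the null exact.

## Known limitations

* The reference agent is an efficient learner: it typically reaches the
  doubled target within ~25 trials (median fraction learned ≈ 1.0).
  Because success is judged against a lagging 10-trial window, that
  improvement transient lifts the session-level success frequency to
  ≈ 0.66, above both the stationary 6/11 and the ≈ 0.47 that human
  cohorts show.  Reproducing a sub-1/2 success frequency requires
  nonstationary wandering error levels (weak retention or a strong
  baseline attractor), i.e. slower, messier learning than the reference
  parameterization produces.  The discrepancy is a property of the
  generative model, not of the reward engine, whose stationary behavior
  matches the 6/11 law exactly.
* The paired-test type-I rate is exactly nominal only under the
  reward-independent null above; with retention active, reward feedback
  truly modulates behavior and a "type-I" reading does not apply.
* Reading foreign trial-summary layouts requires a dialect descriptor
  (column mapping + unit scale) registered at run time; only the native
  layout ships built in.
* Replaying recorded trajectories through `analyze` recomputes rewards
  with this engine's bootstrap choices, which may differ from the
  original software on the first few trials of a session.
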