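# Methods

This note documents the models, conventions and design choices behind
`mtverify`: what the synthetic-experiment generator assumes, how the
trajectory measures and mixed models are defined, and which decisions were
genuinely open.

## The task and its design

One experiment crosses a scene bank (default 225 base scenes) with two
two-level within-item factors — plausibility of the depicted event and
congruency between sentence and scene — yielding `4 × n_scenes` items.
Items are partitioned into four Latin-square lists: each list contains
every scene exactly once, and across lists every scene contributes each
condition cell exactly once, so no participant ever sees the same scene
twice.  The per-scene rotation phase is a seeded permutation balanced over
cells, which keeps every list's cell composition as equal as possible
(±1 when `n_scenes` is not divisible by 4).

Participants (default 64) are assigned to lists round-robin.  The two
between-participants factors — modality order (sentence-first vs
scene-first) and yes/no counterbalancing — are assigned by cycling the four
(order, counterbalance) combinations with a per-list phase stagger, which
balances both factors, their crossing, and their crossing with lists
whenever the participant count is a multiple of four.  Each participant
receives `per_participant` items (default 100) from their list with exactly
balanced cells (25 per cell; remainders rotate across participants), and a
per-(list, cell) round-robin cursor keeps global item usage equal up to
remainder.  Whether the original 100-item selections were cell-balanced is
not documented anywhere we could rely on; balanced cells maximize the power
of the recovery studies and are the package's choice.

## The trajectory generator

Screen geometry: 1024 × 768 px, calibration circle at the bottom-center
(512, 750), response buttons inset 15 % from the top corners
((153.6, 115.2) and (870.4, 115.2)), equidistant from the vertical midline;
sampling at 60 Hz.  Button pixel positions are not specified by the
paradigm description beyond "top corners, equally spaced from the center",
so the 15 % inset is a layout choice.

Each trial unfolds in two phases:

1. **Dwell.** The cursor holds at the calibration point for
   `max(0.05 s, latency_base + βʳᵗ·x + u_p + u_s + ε)` where `x` is the
   trial's ±0.5 contrast-code vector, `u_p, u_s` are participant and scene
   normal random intercepts (SDs 0.08 s / 0.04 s) and
   `ε ~ N(0, 0.08² s²)`.  The additive dwell model gives the generator
   *known* ground-truth fixed effects on the seconds scale, which the
   recovery studies exploit.
2. **Movement.** Per 60-Hz step the velocity is
   `v = s·û_target + λ·w(t)·û_competitor + N(0, σ²I)` with base speed
   `s = 14 px/step` (≈ 0.9 s of movement over the ≈ 729 px start–button
   distance, a realistic movement time), motor noise `σ = 4 px`, and a
   conflict pull `λ = softplus(βᶜ·x)` weighted by `w(t)`, a linear decay
   from 1 to 0 over the first 60 % of the expected path.  Any nonincreasing
   early-weighted pull would serve; linear is the most transparent.  The
   trial ends when the cursor is within 40 px of the responded button; a
   10-s cap raises a runaway error (unreachable under sane parameters since
   the pull decays to zero).

Accuracy is Bernoulli with logit `βᵃ·x + u_p + u_s` (random-intercept SDs
0.8 / 0.5 on the logit scale); an incorrect draw sends the trajectory to
the wrong button.  Response time is the full trajectory duration
(dwell + movement).

Default coefficient vectors (over intercept, P, C, O, P:C, P:O, C:O,
P:C:O):

| vector | default | rationale |
|---|---|---|
| `beta_accuracy` | (2.87, 0.51, 0.005, −0.45, 0.83, 0.26, −0.49, 0) | the reference accuracy-model coefficient structure; makes implausible+congruent the least accurate cell |
| `beta_rt_s` | (0, −0.07, 0.02, −0.02, −0.06, 0.04, −0.06, −0.01) | the reference RT effect structure in seconds, applied to the dwell |
| `beta_conflict` | (11, −1, 0, 0, −3, 0, 0, 0) | pull ≈ 9–13 px/step against 14 px/step base speed; produces exit angles of −2°…−9°, AUC ≈ 0.2–0.35 and 1.5–2.5 x-flips, largest for implausible+congruent |

Randomness uses one root seed split into named substreams (effects,
accuracy, motor) via `numpy` `SeedSequence`, so identical inputs reproduce
byte-identical CSV exports.

**What the generator does *not* emulate.** The reading/preview phase is not
simulated — trajectories start at choice-display onset, where all measures
are defined.  The movement aims directly at the target rather than starting
vertically, so absolute initial-degree values are anchored to the ideal-line
angle (≈ −29° with zero conflict) and only relative, conflict-driven shifts
are meaningful.  Marginal simulated accuracy (~0.93) is higher than typical
human performance on this task (~0.87); the generator inherits the
conditional coefficient scale without the extra heterogeneity (machine
error, lapses) of real data.  Passing tests therefore certify the
*machinery* — measure geometry, estimator calibration, effect directions —
not quantitative agreement with any human dataset.

## Preprocessing

Trials with verification time above `mean + k·SD` (default k = 4) of the
grand RT distribution are removed first; dynamics analyses then keep only
accurate trials.  The SD rule is grand-level and upper-tail-only — the
simplest reading of an exclusion phrased as "greater than"; per-participant
or two-sided variants would be easy to add but are not the default.  Sample
SD uses the n−1 convention.

Canonicalization translates the start point to the origin, flips y so the
response row is positive, reflects x so the **incorrect** button lies at
+x, and rescales to x ∈ [−1, 1], y ∈ [0, 1.5] — the conventional normalized
mouse-tracking space (the correct button sits at (−1, 1.5)).  The frame is
anisotropic, so the canonical object retains the per-axis pixel scales;
every pixel-defined quantity (50-px start radius, x-flip jitter, movement
angles) is evaluated in pixel-equivalents, while AUC is reported in
standardized units.

Time normalization linearly interpolates positions onto `n_bins` (default
101) equally spaced time points and attaches per-bin movement angles
(degrees from vertical, positive toward the incorrect side, computed from
the displacement to the next bin; the final bin reuses the last
displacement).  Displacement angles — rather than cumulative position
angles — keep the growth-curve response on the same scale as the
initial-degree measure.

## Measures

- **Initial degree**: signed angle of the first sample strictly outside the
  50-px start radius (no interpolation to the circle crossing — at 60 Hz
  the difference is sub-degree); missing if the radius is never exited.
- **Latency**: the timestamp of that first exit sample, in seconds; missing
  likewise.
- **x-flips**: x-displacements are accumulated until the running sum
  reaches the jitter threshold (default 3 px; 0 reproduces the naive
  count); sign changes of the surviving displacements are counted.  The
  threshold default is a package choice — no canonical value exists.
- **AUC**: *signed net* trapezoidal area between the sampled polyline and
  the straight start→correct-button segment (excursions on the correct side
  subtract), closed along the ideal line at both ends; this equals the
  shoelace area of the polygon formed by the path and the reversed ideal
  line, which the tests verify on random polylines.  Signed net area is the
  dominant convention and preserves "greater area = stronger competition".

Cell summaries report mean ± SD per order × congruency × plausibility cell;
accuracy over all retained trials, RT and trajectory measures over accurate
trials only (the set the decision-dynamics analyses are defined on).  An
n = 1 cell displays SD 0 in rendered tables but exports a missing SD.

## Mixed-effects inference

All two-level factors are coded ±0.5 (Plausible, Congruent, Scene-First
= +0.5), so main effects are grand-mean effects and a balanced design makes
the seven predictors orthogonal.  Each Gaussian measure is fit by REML with
all seven fixed terms and a maximal *uncorrelated* random structure;
accuracy uses a binomial-logit model (Laplace).

Random-slope admissibility is decided per grouping factor: a slope enters
for every predictor composed solely of base factors that vary within the
unit.  Participants therefore carry plausibility, congruency and their
interaction (order is between-participants; its interactions are
within-participant collinear with lower-order terms, so their variances
would be unidentifiable); scene units (scene × plausibility, mirroring the
450-level scene factor of the original design) carry congruency, order and
their interaction; counterbalancing (2 levels) carries an intercept only —
slopes on a two-level grouping factor are practically unidentifiable.

On a singular fit the slope with the smallest estimated variance is dropped
and the model refit, iterating until non-singular or slopes are exhausted;
the reduction path is recorded in the result.  The accuracy model defaults
to random intercepts (recorded in the result notes) with a maximal option.
p-values use the normal reference for the mixed-model t/z — the df method
behind the original tables is not documented; the policy is recorded in
every result and pluggable in principle.

Estimation is delegated to lme4/glmer through an `Rscript` subprocess
(uncorrelated slopes as separate variance components).  statsmodels serves
as an independent cross-check in the test suite: OLS equality when the
random structure is removed, and MixedLM agreement for a random-intercept
model.

### Growth-curve analysis

Angle profiles are aggregated to participant × condition-cell × bin means
and regressed on orthonormal polynomial time terms (QR-orthogonalized over
the bin grid, constant excluded, default cubic) crossed with the condition
codes, with by-participant random intercept and time slopes.  101 bins and
cubic polynomials follow field convention; both are settings of `GCASpec`.

## Validation studies and their sizes

The `validation` module closes the generator–estimator loop:

- **Type-I calibration**: 200 null experiments (all fixed effects and
  random variances zero, accuracy saturated) at 16 participants × 40 trials
  (40-scene bank); the plausibility × congruency test rejects at the
  nominal 5 % rate.
- **Recovery**: 100 replicate experiments with a known RT interaction
  (−0.06 s) and, separately, a known accuracy-logit intercept (2.87); the
  95 % Wald CIs cover the truth at their nominal rate.  Coverage is a
  size-invariant property, so these studies run at the 16 × 40 scale — a
  full-design (64 × 100) maximal crossed fit takes tens of seconds and
  replicating it hundreds of times would serve no inferential purpose.
- **Conflict sweep**: 200 replicate trajectories per pull value
  λ ∈ {0, 2, 4} at motor noise 5 px.  Mean AUC rises strictly with
  bootstrap-CI-separated differences.  x-flips at these sub-threshold pulls
  are noise-dominated (the pull never reverses lateral motion against a
  14 px/step base speed), so the flip check asserts no CI-significant
  decrease; the flips' positive response to conflict is instead exercised
  at the generator's operating point (λ ≈ 11), where the
  implausible+congruent cell shows the most flips, the largest AUC and the
  lowest accuracy across 20 pooled replicate experiments.

## Known limitations

- The attractor is a phenomenological stand-in: no velocity profiles,
  submovement structure, or reading-phase dynamics, and the conflict pull
  is deterministic given the condition (no trial-level conflict
  variability beyond motor noise).
- Random *slopes* are absent from the generator, so maximal fits on
  generated data are routinely singular and exercise the pruning path by
  construction.
- The normal p-value reference is mildly anticonservative at very small
  sample sizes; the calibration study bounds this at the sizes used.
- Mirror symmetry of the measure set holds as two separate exact
  reflections (across the ideal line for AUC; across the vertical axis for
  initial degree, latency and x-flips) — no single reflection negates both
  area and exit angle while preserving the others.
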