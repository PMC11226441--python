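# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the package, in the order the pipeline
runs them.

## Trajectories, meshes and units

All motion lives on landmark meshes: `K` 3-D points with a named partition
into `head_rigid`, `left_periocular`, `right_periocular`, `perioral` and
`other`.  Coordinates are dimensionless (webcam-style data carries no metric
calibration; magnitudes are only compared within an experiment).  The default
topology is a procedural 64-point face; a 468-point map following the
MediaPipe FaceMesh contour convention is packaged for users with real
tracking data, with procedural coordinates since no canonical face scan is
shipped.  Trials are 20 s at 30 fps (600 frames).

## The synthetic actor

`generate_actor_motion` emulates one person moving freely for one trial.
Two layers:

* **Rigid head motion.**  Euler-angle rotations about the head centroid plus
  translation.  Each of the six pose components is `amp · (sin(2πft + φ) +
  walk_sd · w(t))` with low frequencies (0.045–0.09 Hz), random phases and a
  twice-filtered AR(1) walk `w` (coefficient 0.99, unit variance) — slow
  postural drift, neither pure tone nor jitter.  On top, sparse head
  *gestures*: Poisson repositioning events (default 0.1/s, at least one per
  trial) realised as 0.8-s raised-cosine translation pulses of amplitude
  0.12 along random directions.  The gestures dominate the head and overall
  motion channels, so those channels contribute few, discrete peaks rather
  than a continuous wobble.
* **Facial actions.**  A Poisson stream (default 0.5/s, minimum two, both
  channels guaranteed) of short gestures: eye actions (0.4-s lid-closure
  pulses toward the eye centres, both eyes) or mouth actions (one radial
  open–close cycle at 1.2 Hz).  The channel of consecutive actions switches
  with probability `switch_rate / (60 · action_rate)`, making `switch_rate`
  the expected number of cross-channel switches per minute.

Deformations are applied in the neutral frame *before* the rigid transform,
so head stabilisation recovers them exactly, and everything is linear in its
amplitude parameter: scaling `exploration_multiplier` rescales the identical
realisation (the basis of the exact path-length-doubling test).  Per-landmark
Gaussian tracking noise (sd 0.001) is added last.  All tensor work runs in
float32; the trajectories sit at unit scale, far above float32 resolution,
and every analysis function follows its input dtype so high-precision tests
run in float64.

**Exploration mode** (other-face trials) multiplies all amplitudes by 1.6 and
raises `switch_rate` from 3 to 18 per minute.  The two knobs map one-to-one
onto the two behavioural findings the generator is designed to emulate:
amplitude drives moving distance, switching drives the diversity index.
These values, like every generator default not fixed by the study design,
were chosen once to produce a realistic, clearly detectable effect pattern at
n = 20 and are not fitted to any real data.

## Control mixing and the display

Mixing acts on displacement-from-neutral fields — the mesh-level analogue of
a generative animator's latent motion vectors: `mixed = w·d_self +
(1−w)·d_other`, `w = 1` full control, `w = 0.5` partial control.  A sole
mover under `w = 0.5` keeps full directional control at half amplitude; an
optional renormalisation flag (off by default, since the real system's
behaviour is not documented) restores unit gain.  The displayed trajectory is
the *target identity's* neutral mesh plus the latency-delayed mixed field —
identity is carried entirely by the neutral mesh, motion by the displacement
field, which is exactly the paradigm's separation of appearance and motion.
Latency is a constant 9 frames (300 ms at 30 fps; only a mean latency is
known, so no jitter is modelled).  The display chain adds per-frame global
registration jitter (sd 0.003), which keeps even full-control trials short of
perfect consistency, as in the real apparatus.

## Kinematics

Per frame, the least-squares rigid transform (Kabsch, no scaling, proper
rotation enforced via the determinant sign) maps the neutral pose onto the
frame over the `head_rigid` landmarks; collinear point sets are rejected.
Channels:

* `overall` — mean per-landmark frame-to-frame displacement, rigid motion
  included;
* `head` — the same magnitude computed on the rigid reconstruction of the
  head region (translation contributes its norm, rotation its mean chord
  length);
* `left_periocular`, `right_periocular`, `perioral` — computed after
  re-expressing every frame in the head-fixed coordinates (`remove_rigid`
  defaults to on; the raw-coordinate variant exists because the original
  definition is not public).

**Moving distance** is the path length — the sum of per-frame magnitudes —
over the trial, not the net displacement; all trials share one duration, so
no per-second normalisation is applied by default (a flag exists for
unequal-length data).

## Motion diversity and control error

Each channel (periocular pooled as the mean of left and right) is smoothed
with a centred 0.5-s moving average, z-scored per trial (constant series map
to zeros), and searched for peaks with prominence ≥ 1 z-unit and ≥ 0.3 s
separation (`scipy.signal.find_peaks`; conflicts keep the higher peak).  All
peaks are merged in time — ties broken by the fixed channel order overall <
head < periocular < perioral — and the index is the number of adjacent
cross-channel pairs per minute.  The defaults target sub-second facial
actions with one dominant action at a time; the original detection settings
are not public, so all of them are configurable, as is dropping the
(correlated) overall channel from the switching set.

The control error converts both trajectories to displacement fields,
estimates the display latency as the argmax of the cross-correlation of the
overall-motion series over lags 0..max_lag (ties to the smallest lag,
zero-variance series return 0 with a warning), shifts the display back, and
averages the per-frame RMS landmark-displacement difference over the
overlapping frames.  Under `w = 1` and exact latency compensation the error
is identically zero; at `w = 0.5` it equals half the RMS displacement gap
between the actors plus the display jitter.

## The two-mode agency model

Sensorimotor consistency is operationalised as `c = clip(1 − error /
error_scale, 0, 1)` with `error_scale = 0.12`, placing typical full-control
trials near c ≈ 0.96 and partial-control trials near c ≈ 0.5.  Each mode maps
c to a 0–100 rating through `b + A/(1 + exp(−k(c − c0)))` with `A + b ≤ 100`:

| mode | k | c0 | A | b |
|---|---|---|---|---|
| exploit (self-face) | 20 | 0.88 | 85 | 5 |
| explore (other-face) | 6 | 0.60 | 70 | 15 |

The exploitation curve is steeper with a midpoint close to perfect control;
the curves cross exactly once inside (0, 1) (verified by a sign-change scan),
so the model predicts lower agency for the self-face whenever control is
imperfect and higher agency only near-perfect control.  The four-parameter
logistic is the smallest family that can express steep-vs-gentle curves with
different end confidence; the underlying theory draws the curves without
formalising them, so the parametrisation and all default values are choices
of this package.  Ratings add a participant-level Gaussian intercept (sd 5)
and trial noise (sd 8), truncated to [0, 100].

Self-identification is additive: `20 + 45·[face=self] + 12·[control=full] +
noise(sd 10)` — appearance dominates, control contributes.

`fit_curves` recovers the per-mode parameters by bounded trust-region least
squares from ≥ 5 starts (4 fixed, seeded random extras), requiring ≥ 8
distinct consistency values per mode; non-convergence is flagged on the
result, never raised.

## Statistics

The 2×2 within-subject ANOVA is computed in closed form from the three
orthogonal cell contrasts; each effect's F equals the square of the paired t
on its contrast with df = (1, n−1), which makes the implementation exactly
testable against a brute-force sums-of-squares oracle (and against pingouin
in the test suite).  Zero error variance yields F = +∞ with a warning.
Partial η² = F·df₁/(F·df₁+df₂).  The paired t reports Cohen's
d_z = mean(diff)/sd(diff); exactly identical samples return t = 0 rather than
failing.  d′ = z(hit) − z(fa), with the 1/(2N) correction for extreme rates
when the trial count is supplied.  Power uses the noncentral t distribution —
paired: df = n−1, noncentrality d√n; independent: df = 2n−2, d√(n/2) — and
`sample_size_t` scans upward for the smallest n reaching the target.  At
d = 0.617, α = .05 one-tailed and power 0.8 the paired formulation yields
n = 18 while the independent formulation yields 34 per group; the published
figure of 18 is therefore consistent only with the matched-pairs reading,
which this package adopts as the primary interpretation while implementing
both.  The repetition check is re-specified as a trend test (per
participant × condition least-squares slope of the rating against repetition
1..5, one-sample t of slopes per condition), since the original analysis
form is not described in detail.

## What the generator does and does not emulate

Passing tests show that the *pipeline* recovers the effect structure that the
generator puts in: larger and more diverse other-face motion, error-driven
two-mode ratings, appearance-dominated identification.  They do not validate
the generator against real faces.  Known simplifications:

* behaviour does not react to the control condition (real participants
  reduced eye/lip movement under partial control; here only ratings and the
  control error depend on it, so movement ANOVAs show a face effect but no
  reliable control effect);
* the two-mode curve family implies a face × control interaction in the
  simulated agency ratings that the real data did not show — with crossing
  curves, the full-vs-partial drop is necessarily steeper in exploitation
  mode;
* facial actions are stereotyped pulses; real expressions co-articulate, and
  involuntary blinks are not modelled separately from deliberate eye actions;
* the display chain is a constant delay plus global jitter, with no
  reconstruction artifacts that differ between identities.

## Problem sizes and tolerances

The default experiment is the full study design (20 participants × 4
conditions × 5 repetitions, 600-frame trials, 64 landmarks).  The end-to-end
replication check runs 50 seeded experiments; the curve-recovery study uses
200 trials per mode at rating noise sd 5 with uniform consistency sampling
(identifiable everywhere on the curve).  Exact identities are asserted at
1e−10 (ANOVA vs oracle), geometric recoveries at 1e−8 (Procrustes) and 1e−6
(rigid invariance in float64); generator-level checks use 1e−4–1e−5 because
trajectories are float32.  The Monte-Carlo power oracle uses 10⁵ replicates
(binomial SE ≈ 0.0013, well inside the 0.01 agreement bound).
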