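# facemix

Synthetic face-motion-mixing experiments and their analysis: a testable
re-implementation of the sensorimotor pipeline behind studies in which
people control an animated face — their own or somebody else's — through
their head and facial movements, and report how much agency they feel over
it.

## The scientific problem

When the face on the screen looks like *you*, you believe you are in
control, and that belief changes how you judge control: you become acutely
sensitive to sensorimotor prediction errors (the **exploitation** mode).
When the face belongs to somebody else, no such prior exists; judgments
lean on action–feedback regularities and behaviour becomes larger and more
varied (the **exploration** mode).  The package models both sides of this
story:

* **Behaviour** — a seeded generator produces facial-landmark trajectories
  (a `T x K x 3` tensor at 30 fps) of two actors; the displayed face is
  driven by a convex mix of their displacement fields,
  `w·self + (1−w)·other`, with `w = 1` (full control) or `w = 0.5`
  (partial control) and a ~300 ms display latency.
* **Kinematics** — each trial is decomposed per frame into rigid head
  motion (least-squares Procrustes fit on the rigid landmarks) and
  head-stabilised facial-muscle motion, giving moving distances for the
  whole face, head, left/right periocular and perioral regions, a
  peak-switching **motion-diversity index** (switches of the peak-bearing
  motion channel per minute), and an objective control error between the
  participant's motion and the display.
* **Judgment** — per-trial agency ratings follow a two-mode four-parameter
  logistic in the sensorimotor consistency `c = 1 − error/scale`:

  `rating(c) = b + A / (1 + exp(−k·(c − c0)))`

  with a steep exploitation slope (`k = 20`, midpoint near perfect
  control) and a gentle exploration slope (`k = 6`); the curves cross once
  inside (0, 1), so imperfect control hurts agency over the own face most.
* **Statistics** — the 2×2 (face × control) within-subject ANOVA with
  partial η² (= F·df₁/(F·df₁+df₂)), Bonferroni-corrected paired t tests
  with Cohen's d_z, signal-detection d′, and noncentral-t power analysis.

## Worked example

```
$ python analysis/01_power_analysis.py
paired       d=0.617: minimal n = 18 (power 0.8069)
independent  d=0.617: minimal n = 34 (power 0.8086)
```

At the effect size d = 0.617 observed for the difference between detecting
increases and decreases of control, 18 participants suffice for 80% power
in the matched-pairs noncentral-t formulation (one-tailed, α = .05).

```
$ python analysis/02_simulate_experiment.py --seed 1
wrote 400 trials to results/trials.csv
               agency_rating  identification_rating  dist_overall  diversity  motion_error
face  control
other full            76.473                 31.741         2.483      34.44         0.005
      partial         38.344                 18.527         2.499      31.92         0.063
self  full            78.056                 75.377         1.977      23.49         0.005
      partial          6.754                 64.192         1.957      22.86         0.048
```

The synthetic experiment (20 participants × 2×2 conditions × 5
repetitions of 20-s trials) reproduces the qualitative pattern of the
paradigm: agency is much higher under full than partial control and, in the
partial-control condition, higher for the other-face than the self-face
(38.3 vs 6.8) — the exploitation mode punishes imperfect control;
self-identification is dominated by facial appearance (75 vs 32 at full
control) with a smaller control bonus; moving distance (2.48 vs 1.98,
dimensionless units) and the diversity index (34 vs 23 switches/min) are
larger for the other-face, the explorative-behaviour signature.

```
$ python analysis/03_rating_and_movement_anovas.py
agency_rating        face     F(1,19) =  201.407 p = 0.0000* partial eta^2 = 0.914
...
diversity            face     F(1,19) =  125.393 p = 0.0000* partial eta^2 = 0.868
repetition trend on agency rating: all |t(19)| < 0.77, all p > .45
```

All face effects point the documented way and the repetition check shows no
habituation trend.  `analysis/04_fit_agency_curves.py` refits the two-mode
curve family from the simulated ratings and recovers the slope ordering
`k_exploit > k_explore`.

The same stages are available as a command line (`facemix run|simulate|
stats|fit|power`) and as plain library calls (`facemix.generate_experiment`,
`facemix.rm_anova_2x2`, ...).

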