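# graspbias

Where along an object do people place a precision grip — and why?
When a cylinder lies obliquely on a table, grasping it toward the acting
hand keeps more of the object visible (the hand occludes less of it),
while grasping it toward the hand's start location shortens the reach.
At some orientations these two accounts agree; at others they pull the
grasp to opposite ends of the object. `graspbias` implements the
analysis that decides between them from thumb and index fingertip
contact points, together with a synthetic-data generator that makes the
whole pipeline testable without any recordings.

Intended users: sensorimotor researchers with grasp contact-point data
(e.g. from motion capture) on oriented cylindrical objects, and anyone
who wants a reproducible reference implementation of medoid-based grasp
statistics.

## The analysis

Each trial yields thumb and index contacts **t**, **i** ∈ ℝ³ (cm, table
frame: x right, y away from the actor, z up, origin at the object
center). The grasp center is **c** = (**t** + **i**)/2, and its signed
coordinate *u* along the cylinder's long axis measures the deviation
from the object midline (*u* = 0). Grasps whose thumb–index line lies
within 45° of the long axis sit on the cylinder's ends and are excluded.

Per participant and orientation, the summary grasp is the **medoid** —
the element *g* of a set *G* minimising Σ<sub>h∈G</sub> d(g, h), under a
grasp distance d (default: Euclidean distance between centers). Unlike
a mean, the medoid is always a physically realised grasp. A group
medoid across the per-participant medoids summarises the sample.

The bias magnitude *b* = |*u*| of the medoid at the **reference
orientation (150°)** — where visibility and reach agree on the
preferred side — is carried to the **target orientation (60°)** — where
they disagree — producing two predicted grasps at ±*b* along the axis
with idealised surface contacts perpendicular to it. For each
participant the distances from their 60° medoid to the two predictions,
d<sub>vis</sub> and d<sub>reach</sub>, are compared with a two-sided
paired t-test on d<sub>reach</sub> − d<sub>vis</sub> (df = N − 1); the
winning hypothesis is the one with the smaller mean distance, when
p < α (default 0.05).

The generator simulates the full design — 14 participants × 4 materials
× 5 repetitions at each orientation — under a chosen generative
hypothesis, with participant-level bias drawn from a truncated normal
population, isotropic motor noise on each digit, and a 4% rate of
degenerate long-axis grasps.

## Worked example

```sh
graspbias simulate --seed 5 --out sim.csv
graspbias analyze --data sim.csv --out out --figure
```

prints

```
wrote 560 records to sim.csv
Grasp-bias comparison: object visibility vs. minimum reach
  participants:            14
  long-axis grasps excluded: 3.9%
  reference bias (group):  1.597 cm
  mean distance to visibility prediction: 0.250 cm
  mean distance to reach prediction:      3.252 cm
  smaller mean distance:   visibility prediction
  paired t-test: t(13) = 8.858, p = 7.21e-07 (alpha = 0.05)
  winner: visibility
```

The simulated actors were generated under the visibility hypothesis
(bias 1.5 ± 0.5 cm across participants, 0.5 cm motor noise), and the
pipeline recovers that: the 150° bias (1.60 cm here) transferred to 60°
lands almost on top of the observed medoids (0.25 cm away on average),
while the reach prediction on the opposite side of the midline is
~3.25 cm away — a difference the paired test finds decisive.
`out/result.json` holds the same numbers machine-readably and
`out/grasp_centers.png` shows the per-participant medoids against both
predictions.

The same analysis runs on real data via `--config`, a YAML file naming
the input columns, object dimensions, start location, metric, and bias
source (see `graspbias.AnalysisConfig`).

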