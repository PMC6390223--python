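# Methods

## Coordinate conventions

All geometry lives in a right-handed *table frame*: origin at the
object center on the table surface, x toward the actor's right, y away
from the actor, z up, units cm. The layout constants are encoded once
in `graspbias.config`: hand start at (26, −25, 0) — 11 cm from the
table edge and 26 cm right of an object 36 cm from the edge — and the
transport goal at (28.5, 0, 3.7). The start is therefore
√(26² + 25²) ≈ 36.07 cm from the object center.

The cylinder's long-axis angle θ is measured counterclockwise from +x,
viewed from above. The axis is undirected, so poses are normalised to
θ ∈ [0, 180). Under this convention the two study orientations behave
as described: at 150° the rightward end of the object is also the end
nearer the start (the hypotheses agree), while at 60° the rightward end
is the farther one (they disagree). A test verifies this rather than
assuming it. If recorded data use a different angular convention, the
column-mapping/config layer is the place to convert; the analysis never
guesses.

The object frame at a pose is (u, v, w): u along the axis
(cos θ, sin θ, 0), v along the in-plane normal (−sin θ, cos θ, 0), w
vertical. The *object midline* is the plane u = 0.

## Grasp summaries and exclusion

A grasp's center is the thumb–index midpoint; its long-axis deviation
is the u-coordinate of that center; its grasp-axis angle is the acute
3-D angle between the (undirected) thumb–index line and the long axis,
in [0°, 90°]. Grasps with grasp-axis angle below a threshold lie along
the axis — on the cylinder ends — and are excluded before any
statistics. The threshold defaults to 45°, which partitions grasps into
across-the-axis vs along-the-axis with no gap; it is configurable
because the boundary is a modelling choice, not a measured quantity.
The reported exclusion fraction is computed over the records at the two
analysed orientations, with per-orientation counts alongside so other
accountings can be read off.

## Medoid statistics

The medoid of a grasp set is the element minimising its summed distance
to all elements — a member of the set, so the summary is always a
physically realised grasp. Two distances are implemented:

* `center` (default): Euclidean distance between grasp centers. The
  bias and both hypothesis predictions are statements about the grasp
  center, and this metric is immune to thumb/index labelling errors.
* `mean_digit`: mean of thumb–thumb and index–index distances, for
  sensitivity analyses that care about full grasp configuration.

Both are metrics (each is built from Euclidean norms), which property
tests confirm on random triples. The medoid is computed by exhaustive
pairwise summation — sets here hold ≤ 20 grasps per participant and 14
per group, so O(n²) is the honest and the fast option. Ties are broken
by earliest position in the input sequence; the pipeline sorts records
by (participant, material, repetition) first, so results are
independent of file row order. The same metric is used at both levels
(within participants and across their medoids): a single notion of
grasp similarity throughout.

## Hypothesis predictions

Both hypotheses are reduced to a side-of-midline choice times the
measured bias magnitude, with idealised contacts: diametrically
opposite on the curved surface, grasp axis perpendicular to the long
axis, contact separation 2·radius, thumb on the actor-near side for a
right hand.

* *Visibility*: the preferred side is the acting-hand side — the axis
  end with the larger x for a right hand (smaller for a left). No
  occlusion raycasting is performed; the hypothesis as tested is purely
  about which side of the midline the grasp falls on. θ = 90° has no
  hand side and raises rather than tie-breaking.
* *Reach*: the preferred side is found by evaluating the start-to-center
  distance of both candidate offsets and taking the shorter, so the
  construction generalises to any layout; a test pins the study layout
  to the expected sides (both hypotheses point to the same side at
  150°, opposite sides at 60°).

Bias magnitudes come from the 150° data only; the 60° grasps never feed
the predictions, so the comparison cannot be circular. With
`bias_source = per_participant` (default) each participant's own 150°
medoid deviation is used, matching the per-participant test; `group`
uses the mean deviation for everyone. Zero bias makes both predictions
collapse to the object center.

## The comparison test

Per participant, the distances from the 60° medoid to the two predicted
grasps are compared with a two-sided paired t-test on
d_reach − d_vis (positive t favours visibility). The winner requires
both the smaller mean distance and p < α (default 0.05); otherwise the
result is `inconclusive`. One degenerate corner: if all paired
differences are identical, the t statistic has zero denominator. When
the common difference is zero the samples are indistinguishable and the
test returns t = 0, p = 1; a constant nonzero difference has no finite
statistic and raises, since any declared p would be arbitrary.

## Synthetic data

The generator emulates the study design: 14 participants × 4 materials
× 5 repetitions at each of 150° and 60° (560 records, 20 per
participant per orientation). Per participant, a bias magnitude is
drawn from a normal population truncated below at zero (defaults:
mean 1.5 cm, sd 0.5 cm); each trial's intended grasp sits on the
generating hypothesis's preferred side at that magnitude, with
isotropic Gaussian motor noise (default sd 0.5 cm) added independently
to thumb and index — so the grasp-axis angle is noisy too and the
exclusion filter is exercised realistically. With probability 0.04 a
trial is replaced by a degenerate long-axis grasp spanning the cylinder
ends. The population mean and the degenerate-trial rate mirror the
study conditions; the population sd and motor-noise sd are free
simulation parameters with no measured counterpart, chosen once at
0.5 cm as plausible trial-to-trial and between-participant variability
for fingertip endpoints at this scale.

Because noise can tip an ordinary grasp past the 45° threshold, the
*flagged* fraction runs slightly above the 4% replacement rate (about
5% under defaults); tests therefore compare the pooled flag rate
against the binomial variability a single 560-trial dataset would show
around 4%, not against 4% exactly.

Cylinder dimensions default to length 10 cm, radius 1.25 cm — plausible
for the hand-scale cylinders the design implies — and are configurable;
when analysing real data they should be set to the recorded object's
true dimensions. Material labels carry no geometric effect (the
analysis pools across materials); `material_bias_shift` exists as an
extension hook and defaults to off.

What the generator does *not* emulate: reach trajectories and dynamics,
material/friction effects on contact placement, digit-placement
correlations beyond the shared center, end-cap surface geometry, and
participant handedness mixtures. Passing recovery tests therefore show
that the pipeline identifies the generative side structure under
realistic noise — not that real grasp data satisfy these simplifying
assumptions.

## Numerical choices

* Frame round-trips are exact to 1e-9 cm; tolerance-sensitive
  comparisons in tests use that scale.
* θ = 90° degeneracies (no hand side; contacts with equal y) are
  detected with a 1e-9 tolerance on unit-vector components rather than
  exact equality.
* `surface_contacts` thumb/index assignment: thumb takes the smaller-y
  contact (`near`), falling back to smaller x when y ties (θ = 90°).
* Written CSV coordinates carry 6 decimals, making generator output
  byte-identical across runs with the same seed.
* Medoid ties (equal distance sums) take the earliest element in
  (participant, material, repetition) order.

## Problem sizes

The recovery and calibration checks run 100 simulated datasets per
generative regime at the full design size (560 trials); medoid
correctness is checked against an exhaustive argmin on 200 random sets
of up to 20 grasps. These sizes give binomial resolution of a few
percent on recovery rates while the whole suite stays interactive.

## Known limitations

* The visibility account is operationalised as hand-side preference
  only; a graded occluded-area model would require hand geometry that
  contact points alone do not constrain.
* The reach account uses start-to-grasp-center distance, not arm-joint
  cost or transport-phase distance.
* With `bias_source = group`, a participant whose bias opposes the
  group mean still receives the group magnitude; the per-participant
  default avoids this.
* Only two orientations are analysed; the machinery accepts any
  non-degenerate reference/target pair but has been exercised on the
  150°/60° design.
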