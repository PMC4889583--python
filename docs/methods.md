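# Methods

## The model

`remapnet` simulates a small visuo-oculomotor system as a hierarchy of
topographic *sheets* of sigmoid units. A retina sheet carries the image of a
single object (the "ball") as a Gaussian bump of activity; a superior
colliculus (SC) sheet carries the vector of an impending saccade as a bump on
a motor map, and a copy of that command — the corollary discharge (CD) — is
sent into the network; an eye-position (EP) sheet carries the orientation of
the eye in the body as a bump. Retina and SC project all-to-all onto a
hidden sheet, the hidden sheet projects all-to-all onto an FEF sheet, and the
FEF output is combined with the EP sheet in a frozen body-centered (BC)
stage. Pointing behavior is scored by decoding the BC sheet's activity
centroid and comparing it with the ball's true workspace location; the
network's only training signal is that this pointing be continuously
accurate, at every 10 ms step of every trial, even though the eye (and hence
the retinal image) jumps around.

Two variants share this architecture:

* **Delayed feedforward.** Pathway latencies are hard-coded: retinal input
  reaches the hidden sheet after a 70 ms afferent lag, CD after 10 ms, and
  the saccade follows the SC command by a 50 ms efferent delay. There is no
  recurrence, so the network is a (delayed) function of its inputs.
* **Recurrent.** No imposed input delays; the hidden sheet feeds back on
  itself with a one-step (10 ms) delay. Any useful timing — in particular,
  *when* to shift the FEF representation — must be discovered by learning.

Units are logistic: `sigmoid(gain * (W x) + offset)`. The recurrent feedback
term carries its own gain so that a high afferent gain does not let the
feedback loop swamp the input drive.

## Geometry

All input sheets share one geometry: 21 x 21 units spanning +/-50 degrees (5
deg per unit), encoding bump width sigma = 3 deg, with a unit exactly at
0 deg. Two constraints fix this choice. First, every training-grid location
(multiples of 10 deg out to +/-20 deg) must coincide with a unit center.
Second, the training sets pair +/-20 deg targets with 20 deg saccades, so
postsaccadic retinal eccentricities reach 40 deg; the sheet must contain
them with a margin of a few bump widths, or edge clipping biases decoded
centroids. The bump width is kept below the RF-to-FF midpoint distance
(10 deg for a 20 deg saccade) so that a static bump at the receptive field
contributes only ~0.004 of its peak at the midpoint unit — otherwise the
jump-vs-spread statistic would be contaminated by tails rather than measure
remapping dynamics.

Positions are treated with a planar small-angle approximation throughout
(`retinal = workspace - eye`, per component); over the +/-20 deg workspace
used here the approximation error is negligible relative to the 5 deg unit
spacing.

## The body-centered combiner

The BC stage must turn a retinotopic bump (FEF) and an eye-position bump
(EP) into a bump at their vector sum. A single additive map cannot do this:
the best least-squares additive approximation of `bump(r + e)` by
`f(r) + g(e)` decodes to `(r + e) / 2`. The operation is intrinsically
bilinear, and the canonical shift-invariant bilinear form is the 2-D
convolution of the two sheets: the convolution of a bump at `r` with a bump
at `e` is a (wider) bump whose centroid is exactly `r + e`. The BC stage is
therefore implemented as the full convolution of the FEF and EP sheets (on a
41 x 41 sheet spanning +/-100 deg) followed by a small 9 x 9 kernel, fit
once by ridge least squares so that the result matches the standard
unit-peak encoding bump at `r + e` over the +/-20 deg training region
(`pretrain_bc`). Pretraining verifies a decode error below half a unit
spacing on every training pair and the kernel is frozen thereafter; core
training never touches it. The stage is bilinear and therefore exactly
differentiable for backpropagation.

## Trials

A standard trial is 17 steps of 10 ms: 50 ms of fixation with the target at
its presaccadic retinal location; a 70 ms SC command window encoding the
saccade vector (the retinal image unchanged); then, 20 ms after saccade
onset (onset = command onset + efferent delay), the retinal input switches
discretely to the postsaccadic location for a final 50 ms. The EP input
switches exactly once, at a configurable delay referenced either to the SC
command or to saccade onset. The ball never moves in the workspace, so the
desired output — a bump at the ball's workspace location on the BC sheet —
is constant across the trial. Lengthening the efferent delay to 70 ms (the
delayed-saccade condition used for all recurrent-variant analyses) expands
the presaccadic window and the trial to 19 steps.

The eye movement itself is modeled as a discrete displacement; a constant
speed saccade profile (400 deg/s, so a 20 deg saccade spans 5 steps) is
available for event bookkeeping but the sheet inputs switch in one step, as
does the EP signal.

Training sets are the study conditions, not free parameters: the recurrent
set crosses 5 retinal locations (center and the four 20 deg cardinal
eccentricities) with the 4 cardinal 20 deg saccade vectors (20
combinations); the feedforward set is nominally the full 25-location x
25-vector cross. With one trial defined as one backpropagation pass over one
timeline, a few hundred trials cover less than one epoch of the 625-element
cross, so the feedforward presets train on the same 20 combinations that are
analyzed (the cross remains available via `feedforward_training_set`).

## Training

Learning is plain stochastic gradient descent on backpropagation-through-time
gradients, one trial per update, cycling through the training set in seeded
shuffled order. The loss is the squared mismatch between the BC activity
sheet and the encoded desired-output bump, summed over units and steps — a
differentiable surrogate for the decoded pointing error (backpropagating
through a center-of-mass decode is ill-conditioned when activity is low).
The decoded pointing error is always reported alongside as the behavioral
measure. When the BC stage is bypassed (the "FEF drives the arm" control),
the FEF sheet is compared with the desired bump directly.

Four classic devices keep this otherwise plain procedure healthy; all are
exposed as hyperparameters and default as follows:

* **Weight noise** (default 1e-5, uniform, zero-mean) added to every weight
  on every update, to avoid stagnation in local minima.
* **Flat-spot elimination** (default 0.05) on the FEF layer only: a constant
  added to the sigmoid derivative in the backward pass. Without it, the
  output sheet saturates hard at 0/1 during the early "veridical" phase of
  training and the CD-conditioned remapping association can never form —
  units that must eventually switch sides receive essentially zero gradient.
  The hidden-layer constant defaults to 0 because in the recurrent variant a
  nonzero hidden flat spot inflates the backward Jacobian product through
  time and explodes the gradient.
* **Hyperbolic learning-rate decay** `lr / (1 + trial / tau)`: a high
  initial rate gives fast early learning, the decay restores late stability.
* **Gradient-norm clipping** (default cap 100), a numerical safeguard for
  the recurrent variant.

Defaults per variant (chosen once, during development, so that remapping
emerges within a few hundred trials and training is stable across seeds):
feedforward — learning rate 0.35 decaying with tau = 100 trials, 400 trials;
recurrent — learning rate 0.2, tau = 300, 4000 trials (the EP-locked timing
must be discovered through the recurrence, which is slower than the
feedforward pattern association).  The packaged analyses use these problem
sizes throughout: 20-seed batches for training-dynamics statistics, 36-point
factor grids for lesion sweeps, and the 20-combination analyzed trial set
for every behavioral average.

Training stops at `max_trials` or when the update norm averaged over one
pass through the set falls below 1e-4 of the first pass's average.

### Sigmoid operating regime

The connection weights are initialized uniformly in [-0.1, 0.1]. An encoding
bump has total mass of only a few units, so its projection through such
weights has standard deviation ~0.07: with unit sigmoid gain and zero offset
every hidden unit sits at ~0.5 regardless of the input, the stimulus
modulates activity by a few percent of a dense baseline, and gradient
descent cannot disentangle the 20 training conditions in any usable number
of trials (we verified this regime fails at every learning rate tried). The
default operating regime is therefore *sparse and high-gain*: hidden gain 16
with offset -5, FEF gain 3 with offset -4, recurrent-feedback gain 6. Units
are nearly silent without input and only coincident afferent drive pushes
them through threshold, which (a) makes hidden codes for different
stimulus/saccade combinations nearly orthogonal, and (b) favors conjunctive
(visual x CD) hidden responses. The lesion module can sweep these
coefficients, and the lesion analyses are repeated under several settings.

## Measurements

* **RF / FF / midpoint units**: the FEF units whose centers sit at the
  presaccadic retinal target location, the postsaccadic location, and their
  sheet midpoint.
* **Presaccadic window**: the 5 steps (50 ms) before saccade onset; the
  presaccadic *snapshot* is 20 ms before onset.
* **Centroid distances**: distance of the raw (unthresholded) FEF activity
  centroid from the FF and RF locations at the snapshot; remapping has
  emerged when the centroid is closer to the FF than to the RF.
* **Remapping onset**: time, relative to saccade onset, at which FF-unit
  activity first exceeds half its final sustained level (mean of the last 3
  steps). Crossings are interpolated linearly when the trace is ramping; a
  jump out of silence is dated at the sample itself, since sheet activity
  holds between 10 ms updates.
* **Jump statistic**: max midpoint activity / max(RF peak, FF peak); < 0.1
  is scored as a "jump" (no traveling wave through intermediate locations).
* **Weight-magnitude ratio**: mean |SC->Hidden| over mean |Retina->Hidden|
  afferent weight, restricted to afferents from the trained input locations
  (the 5 retinal locations and 4 saccade vectors of the 20-combination set;
  the 5 x 5 grid subset of the full cross is available via
  `subset_points`). The sign mix of each pathway is reported with it.
* **Lesions** scale every weight of one pathway (CD = SC->Hidden, visual =
  Retina->Hidden) by a factor in [0, 1] at test time, on a copy of the
  trained weights, without retraining. The CD sweep reports mean FF-unit
  activity over the presaccadic window versus factor, and the factor
  producing a given fractional reduction is found by inverse linear
  interpolation. The visual sweep reports full RF/FF traces and the
  RF-to-FF crossover time; the crossover is reported as undefined when the
  lesioned final FF level falls below 10% of the intact level.

## What the generator does and does not emulate

The trial generator produces exactly the study conditions: one persistent
punctate stimulus, discrete input switches, noiseless bumps, a fixed event
schedule, and the stated training grids. It does not emulate photoreceptor
or motor noise, stimulus features (color/shape), smooth saccadic image
motion, variable saccade metrics, flashed or moving stimuli, or double-step
tasks. Results therefore speak to the model class — what gradient training
of a sheet hierarchy on the pointing objective produces — not to
quantitative properties of biological FEF tissue.

## Numerical choices and degenerate inputs

* Decoding a silent sheet (total activity under 1% of a reference bump's
  mass) returns a distinct no-signal sentinel, never (0, 0); pointing error
  is undefined (NaN) at such steps and excluded from means.
* Centroid *trajectories* are computed without this floor (the raw spatial
  average), matching how remapping trajectories are usually plotted.
* The feedforward variant's delay buffers are primed with the first input
  frame: the visual probe is persistent, so the pre-trial input is taken to
  equal the first frame.
* The BC convolutions use FFTs; gradient checks against central finite
  differences pass at 1e-4 relative error on a 5 x 5-sheet toy network.
* Ties in `nearest_unit` round half-up through `round`; training-grid
  points sit exactly on unit centers so no analysis quantity depends on the
  tie rule.

## Known limitations

* **Late-trial ambiguity (feedforward variant).** With a 70 ms afferent lag
  and a 17-step trial, the hidden sheet sees identical inputs early in the
  trial (target = presaccadic location) and late in the trial (target =
  postsaccadic location). A memoryless network must compromise, so trained
  feedforward models retain a residual post-saccadic pointing error until
  the postsaccadic afference arrives; presaccadic remapping measures are
  unaffected. The recurrent variant does not have this ambiguity.
* **Modulator vs. driver degeneracy.** The training set never shows CD
  without a visual stimulus, so two solution families fit it equally well:
  weak-CD solutions in which CD only modulates visually driven activity
  (FEF silent in the no-stimulus probe), and strong-CD solutions in which
  CD-alone drive at future-field units is masked, during training, by
  learned visual suppression. Gradient descent usually finds the second
  family, so the trained models here often fail the no-stimulus control even
  though they remap correctly; the control and the CD:visual
  weight-magnitude ratio are reported per seed rather than assumed.
* **Lesion-curve margins.** Training continues to deepen the CD drive past
  the point where remapping first succeeds, so trained models tolerate
  moderate CD scaling before remapping degrades; the steep portion of the
  CD-lesion curve sits at smaller factors than it would in a just-barely
  converged network. The curve's qualitative shape — flat, then a
  disproportionate collapse, with timing delayed before amplitude vanishes —
  is robust across the sigmoid settings swept.
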