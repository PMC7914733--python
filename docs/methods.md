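# Methods

This note documents the models, algorithms and numerical choices behind
`gaitfloor`: a pipeline that turns the event-based message stream of a
capacitive sensor floor into walker-local activation sequences and learns
walking-mode classifiers and heel-rise regressors from them, together with
the synthetic gait simulator used to validate every stage.

## Sensor model and state reconstruction

The floor is a grid of square modules (edge `l_M`, 0.38 m for the
gait-resolution type), each carrying eight triangular sensor fields obtained
by cutting the square along its diagonals and mid-lines. Every triangle is
right-angled with legs `l_M/2`, so its centroid lies at offsets
`(±2/3, ±1/3)·(l_M/2)` or `(±1/3, ±2/3)·(l_M/2)` from the module centre.
Field slots 1–8 enumerate the quadrants counter-clockwise from (+x, +y),
x-major triangle first; the hardware fixes no order, and any fixed
convention works because the learning stage uses a fixed field-to-input
association.

Modules sample capacitance at 10 Hz but report *event-based*: a module emits
a message (timestamp, module id, all eight current values in [0, 1]) only
when at least one field changed beyond an internal threshold since its last
emission. The receiver therefore maintains a **sensor state** — one entry
per field holding its centroid position, last measurement time and
capacitance — initialised to all zeros and updated by replacing the eight
entries of each arriving message's module. This fold is a discrete-time
dynamical system whose only input is the message stream; `replay` returns
one snapshot per message and is tested bit-exactly against a quadratic
from-scratch rebuild. Out-of-order messages are rejected rather than
re-sorted: the stream is assumed ordered, and radio reordering is out of
scope. Ties in time across modules commute because modules are disjoint.

## Walker-local transformation

Gait is translation- and rotation-invariant, so each snapshot is mapped into
the walker's frame:

1. **Sparsify** — keep fields with capacitance strictly above `c_threshold`
   (default 0.03, i.e. 3 % of the measuring range, suppressing sensor
   fluctuations).
2. **Track** — the walker position is the capacitance-weighted mean of
   active field centroids (centre of mass of a particle system). An empty
   sparse state carries the last position forward and contributes a zero
   vector; states before the first fix are dropped. This single-person
   tracker is intentionally minimal; multi-person separation is out of
   scope.
3. **Walking angle** — from the first to the last tracked position of a
   walk. We define θ as the *signed* angle (two-argument arctangent,
   `θ = atan2(d_x, d_y)`) whose rotation matrix maps the unit direction onto
   (0, 1); its magnitude equals the unsigned arccos formulation, and the
   sign convention is pinned by a property test.
4. **Localise** — translate to the tracked position, rotate by θ, drop
   entries at distance ≥ `r_s`.
5. **Resample** — each entry assigns its capacitance to the nearest point of
   the square lattice `{(i·l_s, j·l_s) : |p| < r_s}`. Exact distance ties go
   to the lower-x (then lower-y) point; when several entries hit one point
   the maximum survives (preserving the strongest activation; the
   alternatives — sum or mean — would manufacture values no sensor
   reported). With a lattice fine enough that no two entries collide, the
   multiset of nonzero grid values equals the multiset of entry
   capacitances (tested).
6. **Unroll** — grid values are flattened in a fixed meander: rows from the
   most negative y upward, alternating x direction. The order is arbitrary
   but must be fixed; it is versioned (`GRID_ORDERING_VERSION`).

`l_s` and `r_s` are free parameters. Defaults: `l_s = 0.10 m`, below the
~0.13 m centroid spacing of the gait-resolution module so distinct fields
rarely collide on one lattice point, and `r_s = 1.0 m`, covering the current
double support plus the adjacent footfalls at an ordinary ~0.7 m step
length. The resulting vector has 305 entries. Rigid motions of the global
frame change the preprocessed vectors only within one-cell quantisation
(bit-exactly for pure translations), which is asserted in the test suite.

## Segmentation, windows and cross-validation

A recording is one out-and-back pass. The trajectory is split at the turning
point — the state farthest from the start along the dominant axis — and all
states within `trim_radius` (default 0.5 m, our choice; turning gait is not
straight walking) of the turn are discarded before windowing. A trajectory
whose return leg is shorter than `trim_radius` counts as a single pass and
is kept whole. Each directed walk gets its own walking angle.

Windows are 30 *consecutive event-driven vectors* (one vector per received
message — not 30 footsteps, not fixed-rate ticks), moved in increments of
one step; a series of `n` vectors yields `n − 29` windows and shorter walks
are dropped and counted. Two leave-one-out designs are built
deterministically: *idiosyncratic* (all walks of one participant, two
classes; test = one walk, validation = the next walk in a fixed rotation)
and *generalised* (test = all walks of one participant, validation = the
next participant). All windows of a walk stay in one set, so no window can
leak between train, validation and test; folds are pure index sets and are
asserted disjoint.

## Network and training

The sequence model is one LSTM layer (output 20, final step forwarded),
four dense ReLU layers of 20 units, and a head of two softmax units
(binary cross-entropy) or one ReLU unit (mean squared error). It is
implemented directly in numpy — forward pass, backpropagation through time
and mini-batch Adam — because the package has no deep-learning framework
dependency; at ~30 k parameters the dominant cost is a single BLAS matrix
product per batch, and the backward pass is pinned to the forward pass by a
finite-difference gradient check. Optimiser settings the protocol leaves
open: Adam, learning rate 1e-3, batch 32 (configurable and logged). The
forget-gate bias starts at 1; for regression the output bias starts at the
training-target mean, since a ReLU output unit initialised near zero can die
before receiving any gradient. Early stopping: any strict improvement of
the validation loss resets a patience of 12 epochs (60 epochs maximum);
the weights of the best validation epoch are restored. Training is exactly
repeatable given a seed; experiment repeats draw fresh seeds and log them.

For regression, the experiment runner can train a small ensemble of
independently seeded networks per fold and average their predictions
(`n_model_seeds`); single-seed runs of a ~30 k-parameter network carry
substantial run-to-run variance, and averaging damps it for the same reason
the recording protocol repeats runs with fresh seeds. The recovery
experiments use three members.

Window-level metrics (accuracy, precision, recall, F1 with the interference
mode positive; RMSE and Pearson r for regression) are the primary report;
walk-level majority-vote metrics are reported separately. Ratios with zero
denominators are reported as not-available and excluded from aggregates
with a count, never silently as zero.

## Synthetic cohort generator

The generator emulates the recording protocol — straight out-and-back walks,
five repetitions per participant and mode — with enough statistical
structure to exercise every stage:

* **Gait**: alternating footfalls along the walking axis; step length
  0.70 m (SD 0.02 within-walk), step width 0.10 m (placement SD 0.015),
  speed 1.25 m/s, step-time CV 0.04, double support 0.10 of the stride,
  values typical of young healthy adults. Stance time is
  `(0.5 + double_support) · stride`; a stance-asymmetry knob shifts
  left/right stance in opposite directions.
* **Foot-to-field coupling**: the foot is a 0.26 m × 0.10 m ellipse; a
  field reads `gain · overlap/field_area` (gain 0.9, clipped to [0, 1]),
  with overlap estimated by deterministic sub-sampling of the ellipse and
  verified against a dense Monte-Carlo oracle. Both feet on one field
  accumulate before clipping. Contact builds up and releases over a 0.15 s
  load ramp, so a footfall produces a handful of messages, not two.
* **Noise**: a per-field Ornstein–Uhlenbeck baseline fluctuation with
  stationary SD 0.01 and 5 s correlation time. Idle capacitive channels
  drift slowly; modelling the noise as white at 10 Hz would flood the
  event-based emission (tick-to-tick deltas of 1.4 % against a 2 %
  threshold) and turn the stream into a fixed-rate one, which contradicts
  the device's design premise.
* **Emission**: threshold 0.02, deliberately below the 0.03 analysis
  threshold so a step can never be silently invisible to the tracker.
  Replaying the emitted stream reconstructs the sampled series within the
  threshold at every tick (tested on every generated fixture).
* **Participants**: latent baseline gait drawn from population
  distributions, plus a latent strength ~N(0,1) that sets the unilateral
  heel-rise capacity (right leg mean 25.7, SD 7.8; left 24.3, SD 7.9;
  counts clipped to 10–45, the cohort statistics the protocol reports).
  `uhr_gait_coupling` optionally shifts step length by 0.08 m per SD of
  strength; its default is **0** because the emulated study itself observed
  no gait–UHR correlation — the coupling is a knob for parameter-recovery
  experiments, not a claim about people.
* **Modes**: multiplicative perturbations of the baseline. Defaults are
  qualitative (closed eyes: speed ×0.85, width SD ×2, timing CV ×2;
  dual-task: CV ×1.5; post heel-rise: +10 % stance asymmetry). The
  `strongly_separated_modes` library used by the recovery experiments makes
  closed eyes far more distinct (speed ×0.7, step length ×0.75, width ×2,
  width SD ×3, CV ×3, double support ×1.4) and deliberately loads on
  spatial cues the 0.10 m grid resolves.

What the simulator does *not* model: foot roll-over and pressure
distribution (capacitive floors do not measure force), radio transport and
packet loss, multiple people, and any physiological claim about why a mode
changes gait. Passing recovery tests therefore show that the pipeline
extracts spatial gait structure it is pointed at — not that real closed-eyes
walking is detectable at any particular accuracy.

## Problem sizes and numerical choices

Recovery experiments run at desk scale: a 16 × 4-module corridor
(1.52 m × 6.08 m), 12 participants × 5 repetitions × 2 modes for
classification (leave-one-participant-out, three seeded runs) and 24
participants of normal-pace walks for regression (folds of 6 held-out
participants), windows strided by 3 and training capped at 30 epochs with
patience 8, batch 64, learning rate 2e-3, float32. These sizes are the
package's validation conditions; the library defaults (stride 1, patience
12, 60 epochs) match the emulated protocol. Degenerate inputs have defined
behaviour throughout: empty layouts and empty sparse states are legal,
walks without net displacement raise a degenerate-walk error, windows
shorter than 30 yield nothing, and undefined metrics surface as
not-available.

## Known limitations

* The tracker is the capacitance centroid of the whole floor: a second
  person, or strong correlated noise, corrupts the trajectory.
* The walking angle is a single walk-level constant; curved paths are
  outside the model.
* Nearest-point resampling discretises field positions to `l_s`; sub-cell
  cues (e.g. small step-width changes) are partially quantised away.
* The numpy network trains on one CPU core; it is sized for this problem,
  not a general-purpose deep-learning stack.
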