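# Methods

This note documents the model behind `gaitid`, the numerical choices, the
synthetic-data generator, and what the package's tests do and do not show
about real recordings.

## Problem and assumptions

Each body-worn IMU reports 3D specific force `s(t)` (accelerometer) and 3D
angular velocity `ω(t)` (gyroscope) in its own, arbitrarily mounted sensor
frame, sampled at a common rate (default 120 Hz).  The task is to map
sensors to body segments from a short recording that starts with quiet
standing (≥ 1 s) followed by at least one — by design three — straight-line
walking cycles at a natural speed.  Assumptions: the subject is actually
walking (activity recognition is out of scope), walks roughly straight, and
moves the arms (a subject with no arm swing loses the arm left/right
signal — see *Limitations*); no magnetometer is used.

## Preprocessing

**Inclination.**  The mean specific force over the static interval is pure
gravity; the shortest-arc rotation taking it to `(0,0,+9.81)` levels the
sensor.  Yaw remains unobservable at this point.  A magnitude outside
`[0.5 g, 1.5 g]` is rejected as "not static".

**Strapdown integration.**  `dR/dt = R·[ω]×` is integrated with per-step
rotations `R_{k+1} = R_k · exp([ω_mid]× Δt)` (midpoint rate).  This is exact
for piecewise-constant rates and keeps `R` orthonormal by construction; the
implementation composes unit quaternions with a parallel prefix scan
(re-normalized every pass), so a trial costs O(log n) vectorized passes.
Tests verify agreement with the matrix-exponential closed form to 1e-6 for
constant rates and orthonormality to 1e-9 throughout random rate series.

**Gravity removal and velocity.**  `a(t) = R(t)·s(t) + (0,0,−9.81)` m/s²;
velocity is the trapezoidal integral of `a`, zeroed at the end of the static
interval (the last instant the sensor is known to be at rest).  Integration
drift is left uncorrected beyond that anchor; its effect on the heading is
bounded below.

**Heading.**  Every sensor translates with the body, so the mean of *its
own* velocity over the first detected walking cycle points along the walking
direction in its own leveled frame.  The signed angle `θ = atan2(v̄_y, v̄_x)`
yields the yaw correction applied to that sensor (the unsigned inner-product
form gives `|θ|`; the sign is required to distinguish leftward from
rightward).  Per-sensor heading is the default because an arbitrary mounting
yaw makes the leveled frames of different sensors differ by unknown yaws
that a single common angle cannot remove; a circular-median common heading
is available as `heading_mode="median"` for well-aligned mountings.  With a
bias-free accelerometer the residual frame error is numerical (< 0.1° in
tests); a constant bias `b` corrupts velocity by at most `‖b‖·t`, i.e.
0.06 m/s after 3 s at the typical bias stability 0.02 m/s², bounding the
heading error near `atan(0.06/1.4) ≈ 2.5°` even without the rest anchor.

**Angular acceleration** is `np.gradient` of the global-frame `ω` (central
differences, one-sided at the ends).  For a 1 Hz sinusoid at 120 Hz the
exact central-difference error is `2π(1−sinc(2π/120)) = 2.9e−3` rad/s², the
`h²/6·‖ω‴‖` Taylor bound.

**Walking-cycle detection.**  Candidate peaks of the across-sensor summary
`Σᵢ(‖aᵢ‖+‖ωᵢ‖)` are found with a 0.4 s minimum spacing; accepted peaks must
have prominence ≥ 0.5× the *median prominence of the candidate peaks*.  The
median-prominence scale is used instead of a signal percentile because the
gait-initiation transient — a single whole-body forward-acceleration spike —
otherwise inflates a percentile-based scale in short trials and suppresses
genuine step peaks.  For the same reason, leading peaks whose following gap
exceeds 1.5× the median inter-peak interval are discarded as initiation
transients.  One peak corresponds to one step; a stride spans two steps, so
every second accepted peak is a cycle boundary.  Both thresholds are exposed
as parameters.

## Features

Per sensor and per signal (`a`, `ω`, `α`), over the window spanning the
first `n_cycles_used` (default 3, allowed 1–3) detected cycles: RMS and
variance of the magnitude and of the x/y/z components (8), row sum and row
maximum of the cross-sensor Pearson correlation matrix for each of the four
components with the diagonal excluded (8), and the three inter-axis
correlations (3) — 19 × 3 signals = 57 features.  All four RMS components
are included; the symmetric 19-per-signal layout is what yields the
57-feature total.

Transforms (per trial, per feature column): **rank** — ascending fractional
ranks, ties averaged (ranks sum to `n(n+1)/2`; invariant to any common
monotone rescaling, which is the point: it removes between-subject and
between-speed variability); **normalize** — z-scores (zero-variance columns
map to 0); **raw** — untouched values with the cross-sensor families
dropped, for the configuration-unknown case.  Undefined correlations
(zero-variance series) are set to 0 with a warning so trees always receive
numbers.

## Classification

**Step 1 — segment class.**  A decision tree grown on the ranked features:
binary numeric splits at midpoints between sorted distinct values, chosen by
maximum information gain (entropy in bits, `0·log 0 = 0`); growth stops on
purity, fewer than 4 instances, or no positive gain; pruning is pessimistic
error-based subtree replacement with confidence factor 0.25 and ≥ 2
instances per leaf (the documented defaults of the common open
implementation).  Gain, not gain ratio, is the criterion, matching the
described method; the MDL numeric-attribute correction and subtree raising
of that implementation are omitted as they change none of the small-tree
behaviour tested here.  Ties between equal-gain splits go to the lowest
feature index, then the smallest threshold; rows at a threshold route to the
`≤` branch — induction and prediction are fully deterministic.  Stratified
10-fold cross-validation with a pooled confusion matrix is provided
(`treeclass.cross_validate`), falling back to unstratified folds with a
warning when a class has fewer instances than folds.

Predicted classes must match the configuration's multiplicities (e.g. one
pelvis, two feet).  Violations are repaired by maximizing the summed leaf
class frequencies under the capacity constraints (an assignment problem
solved exactly), and always flagged — detection rather than silent failure.

**Step 2 — left/right of upper arms and upper legs.**  Trunk roll is
obtained by trapezoidal integration of the pelvis (for legs) or sternum (for
arms) global-frame angular velocity plus linear detrending — full strapdown
integration is unnecessary because trunk orientation excursions during
walking are small.  The candidate whose vertical acceleration correlates
more with the trunk roll angle is the right one.  A trained alternative
(`step2="tree"`: a tree over the 45 pair-ranked limb-vs-trunk correlations —
5 limb signal types × 3 axes × 3 trunk axes) is available; the fixed
published rule is the default since it needs no data.  Correlation
differences below 1e−6 are flagged as ambiguous.

**Step 3 — remaining left/right.**  Processing order shoulders → forearms →
hands → lower legs → feet guarantees each reference pair is already
resolved.  Components: shoulders↔upper arms `a_z`, forearms↔upper arms
`a_x`, hands↔forearms `a_y`, lower legs↔upper legs `a_x`, feet↔lower legs
`a_x`.  The two candidates are matched to the two resolved neighbours by the
pairing with the larger total correlation, which enforces a bijection by
construction; near-ties are flagged.

## Synthetic data generator

`gaitid.gaitsim` emulates the measurement conditions: a 3 s static prefix, a
0.25 s gait-initiation ramp, then `n_cycles` (+ margin) strides at 1.39 m/s
(≈ 5 km/h) with a 1.1 s stride period, 120 Hz sampling, white accelerometer
noise (default σ = 0.02 m/s²), gyroscope noise (σ = 0.01 rad/s), optional
constant accelerometer bias, and fully random 3D mounting rotations (a
"well-mounted" ±10° mode exists).  Defaults are typical values for normal
adult gait and consumer IMUs.

Rather than simulating a musculoskeletal chain, each segment gets an
analytic kinematic signal model chosen to reproduce the *structure* the
method exploits:

* per-segment oscillatory velocity waveforms (differentiated analytically to
  accelerations, so the first-cycle mean velocity equals the walking
  velocity exactly) at the stride frequency — left/right limbs in
  anti-phase, arms in anti-phase with ipsilateral legs — and at the step
  frequency with a phase common to all segments;
* acceleration amplitude tiers strictly ordered foot > lower leg > upper
  leg > (all non-leg segments), so the six largest RMS acceleration
  magnitudes are always the legs — the premise of the first tree split —
  with a second, differently-ordered tier structure on angular rate;
* rotation about a fixed per-segment axis with closed-form orientation
  (gyroscope and specific-force projections are exact, no numerical
  simulation error), with pelvis and sternum roll phase-locked to the
  right-leg and right-arm vertical accelerations respectively — the sign
  convention that makes "largest trunk-roll correlation → right" true;
* same-side phase sharing on every acceleration axis, making same-side
  adjacent-segment correlations exceed opposite-side ones on the step-3
  components.

Sensor IDs are randomly permuted so file order never leaks identity.  The
corpus generator jitters walking speed and stride period (±10%), per-sensor
amplitudes (±3%), heading, mounting and noise seeds per trial.  Setting
`arm_swing_amplitude = 0` removes the stride-frequency arm signature while
keeping the transmitted step-frequency bounce, reproducing the
no-arm-movement failure mode.

**What passing tests therefore show — and what they do not.**  The tests
demonstrate that the pipeline recovers the gait frame from arbitrary
mounting, that each classification step's decision statistic separates the
classes whenever its ordinal/phase premise holds, and that the whole chain
is deterministic and robust to the modelled noise, bias and heading
perturbations.  They cannot certify performance on real gait, where
amplitude tiers overlap across subjects (sternum vs shoulder is the likeliest
confusion, their motion amplitudes being closest), soft tissue and footwear
add structured noise, and pathology alters phase relations.  The simulator's world heading
is deliberately reported as metadata only: yaw-rotating the world changes
neither gravity nor the body-frame rates, so absolute heading is
unobservable from IMU data and frame recovery is measured as the residual
planar (orthogonal-Procrustes) rotation between recovered and constructed
gait-frame signals.

## Numerical choices and degenerate inputs

* Tolerances: rotation orthonormality 1e−9; correlation tie flag 1e−6;
  gain comparisons 1e−12; serialization round-trip 1e−9 (trial CSVs are
  written with 17 significant digits, i.e. exactly).
* Ranking direction is ascending (rank 1 = smallest); trees are invariant
  to the choice as long as training and testing agree.
* Degenerate cases: single-class training data yields a single leaf;
  contradictory duplicate instances a majority leaf (ties to the lowest
  class index); zero-variance features produce zero gain and are never
  split on; an empty summary or flat signal raises "no gait detected".
* Problem sizes in the shipped experiments (31 + 31 trials per
  configuration, 200 oracle tables, 5-trial heading sweeps, 12 + 12 trial
  cycle sweep) were chosen to exercise the full study design at a few tens
  of seconds of runtime.

## Limitations

* Missing feature values are an error: no fractional instance weighting,
  no multi-way splits, no rule post-processing.
* The configuration must be known for ranked/normalized features; the raw
  mode exists but is expected to be substantially less reliable, and the
  package reports that expectation when it is selected.
* Walking must be present and roughly straight; turning, stairs and other
  activities are out of scope, as are real-data artifacts listed above.
* Greedy gain-based induction cannot see pure feature interactions
  (balanced XOR has zero gain for every single split and yields a leaf);
  this is inherent to the algorithm family, not a defect of the
  implementation.
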