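# Methods

## Problem and model

The package estimates 12 lower-limb joint-angle channels (hip
flexion/adduction/rotation, knee flexion, ankle dorsiflexion/inversion, both
sides, in degrees) from the fused orientations of seven body-worn inertial
sensors (pelvis, thighs, shanks, feet) sampled at 60 Hz.

All orientations are handled as world-to-segment direction-cosine matrices.
For a joint with parent (proximal) sensor A and child (distal) sensor B the
kinematic identity

    R_joint = R_A R_Bᵀ

would give the joint rotation exactly if sensors coincided with anatomical
segment frames. They do not: sensors are strapped on with unknown static
mounting rotations, and skin-mounted sensors move relative to the bone
(soft-tissue artifact). The model therefore wraps the identity with learned
corrections, per joint:

    R_joint = R_pre · ΔR_pre · R_A R_Bᵀ · ΔR_post · R_post
    R_pre   = Exp(MLP_pre(Log R_A)),   R_post = Exp(MLP_post(Log R_B))

* **ΔR_pre, ΔR_post** — static sensor-to-segment calibrations, parameterised
  as rotation vectors through the SO(3) exponential map, so every iterate is
  a valid rotation with no projection step.
* **MLP_pre, MLP_post** — two independent 3→32→3 ReLU networks per joint
  (227 scalars each) predicting instantaneous rotation-vector offsets from
  the log-map of the corresponding sensor orientation; these absorb
  orientation-correlated non-rigid effects. Two independent MLPs per joint
  (rather than one shared) is what yields the model's 2,760-parameter /
  10.8 KiB footprint: 6 joints × (2×227 + 2×3) scalars.

`R_joint` is factored into intrinsic Z-Y-X Euler angles (the body-fixed
convention of standard musculoskeletal tooling), R = Rz(z)Ry(y)Rx(x). The
hips supervise (z, y, x) = (flexion, adduction, rotation); the knees z only
(flexion); the ankles (z, y) = (dorsiflexion, inversion). The six remaining
Euler channels are left free — nothing in the loss regularises them.

Initialisation encodes the physics prior: calibration vectors start at zero
and MLP weights at SD 1e-2 Gaussian (biases zero), so a fresh model is a
near-exact `R_A R_Bᵀ` solver and training only has to learn corrections.

## Loss

Training minimises a motion-range-weighted, angle-wrapped L1 loss in degrees:

    L = mean over frames of Σ_{j=1..12} w_j · |wrap(pred_j − target_j)|

with wrap() mapping differences to (−180°, 180°]. Weights are inverse
peak-to-peak motion ranges, normalised to sum to 12, so small-excursion
channels (hip rotation, ankle inversion) are not drowned out by knee
flexion. The default ranges are the simulator's channel ranges (below).
Working in degrees keeps loss values commensurate with reported RMSEs.
Averaging is per frame; the 12-channel sum is not re-normalised.

## Differentiation and optimisation

No deep-learning framework is used: the models are small enough that a
compact reverse-mode autodiff engine over numpy (`orientnn.autodiff`)
suffices. It provides the usual tensor primitives plus two domain-specific
ones with hand-derived Jacobians — the Rodrigues exponential (smooth through
the identity via Taylor-expanded coefficients, with the a′/θ and b′/θ factors
expanded likewise) and the SO(3) logarithm on its smooth branch (trace
clamped to angle ≤ π − ~1e-3; segment orientations during gait stay far from
that branch). Both are verified against central finite differences in the
test suite at 1e-6 relative tolerance, as is the end-to-end loss gradient
for every parameter group.

Optimisation is Adam (β = 0.9/0.999, ε = 1e-8) at learning rate 0.005 for
100 epochs, minibatch 256 frames, final-epoch parameters reported (no early
stopping; the validation block is reserved for protocol-level choices). The
baselines use their own learning rates (0.01 except the transformer's 0.005)
and coupled L2 weight decay 1e-4; the physics-informed model uses none.
All randomness (init, shuffling, dropout) flows from a single integer seed.

## Evaluation protocol

Intra-subject: one continuous recording is split chronologically
60 / 20 / 20 into train / validation / test, sizes ⌊0.6T⌋ / ⌊0.2T⌋ /
remainder. A chronological (not random) split prevents leakage between
autocorrelated neighbouring frames. Accuracy is per-channel wrapped RMSE in
degrees, with 5° as the clinical-reliability bound; phase-wise behaviour is
summarised as mean absolute error in 100 gait-phase bins (heel strike at
phase 0 by construction; empty bins are reported missing, not zero).
Repeated-instance model comparisons (10 independently seeded trainings per
model) use a pooled-variance two-tailed t-test, df = n_a + n_b − 2.

Efficiency is reported as the exact trainable-scalar census, the float32
payload (count × 4 / 1024 KiB, one decimal; 20 KB is the microcontroller
deployment budget), and a per-frame FLOP census under an explicit
convention: by default 2 FLOPs per multiply-accumulate of the learned
linear maps, biases and elementwise nonlinearities excluded. For the
physics-informed model the fixed rotation-algebra cost (per joint: five 3×3
products, two exp and two log maps, one Euler extraction) can be included
separately; FLOP totals are convention-dependent and should be read as
orders of magnitude.

## Synthetic gait generator

The generator emulates the structure of treadmill walking recorded by a
7-sensor lower-limb IMU set, so the whole pipeline is testable without any
recorded data:

* **Trajectories.** Each right-side channel is a truncated 3-harmonic
  Fourier series in gait phase (cadence 0.9 strides/s), seeded, rescaled to
  an exact peak-to-peak range; defaults (hip flex 45°, hip add 12°, hip rot
  12°, knee flex 65°, ankle dorsi 25°, ankle inv 12°) are representative
  walking ranges. Left channels are the right patterns shifted half a cycle.
  Trials default to 420 s at 60 Hz = 25,200 frames.
* **Chain.** Pelvis carries a small (2°) seeded sinusoidal sway; thigh,
  shank and foot are placed by composing the joint rotations
  (knee flexion-only; ankle dorsiflexion + inversion, third angle zero).
  By construction the relative rotation of adjacent segments inverts the
  generator exactly (< 1e-6° round trip).
* **Corruption.** Per sensor: a static mounting offset (uniform axis,
  magnitude uniform in [0°, 15°]) composed on the sensor side, making the
  analytic optimum of the static calibration ΔR_pre = O_parentᵀ,
  ΔR_post = O_child; soft-tissue artifact as per-axis Gaussian
  rotation-vector noise low-pass filtered at 2 Hz (separating it from the
  ~1 Hz gait fundamental) scaled to a ~3° mean perturbation; and white
  orientation noise (0.5° per axis). All corruption is composed
  multiplicatively through the exponential map, so emitted matrices are
  exactly orthonormal — no reprojection is ever needed.

What the generator does **not** emulate: raw gyro/accelerometer signals and
their fusion errors (drift, magnetic disturbance), stride-to-stride
variability of a human walker beyond the harmonic model,
orientation-correlated (rather than independent filtered-noise) soft tissue
motion, treadmill-speed dynamics, and pathological gait. Passing the
synthetic criteria therefore demonstrates that the architecture can identify
static calibrations and remain accurate under realistic corruption
magnitudes — not that it attains any particular accuracy on recorded human
data.

## Identifiability of the static calibration

Calibration-recovery experiments freeze the dynamic MLPs at zero and train
only (ΔR_pre, ΔR_post) on an offsets-only trial. Writing U = ΔR_pre·O_A and
V = O_Bᵀ·ΔR_post, zero loss requires the supervised Euler channels of
U·M(t)·V to equal those of M(t) for every achieved joint rotation M(t):

* **Hip** (three supervised channels, three-axis motion): forces U = V = I —
  the calibration is fully identifiable, and recovery lands well under 2°.
* **Knee** (one channel, pure-z motion): the exact solution set is the
  three-parameter family U = Rz(−β), V = Rz(β)Ry(γ)Rx(δ).
* **Ankle** (two channels): a one-parameter family V → V·Rx(δ).

Recovery error is therefore reported as geodesic distance *modulo* each
joint's gauge group (minimised numerically; the hip comparison is raw).
Beyond the exact gauge there is a *near*-null thickening: a tilt μ of the
knee's hinge axis perturbs the supervised channel only at second order,
ε ≈ μ²⟨α²⟩/2 over the achieved flexion range α — so with ±32° of knee
motion, tilts of 2–4° produce supervised errors below the optimiser's
~0.05° noise floor at fixed learning rate 0.005 and are left uncorrected,
at any epoch count we examined. Gauge-aligned static recovery below 2° is
consequently achievable for the hips but not, structurally, for the hinge
knee (and marginally for the ankle) under this protocol; the corresponding
acceptance test states the 2° bound for all joints and is expected to fail
on the reduced-DoF joints, with this analysis as the explanation. The
supervised kinematics themselves are unaffected: test RMSE on offsets-only
trials converges below 0.1° per channel.

## Numerical choices

* Rodrigues/log-map coefficients switch to second-order Taylor expansions
  below 1e-4 rad; the canonical log has a dedicated branch within 1e-6 of π
  (axis from the dominant diagonal of (R+I)/2).
* Euler extraction at gimbal lock (|cos y| < 1e-7) returns the x = 0
  representative with a flag instead of raising, keeping losses finite.
* Rotation-matrix validation uses 1e-9 (invariants) and 1e-6 (input
  rejection) Frobenius tolerances; geodesic distances clamp the trace
  argument into [−1, 1], which limits distinguishable angles near zero to
  ~1e-6 degrees (arccos conditioning).
* Quaternions are Hamilton scalar-first, canonicalised to w ≥ 0; conversion
  from matrices uses Shepperd's branching for conditioning.
* The t-test handles zero pooled variance explicitly (t = 0, p = 1 for
  identical constant groups; p = 0 for distinct constants).
* Huber delta is 1.0 (degree scale).

## Problem sizes used by the shipped experiments

The acceptance experiments train on full-scale trials (25,200 frames,
100 epochs). Unit and property tests use 5–120 s trials and few-epoch
smoke trainings so the whole suite stays interactive. The baselines'
trainability is smoke-tested at small scale; their published-scale accuracy
ordering is not re-estimated (frame-wise operation at these sizes is an
architecture choice documented above, and their role here is interface and
census parity).

## Known limitations

* The SO(3) log's differentiable branch degrades within ~1e-3 of angle π;
  irrelevant for gait orientations but a caveat for reuse on arbitrary data.
* Frame-wise baselines (singleton LSTM time axis, sensors-as-tokens
  transformer) cannot exploit temporal context; the recurrent weights of
  the LSTM are counted but idle at sequence length 1.
* Loss weights derive from configured motion ranges, not estimated from the
  training block.
* The gauge-aware recovery metric needs the true offsets, so it applies only
  to synthetic trials.
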