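# Methods

## Problem

`gaitphase` estimates the continuous *gait phase* of each leg — a variable
in [0, 1) that is 0 at heel strike and increases linearly to 1 at the next
ipsilateral heel strike — in real time, from four inertial measurement
units (IMUs) strapped to the thighs and shanks. Continuous phase is the
synchronization variable used by assist-as-needed exoskeleton controllers:
a controller that tracks the user's phase can time its assistance to the
user's own gait instead of imposing a fixed trajectory. The estimator must
generalize across individuals and across gait conditions (speed changes,
asymmetric stepping, stop-and-go), which is why it is trained and evaluated
with one-subject-out and one-condition-out cross-validation.

## Phase labels

Ground-truth labels come from a heel-marker trajectory: heel strikes are
samples where the heel height is a local minimum *and* the vertical heel
acceleration (smoothed second difference of the height; there is no
accelerometer on the heel) peaks within ±50 ms. Between consecutive strikes
the phase ramps linearly from 0 to 1. Two rules guard degenerate cases:

* gaps longer than 3 s mean the subject was standing; the phase there is
  undefined and the samples are masked invalid;
* samples before the first and after the last strike are likewise invalid
  (the ramp is undefined there; the boundary rule is ours).

The sawtooth is discontinuous at the stride boundary, so regression targets
use the sinusoidal encoding (cos 2πφ, sin 2πφ) per leg — four outputs
total. Decoding is `atan2(y2, y1)/2π` mapped into [0, 1); it is invariant
to positive rescaling of the pair, so no unit-norm constraint is imposed on
the network output.

Detection parameters (5-point smoothing, minimum prominence 2% of the
signal range, 0.2 s merge floor) are our defaults, exposed as keyword
arguments; the source procedure states the criterion but not its constants.

## Sensor-to-segment calibration and input features

IMUs are mounted arbitrarily; a functional calibration aligns each sensor
frame with an anatomical segment frame (x = flexion axis, z = longitudinal
axis pointing proximally, y = z × x). From a prescribed flexion–extension
trial, the flexion axis is the principal direction of the angular-velocity
cloud, restricted to samples above the 75th-percentile rate magnitude so
rest periods do not dilute it. Its sign is fixed by the convention that the
trial *begins with flexion*; the longitudinal axis comes from the mean
accelerometer direction during a still period (opposite gravity). The two
directions must be at least 10° apart, else the geometry is degenerate and
calibration fails loudly.

Pitch is computed heading-free: world-up is expressed in the segment frame
and pitch = atan2(u_y, u_z). This avoids Euler-sequence gimbal ambiguity
and does not depend on the sensor-fusion yaw, which strapdown IMUs do not
observe reliably. Knee flexion is the sagittal angle of the shank
longitudinal axis expressed in the thigh segment frame, 0 at full
extension, positive in flexion.

The 20 feature channels (10 per leg, right leg first) are: knee flexion,
thigh pitch, shank pitch, thigh/shank longitudinal acceleration a_z,
thigh/shank transverse acceleration magnitude √(a_x²+a_y²), thigh/shank
angular rate about the flexion axis, and the thigh residual angular-rate
magnitude (the shank residual rate is noisy in practice and is excluded).
An 18-channel variant without the shank pitches is available
(`include_shank_pitch=False`). Accelerometers are pre-filtered with a
causal 4th-order Butterworth low-pass at 10 Hz. All filtering in the
package is causal (forward-only): the estimator claims real-time
applicability, so zero-phase filtering would hide group delay that a
deployment would actually see.

## Dual-rate windows

At each prediction step the estimator sees 2.10 s of history in 25 samples:
a *long* window of 20 samples at 10 Hz (deep past) and a *short* window of
5 samples at 50 Hz (most recent 80 ms, ending at the prediction time). The
two windows do not overlap — the long window ends where the short one
begins. Before decimation each branch is low-pass filtered with a causal
2nd-order type-1 Chebyshev filter (cutoffs 25 Hz and 5 Hz; passband ripple
1 dB — our default, recorded in run metadata, since only the order, type,
and cutoffs are stated). Decimation keeps every k-th sample aligned so the
newest sample is always retained. No zero padding is used at the start of a
session: windows are only emitted once 2.10 s of data exist, because padded
history would fabricate a spurious "standing" past.

## Architectures

Three convolutional networks regress the 4-vector encoding from the
windows. Feature maps are 2-D (channel-height × time-width); all 3×1
convolutions slide along time only, so each row keeps its channel meaning
until a final 16-kernel 1×C convolution collapses the channel height into a
single-row time signal, which is flattened into a dense layer with 4
outputs.

* **Single Head-4**: long window only; one 16-kernel entry convolution and
  4 residual blocks with dilations 1, 2, 4, 8, then collapse + dense.
* **Dual Head-1**: one entry convolution and one residual block per window;
  head outputs are concatenated along time (long first, then short) and
  flattened directly into the dense layer.
* **Dual Head-4**: 4 residual blocks per head (dilations 1, 2, 4, 8),
  concatenation along time, then post-merge 3×1 convolutional layers
  before collapse + dense.

A residual block is conv(3×1) → batch norm → leaky ReLU (slope 0.01) →
dropout (rate 0.5) → conv(3×1) → batch norm, summed with a 1×1-projected
copy of its input; each block feeds a 1×1 convolution with 4 kernels that
bottlenecks the maps between blocks. Batch normalization uses a running
mean/variance decay of 0.1. Time width is preserved with symmetric zero
padding (a strictly causal left-padding variant is available as
`padding="causal"`; the padding side is not pinned down by the source
description).

Two genuinely open design points, and what we chose:

* The number of post-merge convolutional layers in Dual Head-4 is described
  inconsistently (2 in the text, 4 in the figure caption). We default to 4
  (`post_merge_layers` is a config knob), with dilations 1, 2, 4, 8.
* Initialization is fan-in-scaled uniform with the leaky-ReLU gain, and the
  closing batch-norm scale of each residual path starts at zero so every
  block is initially the identity-plus-projection map. The zero start is a
  standard residual-network device that materially speeds convergence of
  deep stacks at no cost; nothing in the architecture is changed.

The implementation is a small numpy layer library with explicit
backpropagation (`gaitphase.nn`), laid out channels-last so each
convolution tap is a single GEMM; activations and parameters are single
precision. Parameter counts are snapshot-tested: 8 260 (Single Head-4),
12 140 (Dual Head-1), 20 788 (Dual Head-4).

## Training

ADAM (β₁ = 0.9, β₂ = 0.999, ε = 1e-8), initial learning rate 0.0012, batch
size 128, learning rate multiplied by 0.2 after each epoch, data reshuffled
every epoch. Validation loss is computed every `val_every` iterations
(default 800); training stops when validation has failed to improve on the
best value for 2 consecutive evaluations, and the best-validation
parameters are returned. Windows with invalid labels (standing) are
excluded from training and validation: the phase is undefined there and
fitting it would be noise. Inputs are standardized per channel with
training-set statistics stored in the checkpoint — the channels mix rad,
m/s², and rad/s, whose raw scales differ by an order of magnitude; the
switch is exposed (`standardize=False`).

Note on epoch-dependent quantities: the learning-rate decay and validation
cadence are defined relative to an epoch. At the source's scale an epoch
was several thousand iterations; at the desk scale of the synthetic runs an
epoch is tens to hundreds of iterations, so `val_every` must be chosen
commensurately (the bundled run configurations do this), and most learning
happens in the first two epochs.

## Error metrics

The *spatial* error of one prediction is the signed angle between the
predicted and target encoding vectors, in cycles:
Δφ = atan2(ŷ₂y₁ − ŷ₁y₂, ŷ₁y₁ + ŷ₂y₂)/2π ∈ (−0.5, 0.5]. This is
wraparound-safe (target 0.99 vs prediction 0.01 is an error of 0.02, not
0.98) and scale-invariant in either argument. As printed, the formula is
the angle of the prediction *relative to* the target, i.e. predicted minus
target; all reported statistics use |Δφ| or Δφ², so the sign convention
does not affect results. sRMSE and sMAE are the RMS and mean absolute Δφ
in percent of a cycle, over both legs pooled.

The *temporal* error compares heel-strike timing. Estimated strikes are
the wraps of the decoded phase (a drop of more than 0.5 between consecutive
samples), refined by linear interpolation of the integer crossing; wraps
closer together than 0.2 s — below the physiological floor on stride rate,
hence necessarily jitter around a single true wrap — are merged keeping the
earliest. Each estimated strike is matched to the nearest actual strike and
the offset is normalized by the duration of the previous actual stride;
tMAE is the mean of these in percent. Spurious estimated events are
penalized (each counts as a matched step); actual events with no preceding
stride are skipped. Estimated events falling where the label is invalid
(standing) are dropped before matching, since no actual strikes exist
there to match against.

Cross-validation: `subject_out` holds out one test subject per fold, uses
the next subject round-robin for validation, and trains on the rest (with
16 subjects this is the 14/1/1 split; which subject validates is not
specified at the source — round-robin is our choice). `condition_out`
removes one walking condition from the training and validation sets of
every subject-out fold while the test subject keeps all conditions. Model
comparison uses a Friedman test across the models' per-fold errors,
followed (when significant at α = 0.05) by pairwise two-tailed Wilcoxon
signed-rank tests at the Bonferroni-corrected threshold α/n_pairs;
condition-out comparisons use two-sample Kolmogorov–Smirnov tests with the
same correction.

## Synthetic data

The simulator emulates the 8-condition split-belt treadmill protocol:
normal / short / long / normal strides at 0.8 m/s; a speed sweep
0.1 → 1.9 → 0.1 m/s; stepped holds at 0.2, 0.4, 0.8 m/s; a split-belt
asymmetric condition (left belt at 0.4 m/s for the first half, right belt
for the second); and walk/stop alternation between 0.8 m/s and standing.
Full-length conditions total 9.5 min; every run scales all durations with
a single `duration_scale`.

The gait model is deliberately simple — phase-driven rigid-body kinematics
in the sagittal plane:

* per-leg phase integrates a cadence f = (a·√v + b)/s strides/s, with v
  that leg's belt speed and s the condition's stride-length scale
  (a ≈ 0.55, b ≈ 0.25 per subject: stride duration ≈ 1.45 s at 0.8 m/s
  and ≈ 2.4 s at 0.1 m/s, comfortably below the 3 s standing threshold);
  the left leg starts half a cycle ahead, so strikes interleave;
* hip and knee angles are smooth per-subject templates of phase
  (two-harmonic series; the knee adds a von-Mises swing-flexion bump near
  φ ≈ 0.72), with amplitudes scaled by the condition's stride-length
  scale;
* orientations, angular rates, and sensor-point specific forces follow
  from forward kinematics with the hip fixed in space and gravity
  9.81 m/s² downward; angular rates are analytic, linear accelerations by
  central differences of the analytic positions;
* each heel strike adds a 50 ms damped sinusoid (25 Hz, 15 ms decay) to
  the shank accelerometer, attenuated ×0.3 on the ipsilateral thigh and
  ×0.2/×0.1 on the contralateral sensors — the impact signature the
  estimator exploits near the heel strike;
* the heel-marker height is a phase template: a swing-clearance bump that
  has decayed before the strike plus a narrow impact dip, so the height
  minimum and the vertical-acceleration peak coincide exactly with φ = 0;
* during zero-speed intervals the phase freezes and is flagged invalid
  (standing), producing no heel strikes;
* white noise: 0.25 m/s² on accelerometers, 0.015 rad/s on gyroscopes.

Subject parameters (segment lengths, sensor offsets, template coefficients,
cadence constants) are drawn from documented ranges by a seeded generator;
the same master seed reproduces sessions bit for bit.

What the simulator does *not* model: out-of-plane kinematics, soft-tissue
artifact, sensor-fusion drift, ground-reaction forces, pelvis translation,
and foot geometry (the heel trajectory is synthesized directly from phase,
not from a foot segment). Passing end-to-end tests on this data therefore
demonstrates that the pipeline — labeling, calibration, windowing,
training, and evaluation — is internally consistent and that the estimator
can learn phase from IMU-like signals; it does not certify accuracy on
human data, whose variability is far richer. No per-condition stride
statistics are available at the source to validate simulator realism
against, so only structural properties are asserted.

Simulated sensors are mounted anatomically aligned, and
`default_calibrations()` returns the exact sensor-to-segment rotations for
that mounting (for the shank, a half-turn about z, because the knee
flexion axis is the sensor's −x). Functional calibration is exercised
separately against analytically constructed trials, including remounted
sensors.

## Desk-scale study conditions

The end-to-end gates (used by the test suite and `scripts/acceptance.py`)
run subject-out cross-validation of Dual Head-4 and Single Head-4 on 6
synthetic subjects with `duration_scale = 0.12` (≈ 68 s per session, all 8
conditions), windows every 3rd sample, `val_every = 23`, and at most 2
epochs. These sizes were chosen
as the smallest at which training visibly converges and every condition
still contributes multiple strides per session; the gates assert
sRMSE < 10% and tMAE < 5% for Dual Head-4 and that its mean sRMSE does not
exceed Single Head-4's — a directional, not numerical, check of the
dual-rate design's advantage.

## Numerical choices and edge cases

* Event times snap to the 100 Hz grid (10 ms); no sub-sample ground-truth
  interpolation, since labels are consumed at 100 Hz.
* `decode_phase` of the exact zero vector raises; network outputs that are
  exactly (0, 0) are flagged undefined rather than silently decoded.
* Two phases exactly half a cycle apart have an error of ±0.5 with
  arbitrary sign; only the magnitude is meaningful there.
* Session files validate on read (uniform 100 Hz grid, unit quaternions
  within 1e-6, required channels present) and fail before any computation
  consumes bad data. Files are written without HDF5 timestamp tracking, so
  identical content gives byte-identical files.
* The filter banks are state-equivalent in batch and streaming form
  (`StreamingFilterBank`), verified to 1e-12.

## Known limitations

* The numpy networks train on one CPU core; they are sized for the
  desk-scale synthetic study, not for full-scale datasets.
* Heel-strike detection parameters are tuned for marker-quality heel
  trajectories; very noisy trajectories may need the prominence raised.
* The simulator's stop-and-go freezes posture mid-stride instead of
  settling to quiet standing; the frozen interval is labeled invalid
  either way.
* Single-precision arithmetic bounds batch-vs-single prediction agreement
  near 1e-6, not machine epsilon.
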