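# gaitphase

Real-time **gait-phase estimation** from thigh- and shank-mounted inertial
measurement units (IMUs), using dual-rate sliding windows and dilated
residual convolutional networks — together with a synthetic split-belt
treadmill simulator so the whole pipeline can be developed and tested
without a motion-capture lab.

## The problem

Assist-as-needed exoskeleton controllers need a continuous *gait phase*
variable φ ∈ [0, 1) — 0 at heel strike, increasing linearly to 1 at the
next ipsilateral heel strike — to synchronize assistance with the user's
own stride. Estimating φ in real time from four leg-worn IMUs is hard
because gait varies across people, speeds, stride lengths, and conditions
such as asymmetric stepping or stop-and-go walking.

The estimator regresses the per-leg sinusoidal encoding

    y = (cos 2πφ_R, sin 2πφ_R, cos 2πφ_L, sin 2πφ_L)

from 20 feature channels (joint and segment angles, accelerations, angular
rates, derived from functionally calibrated IMUs at 100 Hz). Each
prediction sees 2.10 s of history in 25 samples: a *long* window (20
samples at 10 Hz) for the periodic structure of gait and a *short* window
(5 samples at 50 Hz) for the most recent 80 ms, each behind its own causal
anti-aliasing Chebyshev filter. Three architectures are provided — Single
Head-4 (long window only), Dual Head-1 (shallow dual-rate), Dual Head-4
(deep dual-rate) — built from 16-kernel 3×1 dilated residual blocks.
Accuracy is reported as the wraparound-safe spatial phase error

    Δφ = atan2(ŷ₂y₁ − ŷ₁y₂, ŷ₁y₁ + ŷ₂y₂) / 2π

(sRMSE, sMAE, in % of a cycle) and the heel-strike timing error normalized
by the previous stride (tMAE, %), under one-subject-out and
one-condition-out cross-validation. See `docs/methods.md` for the full
model description.

## Worked example

Simulate three subjects walking the 8-condition treadmill protocol at 5%
duration and check the heel-strike labeling against ground truth:

```sh
gaitphase simulate --subjects 3 --preset paper --seed 7 \
    --duration-scale 0.05 --out demo/sessions
gaitphase label --session demo/sessions/S00.h5 --out demo/labels.json
```

`label` re-detects heel strikes from the simulated heel-marker trajectory
and checks them against the simulator's ground truth; for the run above it
prints:

```
{"r": {"detected": 20, "truth": 20, "matched_within_10ms": 19},
 "l": {"detected": 20, "truth": 20, "matched_within_10ms": 20}}
```

— 39 of the 40 true heel strikes recovered within one sample (the last is
one sample off). The estimator itself is trained and scored with
`cross_validate`:

```python
from gaitphase.metrics import cross_validate, prepare_subject
from gaitphase.synthetic import default_calibrations, generate_dataset
from gaitphase.training import TrainConfig

sessions = generate_dataset(6, "paper", master_seed=1, duration_scale=0.12)
subjects = [prepare_subject(s, default_calibrations(), stride_step=3)
            for s in sessions]
report = cross_validate(subjects, "dual_head_4", "subject_out",
                        train_cfg=TrainConfig(val_every=23, max_epochs=2,
                                              seed=1))
print(report.summary())
```

This trains six subject-out folds (a couple of minutes each on one core).
The identical computation inside `scripts/acceptance.py --seed 1` produced:

```
dual_head_4    sRMSE 5.01 +/- 1.58 %   sMAE 3.76 %   tMAE 4.28 %
single_head_4  sRMSE 20.90 +/- 3.52 %  sMAE 16.68 %  tMAE 18.80 %
```

i.e. on held-out synthetic subjects the dual-rate estimator tracks the
gait cycle with a spatial RMS error of about 5% of a cycle and places heel
strikes within about 4% of a stride, while the single-rate baseline is far
from converged at the same training budget — the dual-rate design's
advantage, in exaggerated form at desk scale. (Values shift with the seed;
on this clean rigid-body simulation they are optimistic relative to human
data.)

## Command-line interface

`gaitphase` exposes the pipeline stages as subcommands — `simulate`,
`convert` (HDF5 ↔ CSV), `calibrate`/`label`, `train`, `predict`,
`evaluate`, and `run` (full pipeline from a YAML config, with stage
caching). Every run writes a JSON manifest with config hashes and
input/output digests.

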