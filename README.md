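# ecogarm

Continuous decoding of three-dimensional arm trajectories from
electrocorticography (ECoG), for brain–machine-interface and
neurorehabilitation research.

Subdural electrode grids over sensorimotor cortex record multichannel
signals whose band-limited amplitude envelopes co-vary with ongoing arm
movement. `ecogarm` implements the full analysis that turns such recordings
plus motion-capture markers into decoded joint angles and 3D joint
positions, and — because the corresponding patient recordings are not
publicly deposited — ships a synthetic-session generator with exported
ground truth so every stage is testable end to end.

## The method

**Features.** The raw signal (1000 Hz, 15–60 channels) is re-referenced to
the common average, split into the seven sensorimotor rhythms
(δ 0.5–4, θ 4–8, α 8–14, β₁ 14–20, β₂ 20–30, γ₁ 30–50, γ₂ 50–90 Hz) with
4th-order Butterworth bandpasses, rectified, smoothed with a 2nd-order
2.2 Hz low-pass, decimated to 100 Hz and z-scored:

```
z_i(t) = (x_i(t) − µ_i) / σ_i
```

**Decoder.** Each kinematic variable — shoulder
abduction/adduction q₁, flexion/extension q₂, internal/external rotation q₃,
elbow flexion/extension q₄, and the x/y/z coordinates of elbow and wrist —
is predicted from the past second of features:

```
Y_p(t) = w₀ + Σ_i Σ_{j=1..m} w_ij · z_i(t − jΔt),    m = 100, Δt = 0.01 s
```

The weights are fitted by sparse Bayesian linear regression with automatic
relevance determination (ARD): every weight carries its own prior precision
α_ij, re-estimated by evidence fixed-point updates; weights whose α diverges
are pruned to exactly zero, and iteration stops just before over-training
via a chronological validation holdout.

**Trials and evaluation.** Movement trials are delimited where the elbow's
tangential velocity crosses 5% of its per-trial maximum; trials with more
than 20 cm sagittal excursion can be excluded. Decoding is scored by
leave-one-trial-out cross-validation with Pearson's correlation coefficient
(CC) and the range-normalized RMSE (nRMSE), reported as mean ± SEM across
trials. Decoded joint angles are rendered back into 3D arm trajectories
through forward kinematics with the subject's segment lengths, so
reconstructed paths always respect the arm geometry.

## Worked example

```python
from ecogarm import (ArmTrajectoryDecoder, PipelineConfig, SimulationSpec,
                     loo_cv, simulate_session)

spec = SimulationSpec(n_channels=6, n_trials=3, trial_duration_s=12,
                      envelope_snr=10.0, carrier_type="sinusoid", seed=42)
session, truth = simulate_session(spec)
config = PipelineConfig(train_stride=4)

model = ArmTrajectoryDecoder(session, config)        # segments trials, builds targets
targets = {k: model.targets[k] for k in ("q2", "q4", "wrist_y", "wrist_z")}
report = loo_cv(session, model.trials, targets, config)
print(report.summary())
```

prints

```
Leave-one-out cross-validated decoding
======================================
  variable   mean CC     SEM  mean nRMSE     SEM  trials
        q2     0.732   0.062       0.264   0.040       3
        q4     0.905   0.005       0.161   0.005       3
   wrist_y     0.903   0.009       0.166   0.007       3
   wrist_z     0.847   0.005       0.161   0.004       3
```

Each row is one decoded variable: the mean CC between predicted and actual
trajectories in the held-out trials (1 = perfect tracking), and the RMSE as
a fraction of each trial's actual range — e.g. wrist-y is tracked at CC 0.90
with errors around 17% of the movement extent. `model.fit()` returns a
results object whose `sparsity("wrist_y")` table shows which (channel, band)
pairs carry the decoding weight, and whose `reconstruct_trajectory()` turns
decoded angles into geometry-consistent 3D paths.

The same workflow is scriptable from a shell:

```sh
ecogarm simulate --seed 42 --channels 6 --trials 3 --carrier sinusoid --out-dir demo
ecogarm evaluate --signal demo/session.csv --markers demo/markers.csv \
        --targets wrist_y,wrist_z --train-stride 4
ecogarm band-contrib --signal demo/session.csv --markers demo/markers.csv
```

## Layout

| module | contents |
| --- | --- |
| `ecogarm.preprocessing` | CAR, filter bank, envelopes, z-scoring |
| `ecogarm.lagged` | lagged design matrices, causal prediction |
| `ecogarm.slr` | ARD sparse Bayesian regression (Model/Results) |
| `ecogarm.kinematics` | 4-DOF forward/inverse kinematics, velocities |
| `ecogarm.segmentation` | 5%-velocity trial segmentation, exclusions |
| `ecogarm.evaluation` | CC/nRMSE, leave-one-out CV, per-band reports |
| `ecogarm.decoder` | `ArmTrajectoryDecoder` / results facade |
| `ecogarm.simulate` | synthetic sessions with ground truth |
| `ecogarm.io`, `ecogarm.config`, `ecogarm.cli` | sessions, models, configuration, CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
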