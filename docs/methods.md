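# Methods

This note documents the models, algorithms and numerical choices behind
`ecogarm`, in the order data flows through the pipeline.

## Signal model and preprocessing

The working assumption is that movement information in ECoG lives in the
slowly varying amplitude envelopes of band-limited oscillations, linearly
related (with lags up to 1 s) to the kinematics. Preprocessing extracts
those envelopes:

1. **Common average reference.** Each sample's across-channel mean is
   subtracted. This removes the shared reference/common-mode component; it
   also mixes −1/n of every other channel into each channel, which matters
   for small montages (n < ~10) but is negligible at the 15–60 channels the
   pipeline targets.
2. **Filter bank.** Seven 4th-order Butterworth bandpasses
   (δ 0.5–4, θ 4–8, α 8–14, β₁ 14–20, β₂ 20–30, γ₁ 30–50, γ₂ 50–90 Hz),
   `scipy.signal.butter(4, band, "bandpass")` applied as second-order
   sections. The δ band needs a lower edge for a bandpass to exist; 0.5 Hz
   removes drift while keeping movement-locked slow potentials. Filtering
   is **causal** (forward-only) by default: the decoder uses only past
   samples, and a pipeline meant for real-time use must not look ahead. A
   zero-phase mode (`filter_mode="zero_phase"`) exists for offline
   exploration.
3. **Envelope.** Full-wave rectification (absolute value) followed by a
   2nd-order Butterworth low-pass at 2.2 Hz. The smoother has unit DC gain,
   so a unit sinusoid settles at 2/π, the mean of a rectified sine.
4. **Decimation to 100 Hz** by keeping every 10th sample. No extra
   anti-alias filter: the 2.2 Hz smoother already attenuates content at the
   50 Hz output Nyquist by far more than 40 dB.
5. **z-scoring** per feature with the **population** (1/N) standard
   deviation. Features with zero variance on the statistics window are
   dropped with a warning. By default (`normalization="foldwise"`) the
   statistics are computed on training-trial samples only and applied
   unchanged to held-out data, so cross-validation is leakage-free; a
   whole-session mode exists and is recorded in reports.

The filter bank is verified against the analytic analog Butterworth
magnitude `|H(f)| = (1 + ((f² − f_lo f_hi)/(f(f_hi − f_lo)))^8)^(−1/2)`,
valid far below Nyquist where bilinear warping is negligible.

## Lagged design

A target sample at time t is regressed on `z_i(t − jΔt)` for `j = 1..m`
(strictly past; `m = 100`, `Δt = 0.01 s`), plus an explicit constant bias
column. Rows are emitted only where the target sample and all m lags fall
inside valid (trial) samples — rows never straddle trial boundaries, which
would fabricate history. An `include_current_sample` option adds lag 0 but
is off by default.

## Sparse Bayesian regression (ARD)

Weights get independent Gaussian priors `w_k ~ N(0, 1/α_k)`; noise is
Gaussian with precision β. Hyperparameters are re-estimated by the
evidence-approximation fixed point

```
Σ = (β XᵀX + diag α)⁻¹         m = β Σ Xᵀ y
γ_k = 1 − α_k Σ_kk             α_k ← γ_k / m_k²
β ← (N − Σ_k γ_k) / ‖y − X m‖²
```

with these numerical choices:

- **Initialization** α_k = 1, β = 1/var(y): scale-free and reproducible.
- **Damped updates.** α and β move in log space with exponent 0.5
  (`α ← α·(α_new/α)^0.5`). The fixed points are unchanged; the plain
  updates overshoot during the first iterations and oscillate, while the
  damped path is smooth and the marginal likelihood is observed
  nondecreasing between pruning events (asserted in the test suite).
- **Pruning** removes a column when α_k > 10⁶ (weight exactly zero
  thereafter; the bias is never pruned). On z-scored features α = 10⁶ means
  a prior standard deviation ≤ 10⁻³ — a negligible contribution. A much
  larger threshold would keep spurious features indefinitely: under the
  fixed point, a pure-noise feature whose marginal |t| barely exceeds 1
  stalls at a finite α ≈ β·n/(t²−1), which can be anywhere up to ~10¹²;
  pruning at 10⁶ removes them while leaving genuinely informative weights
  (α < 1 in practice) untouched. Deleting such a stalled feature discards
  its small evidence contribution, which is why the monotonicity guarantee
  is stated between pruning events.
- **Dual-form solves.** While the active set is larger than the number of
  training rows, the posterior is computed through the Woodbury identity on
  an N×N system, so designs with tens of thousands of lagged columns cost
  O(N²K) per iteration and shrink rapidly as pruning proceeds.
- **Early stopping** ("terminate just before over-training"): the
  chronologically last 10% of training rows are held out; fitting stops
  after 3 (patience) consecutive validation-MSE rises and returns the
  best-validation snapshot. Chronological (not random) holdout respects the
  serial correlation of 100 Hz rows. A rise is only counted when the MSE
  exceeds the best seen so far by more than one sampling standard deviation
  of the MSE estimate (relative sd ≈ √(2/n_val)), and never before 10
  burn-in iterations — otherwise the holdout's noise, not over-training,
  stops the fit. Within that margin, ties go to the later (sparser)
  snapshot.
- **Convergence** requires stable weights (relative change < 10⁻⁵), stable
  finite alphas and no pruning within the iteration.
- **Conditioning guard**: jitter 10⁻¹⁰·trace/K on the posterior-precision
  diagonal.

## Kinematics

World frame: x lateral (subject's left), y anterior, z superior. The
shoulder rotation is `R = R_y(q1) · R_x(q2) · R_z(q3)`; the upper-arm rest
axis is −z, so R_z(q3) leaves the elbow invariant and q3 acts only on the
forearm ("internal/external rotation"). The forearm direction in the
upper-arm frame is `R_z(q3)·(0, sin(π−q4), −cos(π−q4))`: q4 = π is full
extension, and in the zero posture (q1 = q2 = q3 = 0, q4 = π) the arm hangs
along −z with the palm anterior.

Inverse kinematics: q4 from the elbow angle
(`arccos` of the normalized segment dot product), q2 = arcsin(u_y) and
q1 = atan2(−u_x, −u_z) from the upper-arm direction u, q3 from the forearm
direction rotated back into the shoulder frame. Branch cuts are fixed by
atan2; q2 ∈ [−π/2, π/2], q1, q3 ∈ (−π, π]. At the extension singularity
(q4 → π) q3 is indeterminate from three markers; the last well-defined
value is carried forward (0 at series start) and a warning is logged.
FK∘IK and IK∘FK are identity to 10⁻⁹ away from the singularity (tested on
10,000 random postures).

Tangential velocity is the Euclidean norm of per-axis central differences,
then a causal 2nd-order Butterworth low-pass at 5 Hz — well above reach
dynamics (< 2 Hz) but suppressing differentiation noise; small negative
filter undershoot is clipped to zero.

## Trial segmentation

The 5%-of-per-trial-maximum rule is circular as stated (the per-trial
maximum presupposes boundaries), so it is realized in two passes: candidate
bursts from a global 5%-of-session-maximum threshold; bursts closer than
`min_gap` merged; then each burst's boundaries moved outward to its own 5%
crossings (the per-burst threshold is never above the global one), bounded
by neighbouring bursts. Crossings are resolved at sample resolution, first
crossing wins. Defaults: `min_gap = 1.5 s` — grasp/release pauses inside a
transport cycle last up to ~1.1 s and must merge, while inter-trial rests
of ≥ 3 s must not — and `min_duration = 2 s` (cycles run 15–20 s; shorter
bursts are twitches). Trials whose within-trial marker range along a chosen
axis exceeds a limit (20 cm sagittally, by convention) can be excluded.

## Evaluation

One decoder per scalar variable (4 angles + 6 coordinates). For each
held-out trial: fit on all other trials' rows, predict the held-out trial
(its first second has no lag history and is skipped), score CC and nRMSE,
then aggregate as mean ± SEM (sample sd/√n) across trials. nRMSE divides
the RMSE by the actual trajectory's range within the test trial — the
common convention in trajectory decoding; an sd-normalized variant is
available by flag and labeled in reports. CC is computed per trial and
averaged, not pooled. Normalization statistics and the early-stopping
holdout come from training trials only. Per-band evaluation restricts the
design to one band's features (n_channels × m columns + bias) and is
otherwise identical.

## Synthetic sessions

The generator produces the statistical structure the decoder assumes, with
exported ground truth:

- **Kinematics.** Per trial, three block transports among the corners of a
  25 cm square on a table in front of the subject (square center
  (0, 0.28, −0.28) m relative to the shoulder, lift height 8 cm, grasp and
  release dwells of 0.4 s), visiting all four corners. Waypoint postures
  come from a 4-DOF inverse kinematics with the elbow on the natural
  (downward) side; motion between postures is minimum-jerk **in joint
  space**, so marker triples always satisfy the segment lengths and avoid
  singularities. Segment durations are proportional to wrist travel so peak
  speeds are comparable across long carries and short lifts. Trials are
  separated by ≥ 3 s rests of exactly zero velocity. Default trial duration
  16 s (patient-paced cycles run 15–20 s).
- **Signal.** Each channel at 1000 Hz is
  `Σ_bands carrier_b(t) · envelope_b(t)` plus a pink-noise floor (amplitude
  0.1). A fraction (default 0.3) of (channel, band) pairs is informative:
  their envelope is `1 + 0.35·s(t)` where s is a unit-variance sparse
  combination of 1–2 kinematic variables lagged by 0.15 s (inside the
  decoder's 1 s window); the rest carry envelope noise only. Envelope noise
  is band-limited to ≤ 2 Hz — the envelope band — so the specified
  envelope SNR (signal-envelope variance over noise variance) survives the
  2.2 Hz analysis smoother and actually controls the difficulty;
  broadband envelope noise would be mostly filtered away. Multiplicative
  amplitude modulation is the generative inverse of
  rectify-and-low-pass, making the pipeline the matched analysis.
- **Carriers.** `band_noise` (default): unit-variance Butterworth-filtered
  white noise per band — realistic, but its rectified amplitude is itself a
  noisy envelope estimate, capping recovered-envelope fidelity at CC
  ≈ 0.5 (δ) to 0.85 (γ₂) regardless of envelope SNR. `sinusoid`: a fixed
  tone per band whose amplitude the pipeline recovers essentially exactly;
  the tone sits at the band center, floored at 6.6 Hz (3× the smoother
  cutoff) where the band allows, so the rectification ripple at twice the
  carrier frequency stays out of the envelope band. The benchmark "high
  envelope SNR" condition is therefore sinusoid carriers at SNR 10; "low"
  is band noise at SNR 1.

What the generator does **not** emulate: 1/f spectral shape beyond the
fixed pink-noise floor, pathological (e.g. epileptiform) activity, channel
cross-correlation structure beyond the common average, marker occlusion
gaps, torso sway (except as constructed test cases), and nonlinear or
non-stationary envelope–kinematics coupling. Passing the synthetic
benchmarks shows the pipeline is correct and self-consistent for the
assumed signal model — not that comparable accuracy is attainable on any
particular patient recording.

## Study sizes in the shipped experiments

The end-to-end experiments are scaled to single-CPU runtimes: the benchmark
uses 15 channels × 5 trials × 15 s with training rows thinned to 25 Hz
(`train_stride = 4`; prediction always runs at full 100 Hz), and the
envelope-SNR ladder uses 6 channels × 4 trials × 12 s per session — with
fewer trials the zero-SNR CC's sampling spread across seeds is wider than
the ±0.15 band it is checked against, so 4 leave-one-out folds are the
minimum that resolves the null. Row thinning at 25 Hz costs little
information because both envelopes (≤ 2.2 Hz) and kinematics (< 2 Hz) are
heavily oversampled at 100 Hz. `PipelineConfig` defaults keep
`train_stride = 1`.

## Known limitations

- The ARD fixed point is a local optimization; which weakly informative
  features survive depends on the data realization (the support-recovery
  tests bound this: median ≤ 2 false inclusions on the 20-feature
  reference problem).
- Decoding wrist/elbow coordinates with a linear readout of envelopes is
  exact for the generator's coordinate-coupled pairs but only a local
  linearization where couplings run through joint angles.
- The EDF writer is minimal (16-bit, 1 s records) and quantizes amplitudes;
  lossless round-trips use CSV.
- q3 near full elbow extension is reconstructed by carry-forward, not
  measurement.
- The per-trial 5% rule inherits the two-pass construction; pathological
  speed profiles (e.g. long sub-5% plateaus inside a movement longer than
  `min_gap`) can split differently than a human rater would.
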