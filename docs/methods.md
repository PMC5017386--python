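# Methods

This note documents the models, parameter choices and numerical decisions
behind `scrubseq`, and what the synthetic-data experiments do and do not
establish.

## Problem setting

The WHO hand-hygiene routine is a fixed sequence of nine gestures
(G1 … G6R, the asymmetric movements duplicated per leading hand). The task
is frame-level gesture recognition from two forearm armbands, each
providing 8 surface-EMG channels (int8, 200 Hz) and a 10-channel IMU
(orientation quaternion w,x,y,z; acceleration x,y,z; angular velocity
x,y,z; float, 50 Hz). Classification runs at the 50 Hz IMU frame rate;
labels are defined per IMU frame.

## Feature extraction

**Cross-rate alignment.** Downsampling raw EMG to 50 Hz before feature
extraction would destroy its high-frequency content (most sEMG power lies
above 25 Hz). Instead, features are computed per channel at native EMG
resolution and the *feature vectors* are decimated: frame *i* uses an EMG
analysis window centered on EMG sample 4·i.

**Windows.** Defaults `emg_window=128` (0.64 s at 200 Hz) and
`imu_window=32` (0.64 s at 50 Hz), so both modalities see the same time
horizon. Windows are centered (center index `width//2`) and
reflection-padded at session edges; centering is a convention, chosen so a
one-frame shift of the signal shifts the feature matrix by exactly one row
in the interior.

**Wavelet features.** Per channel, a level-L Daubechies decomposition
(default db4) summarized as one scalar per band: `log10(eps + mean-square
coefficient)` for each detail level 1…L plus the final approximation —
L+1 values per channel. This is the only per-level scalarization consistent
with the feature-count formula `D = 36 + 36(L+1)` (432 at L = 10); the
log makes the feature scale-aware and compresses the dynamic range, and
`eps = 1e-12` keeps silent bands finite (a constant window yields exactly
`log10(eps)` in every detail band because Daubechies filters annihilate
constants).

The DWT uses **periodized (circular) convolution**, which keeps the
transform unitary at every level whose input length is even: band energies
then partition the window energy exactly (Parseval), which is what makes
"energy per band" well defined. Filters are built by spectral factorization
of the Daubechies Bernstein polynomial (extremal-phase root selection), so
any order is available without coefficient tables; construction is
validated against the closed-form db1/db2 coefficients and the
orthonormality/vanishing-moment identities.

**Feasibility cap.** A window of length n supports only `v2(n)` circular
halvings (7 for 128, 5 for 32). Levels beyond feasibility are emitted as
`log10(eps)` — zero information, but the column count honours the
dimensionality formula for every L, including L = 20 where the printed
feature count would otherwise be unreachable on short windows.

**Raw values** are the instantaneous center samples (EMG) and the current
frame (IMU); whether "raw" means instantaneous samples or window means was
an open convention, and instantaneous samples were chosen as the simpler
reading.

## Classification

Nine binary feed-forward networks (one-vs-all), each: input D, tanh hidden
layers (default 1 × 25 nodes), one sigmoid output, binary cross-entropy
computed from logits for numerical stability. Features are z-scored with
training-set statistics; zero-variance features get std 1 so they map to a
constant 0. Weights initialize uniform in ±1/√fan_in, seeded per gesture.
The winner is the network with the highest sigmoid response; exact ties
break toward the lower routine ordinal (deterministic).

**Optimizer.** Scaled conjugate gradient (Møller-style): conjugate
directions with curvature along the direction estimated by a
finite-difference Hessian-vector product (σ = 1e-4) and a
Levenberg–Marquardt scale λ (initial 1e-6) adapted by the comparison ratio
between predicted and achieved decrease; only improving steps are accepted,
so the objective trace is non-increasing. Stopping: gradient norm < 1e-6,
`max_iter` = 300, or an objective plateau (improvement of mean
cross-entropy < 1e-5 over 10 accepted steps). The plateau rule is what
keeps full-cohort training within a single-CPU budget; on the synthetic
task it typically triggers after 50–150 iterations, long after frame
accuracy has saturated.

**Training stride.** Adjacent 50 Hz frames share ~97 % of their analysis
windows, so training uses every 4th frame by default
(`train_frame_stride=4`), a 4× cost reduction with negligible information
loss. Prediction and evaluation always use every frame.

## Sequence smoothing

A 9-state left-to-right chain HMM encodes the routine: state i may persist
(probability `self_prob`, default 0.995) or advance to i+1; the last state
is absorbing. Observations are the classifier's hard frame labels with a
discrete emission matrix: `emission_correct` (default 0.9) on the diagonal,
the remainder uniform. The initial distribution is concentrated on G1 (the
routine starts at palm cleaning); a uniform start is available for
free-standing sequences.

At 50 Hz, these defaults price a state switch at log(0.005/0.995) ≈ −5.3
against a per-frame emission log-ratio of log(0.9/0.0125) ≈ 4.3, so a
switch needs roughly two consistent frames of contrary evidence — isolated
misclassifications are overridden, genuine gesture changes are found within
a frame or two.

**Flooring and hard zeros.** Emission and initial probabilities are floored
at 1e-12 before taking logs, so no observation sequence has zero
likelihood. The structural zeros of the transition matrix are *not*
floored (they are represented by a finite −1e30 sentinel in log space,
avoiding −inf/NaN arithmetic): if backward transitions were merely
improbable rather than impossible, a long burst of contrary labels could
make a backward step optimal and the monotonicity guarantee would be
false. With hard zeros, every decoded path is provably non-decreasing in
routine order with at most 8 switches. Viterbi ties break toward the lower
state ordinal during backtracking.

## Synthetic cohort generator

The generator emulates the acquisition design the pipeline targets:
17 subjects × 3 repetitions, the nine gestures in routine order at 5 s
each, armband re-seated slightly between repetitions. Defaults are the
stated protocol; the generator is a statistical stand-in, not a
physiological simulator.

* **EMG** per channel: subject gain × placement-mixed template RMS ×
  (1 + 0.1 sin 2πft) × unit-variance band-limited Gaussian noise
  (4th-order Butterworth band-pass 20–95 Hz), plus an additive noise floor
  (RMS 2 int8 counts), clipped and quantized to int8. Amplitude-modulated
  band-limited noise is the standard surface-EMG surrogate. Template
  activations span ≈ 6–44 counts, keeping the clipping rate ≪ 1 %.
* **Templates**: per gesture, a seeded per-arm 8-channel activation
  pattern (pairwise cosine distance ≥ 0.1 enforced by rejection) and one
  dominant rubbing motion (axis, frequency 0.8–2.8 Hz, amplitude
  0.25–0.45 rad). The `separation` dial blends all templates toward their
  common mean; 1.0 is the stated world, smaller values create genuinely
  harder problems (used to verify that downstream accuracy responds
  monotonically).
* **Subjects**: lognormal per-channel gains (σ = 0.25), standing in for
  inter-subject differences in skin conductivity and musculature; a
  per-repetition armband rotation uniform in ±π/8, applied as fractional
  circular interpolation across the 8-electrode ring.
* **IMU**: orientation is a small-angle sinusoidal rotation about the
  gesture's motion axis, emitted as unit quaternions; acceleration is
  gravity (9.81 m/s², world +z) rotated into the sensor frame plus a
  tangential sinusoid and Gaussian noise (σ = 0.05 m/s²); angular velocity
  is the analytic derivative of the orientation plus noise
  (σ = 0.5 rad/s).
* Gestures were recorded individually in the emulated protocol, so there is
  no transition blending by default; an optional linear cross-fade
  (`transition_fade_s`) exists for robustness experiments.

**What a green test establishes.** The synthetic world preserves the
structure that drives the method — rate mismatch between modalities,
per-channel amplitude coding of gestures, subject-level gain nuisance,
placement rotation, routine order — so it exercises every stage end to end
and verifies the claimed behaviours (feature dimensionality, no leakage
across subject folds, HMM never hurting on routine-ordered data). It does
*not* reproduce real sEMG nonstationarity, motion artifacts, electrode
lift-off, or anatomical variability, so absolute recognition rates on
synthetic cohorts (≈ 99 % cross-validated at the reference configuration)
are not comparable to rates on real recordings and no such comparison is
made.

## Evaluation conventions

* Folds partition *subjects* (seeded shuffle + contiguous split, sizes
  differing by ≤ 1; 17 subjects, k=5 → 4+4+3+3+3); all sessions of a
  subject share a fold.
* Recognition rate is frame-level accuracy over all test frames — the
  simplest definition consistent with confusion-matrix reporting.
  Across-fold dispersion is the sample (n−1) standard deviation.
* HMM decoding is applied per session: each session is one routine
  instance.
* The sweep harness varies exactly one axis (hidden nodes, hidden layers,
  wavelet level) around a base configuration, mirroring incremental
  hyperparameter tuning.

## Known limitations

* The chain HMM assumes the prescribed gesture order; out-of-order
  performances require a richer transition topology (not implemented).
* Discrete emissions discard the classifier's confidence; a soft-emission
  variant is out of scope.
* Transition frames near gesture boundaries mix adjacent gestures within
  the 0.64 s analysis window; most residual classifier errors sit there,
  which is also where the HMM helps most.
* The on-disk format stores one label track per session; per-arm label
  disagreement is not representable.
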