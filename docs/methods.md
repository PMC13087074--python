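# Methods

This note documents the models, algorithms and numerical choices behind
`fcdlif`, and what its synthetic experiments do and do not demonstrate.

## Problem

Kinetic modeling of dynamic PET requires the arterial input function (AIF)
— the tracer concentration in arterial blood over time.  In mice the gold
standard, arterial cannulation, is terminal and precludes longitudinal
studies.  `fcdlif` predicts the AIF directly from the reconstructed 4-D
dynamic PET volume with a compact, fully convolutional network, and
carries the prediction through to physiology with Patlak graphical
analysis and irreversible two-tissue compartment (2TCM) fits.

## Data model and units

All times are seconds from injection; concentrations are standardized
uptake values, SUV = activity × body weight / injected dose (g/mL); net
influx rates K<sub>i</sub> are per minute.  A dynamic image is a
`(time, depth, height, width)` SUV array bound to a frame schedule.  The
canonical whole-body mouse protocol reconstructs 42 frames
(1×30 s, 24×5 s, 9×20 s, 8×300 s; 2730 s total) at 96×48×48 voxels.
Curves derived from frame-averaged data are sampled at frame midpoints,
the standard convention for frame-averaged quantities.

## Network

The predictor has two purely convolutional parts:

- **Spatial feature extractor (SFE).**  Applied to every time frame with
  shared weights: three stages of (2× max-pool → residual block) with
  channel widths 16, 8, 40, then a 4×2×2 convolution to 32 channels and
  global average pooling, yielding one 32-vector per frame.  Residual
  blocks are two 3³ convolutions with ReLU and a 1×1×1 projection
  shortcut where widths change; no normalization layers (batch size is 1).
  The second block is deliberately the narrowest: temporal modeling is
  deferred to the head, so spatial capacity is kept low mid-cascade.
- **Temporal feature extractor (TFE).**  Three 1-D convolutions
  (32 → 17 → 6 → 1, kernel 7, zero "same" padding, no dilation) over the
  stacked (T, 32) sequence.  Same-padding preserves the temporal length
  for any T ≥ 1, and makes the output covariant with time shifts of the
  input except within the receptive-field radius (3 layers × 3 = 9
  frames) of the sequence boundaries.

Only the total trainable parameter budget of the published model — 90 124
weights and biases (352 KB in FP32) — constrains the widths, so the
shipped configuration was chosen by exhaustive enumeration
(`scripts/architecture_search.py`) over admissible families (three blocks,
second no wider than the first, decreasing head, odd kernel) to hit the
budget exactly.  Other width combinations also satisfy it; the shipped
config is one admissible member, and the parameter count is independent of
the spatial input shape because the model is fully convolutional.

The engine is written on numpy: im2col convolutions backed by BLAS
matmuls, with the patch gather and its scatter-add adjoint JIT-compiled by
numba, explicit backpropagation, and ADAM.  Everything is float32 and
deterministic for a fixed seed on a fixed BLAS.  Inference chunks frames
through the SFE to bound memory; the gradient of the input image is never
computed (the first block's input gradient is skipped).

## Training

The loss is a weighted MSE over the predicted curve,
(1/T) Σ w_t (ŷ_t − y_t)².  On the canonical schedule the first 25 frames
(peak), middle 9 (intermediate) and last 8 (tail) carry weights 0.4, 0.7
and 1.0 — roughly inverse to the sampling density, so the sparse tail is
not drowned out.  The mean (rather than sum) over frames keeps the loss
comparable across sequence lengths.  For non-canonical lengths, segments
are assigned by frame start time (peak < 150 s, intermediate < 330 s),
which reproduces the canonical split exactly.

Augmentation degrades each image once per epoch with additive Poisson
noise: p ~ Unif(0, 1) per image, Λ = I·p per voxel, output
I + Pois(Λ) − Λ.  The expectation is unchanged and the injected variance
is proportional to the local intensity, emulating count-limited framing.
One p per image (not per voxel) is used.

Canonical protocol: ADAM (β = 0.9/0.999, ε = 1e-8, no weight decay, no
schedule), learning rate 1e-4, 1000 epochs, batch size 1, 10-fold
cross-validation with 10 repeated runs per fold.  The desk-scale protocol
used by the tests and the acceptance script
(`fcdlif.training.desk_scale_config`) trains on 20 noiseless reduced-grid
phantoms for 40 epochs at 1e-3 with augmentation off: the published
schedule takes ~63 000 optimization steps, so the reduced run compensates
its ~80× fewer steps with a 10× larger step size.  Augmentation is off
because the recovery experiment is defined on noiseless phantoms.

## Synthetic phantoms

Real paired (scan, blood-curve) data cannot be redistributed, so the
phantom generator supplies ground truth.  A Feng-style tri-exponential
models the AIF:

C(t) = (A₁τ − A₂ − A₃)e^{−λ₁τ} + A₂e^{−λ₂τ} + A₃e^{−λ₃τ},  τ = t − t₀,

zero before arrival t₀ and continuous at it.  Defaults (A₁ = 1.6 SUV/s,
A₂ = 1.5, A₃ = 0.85 SUV, λ₁ = 0.05, λ₂ = 0.01, λ₃ = 1e-4 /s, t₀ = 5 s)
give a bolus peaking near SUV 12 within the first minute and a tail near
SUV 0.7 after 45 min — plausible for an FDG bolus in a mouse.  Organs are
axis-aligned ellipsoids whose tissue curves solve the irreversible 2TCM

dC₁/dt = K₁C_p − (k₂+k₃)C₁,  dC₂/dt = k₃C₁,
C_T = (1−v_B)(C₁+C₂) + v_B·C_wb,

with plausible mouse FDG rates (myocardium-like K₁ 0.7, k₂ 1.2, k₃ 0.1,
v_B 0.1; brain-like 0.15/0.25/0.05; liver-like 0.45/0.7/0.01; faint
background).  The ODE is solved with LSODA (rtol 1e-9, atol 1e-12) on a
dense grid and frame-averaged by composite trapezoid quadrature with 129
points per frame (error well below 0.1 % per frame against a 10 000-point
reference).  The blood-pool ellipsoid carries the frame-averaged AIF.

Noise, when enabled, is Poisson on simulated counts: expected counts are
value × duration × noise-scale per voxel and frame, sampled and rescaled
to SUV.  This preserves the expectation and reproduces the
duration-dependent SNR of real framing (short early frames visibly
noisier than the 300-s tail frames).  No quantitative scanner noise level
is available, so the scale is a free knob calibrated only qualitatively,
with 0 (noiseless) the default for recovery experiments.  Inter-animal
variability is emulated by jittering input-function and kinetic
parameters by ±30 % and the arrival delay over 0–15 s.

What the phantoms deliberately omit: anatomical realism (no atlas),
scanner physics (PSF, scatter, dead time, partial volume), motion, and
reconstruction artifacts.  Passing the recovery experiments therefore
demonstrates that the architecture, loss, optimizer and kinetic code are
implemented correctly and that the model can learn the image-to-AIF map
under controlled conditions — not that the shipped weights or scores
transfer to animal data.

## Kinetic quantification

Whole-blood curves are converted to plasma by a pluggable ratio model
(constant or time-tabulated, linearly interpolated).  The default ratio
of 1.0 is a placeholder: the plasma/whole-blood ratio is tracer- and
species-specific and must be supplied for real studies.

Patlak analysis regresses y = C_T(T)/C_p(T) on
x = ∫₀ᵀC_p dt / C_p(T) by ordinary least squares over frames with
midpoint ≥ t*; the slope (×60) is K_i per minute.  The integral is
cumulative trapezoid anchored at (0, 0) — concentration is zero at
injection.  t* defaults to 600 s, the start of the 300-s frames, past
the distribution phase.  The intercept is reported without physiological
interpretation.  Voxel maps run the same arithmetic in batch, so a map
entry and a single-curve fit agree bit for bit; failed or unmasked voxels
are flagged NaN rather than raising.  With a blood-volume fraction v_B in
the tissue, the recovered slope is (1−v_B)·K₁k₃/(k₂+k₃), since the blood
term is proportional to the input and moves only the intercept.

The 2TCM fit is trust-region nonlinear least squares (scipy
`least_squares`) against the forward model, k₄ fixed at 0, uniform
residual weights by default (the weighting used in regional fits is not
standardized), bounds [0, 10] on rates and [0, 1] on v_B, and v_B fixed
at its initial value unless `fit_vb=True`.

## Evaluation machinery

Curves are compared frame by frame: unweighted MSE, Pearson r, and Deming
regression with variance ratio δ = 1 (orthogonal regression, accounting
for error in both predicted and measured values; δ is exposed and the
estimate approaches OLS as δ → ∞).  Dataset-level comparison adds pooled
pointwise statistics, per-frame paired t-tests across samples at α = 0.05
(unadjusted, with an optional Bonferroni flag), and quantile–quantile
pairs of pooled differences for normality inspection; r² is reported as
the squared correlation about the Deming line's predictions.  Best,
median and worst samples are ranked by ascending unweighted MSE with ties
broken by index and the median taken at position ⌊n/2⌋ of the sorted
order.

Robustness operations: the shift test prepends one 30-s frame (zeros by
default, or a copy of the first frame — both conventions appear in
practice, so both are implemented behind `--shift-mode`) and scores the
alignment between the original prediction and the shifted prediction with
its first frame dropped; the truncation test removes the first 4 and last
6 frames (the 30-minute tail) and re-anchors the schedule.  Note the
first four canonical frames span 45 s (30+5+5+5); the conventional "first
40 s" label for this truncation is approximate and frame counts are
treated as authoritative.  t-SNE embeds the per-frame 32-feature SFE
vectors (perplexity min(30, (n−1)/3), PCA initialization, seeded).

## Problem sizes used by the shipped experiments

Reduced-grid phantoms are 42×32×16×16 — the smallest grid the pooling
cascade and the 4×2×2 kernel admit — with 25 phantoms (20 train, 5
held-out) in the recovery run, 40 epochs, and 10⁵ draws for the
augmentation moment check.  These sizes were chosen so a complete run is
a desk-scale, single-CPU experiment; the canonical 96×48×48 grid and
full protocol are configuration, not separate code paths.

## Known limitations

- The engine is CPU-only and single-device; there is no GPU path.
- Spatial input dimensions are fixed per trained model (only time is
  free); inputs must be resampled to the trained grid.
- The default plasma ratio of 1.0 is not physiological.
- Phantom realism is limited as described above; no pretrained weights
  are distributed, and published cross-validation scores on animal data
  are not reproducible from this repository.
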