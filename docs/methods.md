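# Methods

## Problem

During 5-ALA fluorescence-guided resection of gliomas, the protoporphyrin IX
(PpIX) accumulated in tumor tissue fluoresces around 634 nm under 405 nm
excitation. A hyperspectral imaging system sweeps a tunable filter from
421 to 730 nm in 3 nm steps (104 bands) and records one image per band; each
binned pixel yields a fluorescence emission spectrum Φ_fluo and, under broadband
illumination, a white-light reflectance spectrum Φ_ref. Quantifying PpIX from
Φ_fluo requires two steps:

1. **Attenuation correction** — heterogeneous tissue absorption, scattering
   and geometry multiply the emitted spectrum by an unknown smooth factor;
   Φ_ref carries information about that factor.
2. **Unmixing** — the corrected spectrum is modeled as a non-negative linear
   combination of K = 5 known endmember emission spectra (PpIX634, PpIX620,
   lipofuscin, NADH, flavins): Φ = B z, z ≥ 0.

The package implements the classical benchmark (dual-band normalization +
non-negative least squares), a supervised residual CNN (ACU-Net) that maps
(Φ_fluo, Φ_ref) directly to absolute abundances, and a semi-supervised
Siamese autoencoder (ACU-SA) with an explicit corrected-spectrum
intermediate, together with PLS and naive-MLP baselines, evaluation
machinery, and a seeded synthetic data generator that stands in for the
(private) phantom, pig-brain-homogenate (PBH) and human datasets.

## Classical benchmark

The dual-band factor integrates Φ_ref over an excitation-side band
(450–480 nm) and the PpIX emission band (620–640 nm), raises the first
integral to an empirical exponent x = 0.7, and divides Φ_fluo by the
product. Band integrals use the trapezoid rule on the native 3 nm grid; the
bands and exponent are configurable (`DualBandConfig`). Unmixing is
active-set NNLS (`scipy.optimize.nnls`); its objective is verified in the
tests against an accelerated projected-gradient oracle and, on small
instances, a dense grid search.

## Synthetic forward model

No public data exist for this problem, so the generator defines the study
conditions. It is a diffusion-flavored phenomenological model, not radiative
transfer:

- absorption µ_a(λ) = µ_a,405 · exp(−(λ−405)/120 nm); reduced scattering
  µ_s′(λ) = µ_s′,635 · (λ/635)⁻¹;
- unit-geometry reflectance shape Rs(λ) = µ_s′/(µ_a + µ_s′);
- white-light spectrum R(λ) = geom · Rs(λ) (flat illuminant);
- fluorescence attenuation
  A(λ) = geom^1.7 · E · Rs(λ)^0.7 · mean(Rs over 620–640 nm) with the
  excitation-penetration factor E = exp(−µ_a,405 / 40 cm⁻¹).

Design rationale:

- The geometry exponent of A equals 1 + x, so the dual-band factor (which
  scales as geom^(1+x) through the reflectance) removes geometric variation
  *exactly*. In the geometry-only sub-model the classical pipeline is
  therefore perfectly linear — a strong internal consistency check.
- E uses a Beer–Lambert-like form in the excitation absorption, deliberately
  different from the albedo-ratio form of the reflectance. A scalar factor
  built from reflectance band integrals can compensate it only partially, so
  the classical method retains a systematic residual across the
  absorption/scattering grid, while the learned models — which see the full
  reflectance shape and can infer µ_a — can remove it. The e-folding scale
  40 cm⁻¹ makes the residual large enough to separate the methods (the
  classical held-out correlation sits near 0.91–0.97 depending on the split)
  without drowning the concentration signal.
- The wavelength-dependence Rs(λ)^0.7 adds shape distortion that no scalar
  correction can undo.

Endmembers are parametric Gaussians (PpIX634: 634 nm σ 10 nm plus a
0.35-height secondary at 704 nm; PpIX620: 620 nm σ 12 nm; lipofuscin 500 nm
σ 50; NADH 460 nm σ 35; flavins 525 nm σ 60), peak-normalized to 1; a seed
perturbs centers by ±2 nm and widths by ±10% for robustness testing.
Abundances then carry all magnitude, and the phantom label (µg/mL) is the
PpIX634 abundance itself.

Datasets:

- **Phantom**: 5 concentrations (0.0, 0.2, 0.6, 1.25, 2.5 µg/mL) × 9 optics
  (µ_a,405 ∈ {18, 42, 60} cm⁻¹ × µ_s′,635 ∈ {8.7, 11.6, 14.5} cm⁻¹) = 45
  vials. Vials are homogeneous: one abundance vector and one optics setting
  per vial; pixels differ only by camera noise. A small dye/background
  autofluorescence (0.05 on flavins) is always present. Vials sit at a fixed
  ladder of working distances — geometric factors (0.4, 0.7, 1.0, 1.6, 2.6)
  cycled across vials with 10% lognormal jitter — so the uncorrected
  magnitude spread across the grid is large and reproducible.
- **PBH**: 7 concentrations (0.0–4.0 pmol/mg) × 4 samples, each sample with
  its own optics (uniform over the phantom ranges ±20%, lognormal geometry,
  σ = 0.5) and its own lognormal autofluorescence (median 0.2). The label is
  the per-sample spike concentration; per-pixel PpIX jitters with 5% CV
  (homogenate heterogeneity); PpIX620 is co-generated at 15% of PpIX634
  (second photostate).
- **Unlabeled (human-like)**: sparse abundances (each endmember present with
  probability 0.6, Dirichlet-distributed magnitudes) under per-pixel random
  optics.
- **Cube rendering** tiles pairs into 10×10-pixel blocks inside a dark
  border, adds a dark offset (0.05) and Gaussian read noise, and emits the
  fluorescence/white/dark ENVI triplet the preprocessing pipeline consumes.

Camera noise defaults to Gaussian read noise with σ = 0.004 in normalized
count units — about 1% of a typical peak signal, consistent with the long
(500 ms) exposures the instrument uses; Poisson shot noise is available but
disabled by default. All generators are pure functions of (parameters, seed).

What the simulator does *not* emulate: multiple scattering and other
non-multiplicative distortions, PpIX photobleaching and pH-dependent
photostate exchange, specular saturation, spatial correlations between
pixels, and instrument wavelength drift. Passing tests therefore demonstrate
correctness of the algorithms under the stated generative assumptions, not
clinical performance.

## Preprocessing

Raw cube triplets are dark-subtracted (clamped at zero), divided by
filter-transmission × camera-sensitivity curves, averaged over
non-overlapping 10×10 blocks (remainder pixels dropped), and masked by Otsu
thresholding of the band-integrated white image followed by morphological
opening (3×3 structuring element, Chebyshev radius 1 binned pixel) and
largest-connected-component selection. Dark subtraction precedes binning;
both operations are linear, so the order only matters for the zero clamp.

## ACU-Net

A 1-D residual CNN over the stacked two-channel spectrum (2 × 104):

- stem convolution to 8 channels; four residual blocks (two
  same-convolutions each, identity skip) with max-pool 2 after each block;
  channel-doubling transition convolutions between blocks (8→16→32→64);
  kernel 5 in the first two blocks, 3 in the last two;
- three fully connected layers (256, 64, K = 5);
- a ReLU at the output enforces z ≥ 0.

The channel ladder (8, 16, 32, 64) and FC sizes are free choices (the
architecture description fixes only the block/kernel structure); the ladder
doubles per stage and is wide enough that the 32-sample memorization test
passes with two orders of magnitude to spare.

Loss per sample, with learned homoscedastic task uncertainties σ_C, σ_rec
(parameterized as log σ, floored at 10⁻³):

L = (z₁ − c_PpIX)²/(2σ_C²) + ‖B ẑ − Φ̃‖²/(2σ_rec²) + log(σ_C σ_rec),

where z₁ is the PpIX634 component, ẑ = z/‖z‖₂, and Φ̃ is the unit-ℓ2
normalized measured fluorescence spectrum. Both reconstruction sides are
normalized so the term compares spectral shape — otherwise strong PpIX
spectra dominate. The σ-gradient has the closed form 1 − r²/σ², so each σ
tracks its task's residual magnitude; a task with zero residual drives its
σ to the floor without affecting the other task.

Optimization: AdamW (decoupled weight decay 10⁻⁴, not applied to biases or
log σ), batch 256, learning rate 2·10⁻³ halved when the epoch loss fails to
improve by 10⁻⁴ for 10 epochs, stop at 200 epochs or learning rate < 10⁻⁶.
Training is single-threaded, float32, and bit-reproducible under a fixed
seed.

Two data augmentations are applied per batch (both label-invariant, both
disabled for capacity/memorization tests):

- **geometry augmentation** — each sample's reflectance is multiplied by a
  random lognormal factor g (σ = 0.3) and its fluorescence by g^1.7,
  the distance scaling the correction problem is built on. This matters
  greatly: vials are internally homogeneous, so without it the network
  memorizes each training vial's magnitude signature and held-out R
  *decreases* with training (0.97 at 60 epochs → 0.91 at 200); with it the
  mapping becomes geometry-invariant and held-out R exceeds 0.999;
- **noise re-sampling** — fresh Gaussian camera noise (σ = 0.004, the
  generator's read-noise level) added to the inputs.

Two numerical choices matter for trainability of rectified regression heads:

- the output layer starts with near-zero weights and bias 0.1, so every
  abundance channel begins alive;
- at a dead output (logit ≤ 0) the one-sided derivative along +z is used
  when it favors reviving the unit (a valid subgradient of the composite
  loss), preventing irreversible channel death — without this, the
  normalized reconstruction term collapses the head onto a single endmember
  early in training.

## ACU-SA

The HU (hyperspectral unmixing) module reuses the encoder trunk with a
single input channel; the decoder is the fixed linear map z ↦ B z. The twin
encoder shares all weights and reads the same logits through a softmax; the
endmember-guidance term scores the K pure endmember spectra against one-hot
targets with softmax cross-entropy (standard negative log-softmax; the
guidance sum is evaluated every batch). Stage-1 loss:

L_HU = (1/2Kσ_EG²) Σ_k CE(twin(Φ_spec,k), k)
     + ‖B z − φ‖²/(2σ_rec²) + log(σ_EG σ_rec),

trained on a pool of synthetic corrected-domain mixtures (B z + ε, sparse
random z, no attenuation) and unit-normalized real unlabeled spectra.
The reconstruction uses the *absolute* abundances against the spectrum at
its natural scale, and each batch additionally rescales its inputs (and
thus targets) by a random lognormal factor. This is deliberate: a
shape-only reconstruction (normalizing both sides) leaves the encoder's
magnitude response completely unconstrained, and the downstream
normalization stage — which must convert spectrum magnitude into
concentration through the frozen encoder — then succeeds or fails depending
on initialization luck. Tying ‖z‖ to the input intensity makes the
composition well-posed; held-out recovery is stable (R 0.90–0.99) across
seed sets where the shape-only variant oscillated between 0.99 and
collapse.

Stage 2 freezes the HU module, attaches the normalization CNN g (four
same-convolutions, channels 16, 16, 8, 1, kernel 5, no residual blocks,
rectified output) in front, and minimizes ([f(g(Φ_fluo, Φ_ref))]₁ − c)² on
labeled pairs, updating only g (with the same geometry/noise augmentation
as ACU-Net). g is initialized near-identity on the fluorescence channel, so
stage 2 starts from the corrected-spectrum stand-in the supervised model
uses (the raw Φ_fluo) rather than an arbitrary function. Only the PpIX634
component is supervised because only PpIX634 labels exist. The corrected
spectrum g(·) is exposed by `predict_acusa` as the model's interpretable
intermediate; `predict_acusa` also reports B ẑ (unit-normalized code) for
the shape-comparison ReMSE metric.

Stage 1 runs at learning rate 10⁻³ (its own default): hotter rates reach a
similar stage-1 loss but can leave the frozen encoder in a regime stage 2
cannot use.

## Baselines and evaluation

PLS (scikit-learn, NIPALS) regresses the concentration on the concatenated
208-feature vector. The naive MLP is 2m → 8 → K → 8 → m with the rectified
K bottleneck supervised as abundances and the final output as an
unstructured reconstruction head, trained with the same homoscedastic loss
and optimizer contracts; its inputs are z-scored with training-set
statistics (a narrow fully connected net does not train on raw intensities
spanning orders of magnitude).

Evaluation always splits by group (vial/sample), never by pixel: groups are
shuffled under the seed and moved to the test side until its pixel count
reaches 15%. Reported metrics: Pearson R (and R²; the two are reported
separately because the literature uses both names for the same column),
RMSE in label units after a single least-squares calibration factor fit on
the training split, reconstruction MSE with both sides unit-normalized, and
the false-positive rate — the fraction of truly PpIX-free spectra whose
predicted PpIX exceeds a tolerance, default 1% of the maximum training-set
prediction (rectified networks never emit exact zeros, so a tolerance is
required; NNLS produces exact zeros and is insensitive to it). The
two-sample Kolmogorov–Smirnov test (scipy) with p < 0.05 is provided for
distribution comparisons.

## Problem sizes used by the test suite and acceptance script

The phantom benchmark runs at its native size (45 vials × 200 pixels,
85/15 split by vial). ACU-Net trains for up to 200 epochs (120 in the test
suite); ACU-SA uses 40 stage-1 epochs on ~8,000 corrected-domain spectra
(5,000 synthetic mixtures + unlabeled pool) and 120 stage-2 epochs.
The stage-1 denoising check runs on a 32-band grid, where the
autoencoder converges tightly in under two minutes; the property it checks
(held-out reconstruction error below the injected noise floor) is
scale-free. The NNLS-vs-oracle comparison uses 200 random instances at the
native m = 104, K = 5.

## Known limitations

- The attenuation model is multiplicative and smooth; none of the methods
  are exercised against non-multiplicative distortions (the paper-world
  failure mode of saturated specular pixels is out of scope).
- The identifiability assumption — all pixels of a vial share one
  underlying pure spectrum — is built into the generator; homogenate
  concentration jitter (5% CV) is the only within-group abundance
  variation.
- ACU-SA's corrected spectrum is constrained only to be non-negative;
  nothing forces it to resemble a physically plausible emission spectrum.
- The numpy training engine is single-threaded; wall-clock budgets, not
  model capacity, set the default channel widths.
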