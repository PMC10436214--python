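# Methods

## Problem and models

The package learns a voxel-wise mapping from FLAIR brain MRI slices to
diffusion scalar maps (FA or MD) using four 2-D translation families.
All images are single-channel slices normalized per volume to [-1, 1];
generators end in tanh so outputs live in the same range.

**pix2pix.** U-Net generator (4×4 stride-2 encoder convolutions with
instance normalization except on the outermost and bottleneck layers;
decoder blocks are nearest-neighbour upsampling followed by a 3×3
convolution, with encoder features concatenated at each resolution) and a
conditional PatchGAN discriminator that scores overlapping patches of the
(source, target) pair. Losses are binary cross-entropy for both networks,
plus an L1 term weighted λ = 100 on the generator. We use
resize-convolution decoders rather than transposed convolutions: the
layer counts and skip structure are identical to the transposed-conv
formulation, and nearest-upsample + conv avoids checkerboard artifacts
while keeping the backprop backend small.

**CycleGAN (paired / unpaired).** Two ResNet encoder-decoder generators
(7×7 stem, two stride-2 downsamplers, 6 residual blocks below 256×256 and
9 at 256×256, two upsamplers) with least-squares adversarial losses and
an L1 cycle-consistency term weighted λ_cyc = 10. Identity loss is not
included. The paired and unpaired variants share architecture; they
differ only in whether source and target slices come from the same
subjects. The discriminators default to the *modified* form: spectral
normalization on every convolution plus additive Gaussian noise
(σ = 0.1) before each layer at training time, plus one-sided label
smoothing (real target 0.9) — three measures against mode collapse, which
otherwise appears when training on anatomically diverse whole-volume
slices.

**Autoencoder.** The pix2pix generator with all skip concatenations
removed and no discriminator, trained with MSE. It is the ablation
showing what the adversarial term and skips contribute; its parameter
count differs from the U-Net by exactly the skip-concatenation input
channels (asserted in the tests).

**Training recipe.** Adam (β₁ = 0.5, β₂ = 0.999) with initial learning
rates 4e-4 (generators, autoencoder) and 1e-4 (discriminators), constant
for the first half of training then decayed linearly to zero; 100 epochs
by default; batch size 8 for pix2pix/autoencoder and 1 for the
CycleGANs; discriminator and generator alternate one update per step,
discriminator first. Desk-scale experiments in the tests shrink epochs,
filters and image size but keep the recipe.

**FID-based epoch selection.** After each epoch the generator translates
a held-out set of source slices; generated and real target sets are
embedded, a Gaussian is fitted to each, and the Fréchet distance
‖μ₁−μ₂‖² + tr(C₁+C₂−2(C₁C₂)^½) is recorded. The epoch with the lowest
FID is selected (ties → earliest) and its parameters restored. The
embedder is injected: production users can plug a pretrained
medical-imaging network; the package ships a frozen random-projection
convolutional embedder (three stride-2 random convolutions, global
mean+std pooling) that is deterministic for a fixed seed.

A caveat the desk-scale experiments make visible: reliable epoch ranking
by FID presumes hundreds of generated and thousands of real images.
With a small holdout (tens of images) the FID curve flattens into noise
once training has roughly converged, and the argmin is close to a random
draw among post-convergence epochs. Estimators therefore expose
``restore_best_epoch``: protocol-faithful restoration is the default,
while small-sample studies (including the reproduction script) may keep
the final model — the linearly annealed learning rate makes late epochs
stable — and read the FID history as a diagnostic instead.

## Numerical backend

No deep-learning framework is used. `flairsyn.nn` implements
reverse-mode layers on numpy arrays: im2col convolutions, instance norm,
leaky ReLU/tanh, nearest upsampling, training-time Gaussian noise, and a
spectral-norm wrapper. Each layer caches forward contexts on a stack and
pops them in backward, so a module may appear several times in one graph
(the CycleGAN cycle) provided backwards run in reverse order of
forwards. Gradients were verified against central finite differences
(tests assert agreement to ~1e-6).

Spectral normalization follows standard practice: one power iteration
per training step with a persistent left-singular-vector estimate; at
evaluation time the stored vector is reused without updating, making
eval-mode forward passes deterministic. The backward pass treats the
estimated σ as a constant (gradient / σ); detaching the iteration
vectors is standard, and we additionally drop the rank-one correction
term, which at these scales has no observable effect on training. The
standalone `spectral_normalize(weight, n_iters)` runs many iterations;
worst-case error over random matrices decays like 1/n_iters, and ~500
iterations guarantee σ of the normalized matrix is 1 ± 1e-3 even when
the top singular values nearly coincide.

## Metrics

* **MSE** — mean squared difference, optionally mask-restricted.
* **PSNR** — 10 log₁₀(L²/MSE) with L the dynamic range (2 for [-1, 1]
  data; for continuous data the gray-level convention L−1 maps to the
  data range). Identical images report +∞.
* **SSIM** — luminance · contrast · structure with the canonical
  components l = (2μxμy+C1)/(μx²+μy²+C1), c = (2σxσy+C2)/(σx²+σy²+C2),
  s = (σxy+C3)/(σxσy+C3), exponents α = β = γ = 1, C1 = (0.01L)²,
  C2 = (0.03L)², C3 = C2/2. Global mode (whole-slice statistics) is the
  default; windowed mode averages per-window SSIM over every window that
  fits, and equals global mode exactly when the window is the whole
  slice.
* **Hist-KL** — KL(P‖Q) in nats between 256-bin histograms over [-1, 1]
  of the real (P) and generated (Q) image. Both histograms are floored
  at ε = 1e-10 and renormalized, so the value is finite and nonnegative,
  zero iff the histograms coincide; low Hist-KL means high
  intensity-distribution similarity. The divergence is implemented in
  its standard nonnegative orientation. Because histograms ignore
  geometry, Hist-KL responds strongly to tissue-proportion errors (a
  generation that doubles the CSF-like area shifts visible mass between
  histogram peaks) while global SSIM, dominated by means and variances,
  moves little — the property the acceptance tests demonstrate. Absolute
  Hist-KL values depend on bin count, range and background handling, so
  only comparisons under a fixed configuration are meaningful.
* **Fréchet distance** — closed form above, via `scipy.linalg.sqrtm`;
  near-singular covariance products get a 1e-6 diagonal jitter with a
  warning.

## Phantom data

Phantoms stand in for clinical cohorts so that every component is
testable with known ground truth. Each subject is an elliptical "head"
whose cross-section shrinks toward the first and last slices: a WM-like
core (normalized elliptical radius < 0.62), a GM-like band outside it,
and a thin CSF-like film (1 voxel at the reference 256-grid resolution,
~1 mm — subarachnoid CSF is a narrow rim in brain-extracted FLAIR) at
the tissue surface; plus quadratic-Bezier "tracts" of distinct intensity
rasterized inside the WM core. Class intensity bands do not overlap and
are ordered CSF < WM < tract < GM in source intensity (CSF suppressed
and GM brightest, as in FLAIR; tracts a distinct band between WM and
GM), so the FA-like and MD-like targets are exact piecewise-linear
functions of source intensity: FA-like enhances tracts and is monotone
over the WM band, MD-like enhances the fluid film. The tract band sits
adjacent to — not inside — the WM range so the FA map's within-WM slope
agrees with its local trend; a smooth regressor then recovers
per-subject WM levels instead of averaging across a sawtooth. Within each band, every subject
occupies its own sub-band anchored at the band top (a per-subject,
per-class "width" draw): class medians genuinely vary across the cohort
— as regional medians do across patients — while the volume maximum, and
hence the per-volume min-max normalization, stays consistent, keeping
the normalized source-to-target mapping a single learnable function.
Anchoring at the top matters: a sub-band that shifted all classes
proportionally would be cancelled by the normalization and leave the
cohort without usable between-subject variation. Additive target noise (truncated
to keep values in (0, 1]) is optional. The mid-volume tissue fraction is
controlled to the configured range by construction (target fraction
sampled from the middle half of the range, one corrective rescale
against rasterization error).

What the phantoms do **not** emulate: MRI physics (bias fields, k-space
artifacts, partial voluming), registration warping, lesions, anatomical
variability beyond ellipse geometry and tract placement. Passing
phantom-based tests therefore demonstrates that the machinery learns an
attainable mapping and that the metrics order models correctly — not
clinical-grade synthesis quality.

Default cohort geometry is the 256 × 256 × 55 reference grid; tests and
the acceptance script use 32 × 32 × 12 with 6–12 subjects, 20 epochs and
16 base filters so the full pipeline runs in minutes on one CPU. The FID
holdout scales accordingly (16 images from 4 subjects instead of 256
from 9).

## Preprocessing conventions

"Tissue" means strictly nonzero voxels of the pre-normalization volume
(brain-extracted background is exactly zero). The slice filter keeps
slices with at least 15 % tissue, boundary inclusive; it is computed on
the source (FLAIR-like) volume and the same indices are applied to the
targets. Normalization is per-volume min-max to [-1, 1] (per-slice
scaling would destroy inter-slice contrast). Splits are patient-disjoint
with train size ⌊0.8 N⌋; randomness acts on the sorted subject list
under an explicit seed. For unpaired training the training subjects are
halved (sizes differ by ≤ 1) so source and target slices come from
different patients. The FID holdout draws n images from exactly k
training subjects (each chosen subject contributes ≥ 1 slice) and those
slices never enter the gradient stream.

## Regional analysis

GM/WM masks restrict all four metrics to region-interior voxels
(histograms are rebuilt from masked voxels, not post-hoc restricted).
Per-slice profiles skip slices with fewer than 8 in-region voxels —
image statistics on smaller samples are meaningless. Regional medians
are per-volume scalars over mask-interior voxels; Pearson correlation
(two-sided p from the t distribution with n−2 df) compares real vs
synthetic medians across subjects, requiring n ≥ 3.

## Design notes and limitations

* The experiment orchestrator fans one global seed out to fixed named
  sub-seeds (data / split / FID / training) so randomness sources are
  isolated and runs are exactly reproducible.
* `TrainingData` carries assembled slice arrays; the estimators and the
  orchestrator do the manifest/split-to-array assembly, keeping the
  training loops free of I/O.
* Checkpoints are per-epoch `.npz` parameter dumps; reloading epoch k
  reproduces the logged epoch-k validation loss exactly.
* The PatchGAN defaults to the canonical 3-downsampling (70×70 receptive
  field) configuration and shrinks automatically for inputs below 32 px.
* 2-D slice models only; no 3-D context, no perceptual losses, no
  gradient penalty. Real-data preprocessing (brain extraction, bias
  correction, atlas registration) is out of scope — inputs are assumed
  brain-extracted and co-registered.
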