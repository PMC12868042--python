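# Methods

`phantomforge` turns noise-free, piecewise-constant digital phantoms into
patient-realistic CT and MRI volumes by unpaired style transfer, and provides
the full evaluation machinery — paired similarity, unpaired realism
statistics, and dose-volume-histogram summaries — needed to use such volumes
as validation test-beds for cross-modality synthesis models.

## The problem

Digital anthropomorphic phantoms give perfectly aligned multimodal anatomy
with known ground truth, but their images are unrealistic: each tissue is a
single constant intensity, so the volume's histogram has a handful of
discrete peaks, there is no noise, no texture, and no scanner response.
Models validated only on such data overestimate their real-world accuracy.
The pipeline here maps the phantom domain onto the patient domain *without
paired examples*, preserving the phantom's geometry (which is the whole point
— the aligned labels remain valid) while acquiring patient-like intensity
statistics.

## Translation model

Two generator/discriminator pairs form a cycle-consistent adversarial
translator. Generators are ResNet encoder–decoders: a 7×7 stem, two stride-2
encoding convolutions, `n_res_blocks` residual blocks, two decoding stages of
bilinear 2× upsampling + 3×3 convolution (upsample-then-convolve avoids
checkerboard artifacts), reflection padding throughout, instance
normalization, and a tanh head so outputs stay in (−1, 1). Discriminators
are 70×70 PatchGANs: five 4×4 convolutions with strides (2, 2, 2, 1, 1) and
padding 1 ending in a sigmoid map; on a 256×256 input the map is 30×30 and
each unit's receptive field is 70×70 by the standard recurrence
r_in = (r_out − 1)·s + k.

The generator objective for the phantom→patient direction G is

    L(G) = λ_adv · L_GAN + λ_cyc · (L_cyc_fwd + L_cyc_bwd)
         + λ_int · L_int + λ_gdl · L_gdl

with binary-cross-entropy adversarial loss L_GAN = mean(−log D(G(x)))
(ε = 1e−7 clamp inside every log), L1 cycle terms in both directions, an L1
intensity loss |G(x) − x| anchoring organ intensities to the phantom, and a
gradient-difference loss that penalizes squared differences between the
absolute one-pixel horizontal/vertical gradients of input and translation
(so it is invariant to constant shifts). The discriminator loss is halved,
L(D) = ½[BCE(1, D(real)) + BCE(0, D(fake))], which balances generator and
discriminator learning; at the uninformative fixed point D ≡ ½ it equals
ln 2 exactly, a property the tests assert. Discriminators train against a
fake drawn from a 50-image history buffer: once full, each new fake either
replaces a random stored image (which is returned) or is returned directly,
each with probability ½.

Defaults follow standard unpaired-translation practice: λ_cyc = 10,
λ_adv = 1, generator learning rate 2e−4, Adam with β₁ = 0.5, batch size 1,
constant learning rate. λ_int, λ_gdl and the discriminator learning rate are
the tunable knobs (defaults 1, 1, 2e−5). At every iteration each of the four
networks is updated independently: each generator differentiates its full
composite objective w.r.t. its own weights with the other networks frozen
(the shared cycle terms therefore contribute gradients to both generators,
once in each generator's own update).

The networks are implemented directly on numpy arrays shaped (C, H, W) with
analytic backward passes for every layer (convolution via im2col, exact
adjoints for reflection padding and bilinear upsampling, the standard
normalization backward for instance norm). The test suite verifies every
layer's input and parameter gradients against central finite differences,
and end-to-end training is bit-reproducible for a fixed config seed. Width
and depth are configurable, so the same code expresses the paper-scale
network (9 residual blocks, 64 base filters, 256×256 inputs, 150 epochs) and
the desk-scale network the tests train (1 block, 8 filters, 64×64, 30
epochs). The PatchGAN accepts inputs down to 24 px (below its 70 px nominal
receptive field every map unit simply sees the whole patch), which lets the
smoke-scale 64×64 configuration run unchanged.

## Data preparation and patching

CT volumes are clipped to [−1000, +1047] HU; a per-slice body mask is built
by thresholding at −110 HU, binary hole filling, a Sobel boundary-band
refinement that reseals single-pixel leaks before re-filling, and largest
connected component; background is forced to −1000 HU (0 for MRI). All
images are rescaled linearly to [−1, +1] — CT with the fixed clip range, MRI
with its per-volume (min, max), recorded for exact inversion; generator
overshoots are clamped before denormalizing.

Training patches are drawn on a stride lattice (origins 0, s, 2s, …, plus a
clamped final origin at dim − patch at the far edge), a fixed number per
slice without replacement, optionally filtered to ≥ 20 % body-mask coverage.
Inference tiles every axial slice deterministically with the same lattice —
for 348×348 slices, 220×220 patches, stride 64 this is {0, 64, 128}²: nine
patches covering the slice exactly (128 + 220 = 348). Patches are
bilinear-resized to the network input size (256 nominal), translated,
resized back to native patch geometry, mapped back to physical units, and
fused by averaging overlaps ("mean patch fusion"). Fusion of pass-through
predictions is bit-exact; with the 220↔256 resize cycle the reconstruction
error on band-limited content is below 2 % RMS of the dynamic range.

## Synthetic phantoms

The generator module stands in for licensed anthropomorphic phantom
libraries at desk scale. Anatomy is analytic: an elliptical body cylinder
containing two lungs, a liver, spine + ribs, an aorta and bowel loops, with
seeded jitter of positions and radii. Default grid 20×160×160 at
2 × 1.0625 × 1.0625 mm³ (the in-plane patient spacing the pipeline targets).
CT numbers come from per-tissue linear attenuation coefficients at 120 keV
via HU = 1000·(μ − μ_water)/μ_water with μ_water = 0.1615 cm⁻¹ (only the
ratio matters); MRI intensities are a per-tissue lookup with T1-weighted
gradient-echo-like contrast. CT and MRI render from one label map, so the
pair is voxelwise co-registered by construction, and each rendered volume
has at most one intensity per label — reproducing the discrete-histogram
premise that makes raw phantoms unrealistic.

Patient-like counterparts add, in order: a smooth multiplicative bias field
(Gaussian-filtered white field, σ = 24 voxels, amplitude 5 % on the offset
from background), optional smooth per-organ texture, and correlated Gaussian
noise (Gaussian-filtered white noise renormalized to `noise_sigma`; default
20 HU at correlation length 1 voxel — a plausible abdominal CT noise level).
What this emulates is the *statistical* gap between phantom and patient
images: noise magnitude and texture, histogram spread, smooth intensity
inhomogeneity. What it does not emulate: scanner physics (beam hardening,
scatter, k-space artifacts), true anatomical texture, lesions, motion. Tests
passing on these fixtures therefore demonstrate that the pipeline's
machinery is correct and that the translator can close a known, synthetic
domain gap — not that it reproduces clinical image quality.

## Evaluation machinery

Paired (slice-aligned, generated vs reference): MAE; SSIM (Gaussian window
σ = 1.5, K1/K2 = 0.01/0.03, data range 2047 for CT, per-volume for MRI);
FSIM implemented from its definition (log-Gabor phase congruency over 4
scales/4 orientations, minimum wavelength 6, multiplier 2, σ_f/f = 0.55,
Scharr gradient magnitude, constants T1 = 0.85, T2 = 160 on a 0–255 scale);
edge preservation and generation ratios EPR = |EM_orig ∩ EM_gen|/|EM_orig|
and EGR = |EM_gen|/|EM_orig| from Canny maps (σ = 1.0, hysteresis at
10 %/20 % of each image's dynamic range — recorded in every report; slices
with empty reference edge maps are excluded from the EPR/EGR averages and
counted); center-patch perceptual distance through a pluggable LPIPS-style
backend (no pretrained weights ship with the package; without a backend the
field is reported unavailable); and PSNR/NCC/RMSE plus per-channel MAE for
synthetic-CT validation, with air/soft/bone channels thresholded at
−200/+200 HU (configurable). Volume scores are means of per-slice scores.
Every scalar metric is checked against an independently coded brute-force
loop implementation (FSIM to 1e−3, the rest to 1e−6).

Unpaired (cohort realism): noise magnitude as the standard deviation inside
a large homogeneous organ (liver); the radial noise power spectrum — per
slice mean-subtraction, 2D FFT, |·|²·ΔxΔy/(NxNy), slice-averaged, binned
into equal-width annuli up to the Nyquist frequency with the DC component
excluded and empty bins dropped — compared between cohorts by Pearson
correlation; and HistCC, the Pearson correlation between cohort-mean density
histograms (CT: fixed 10 HU bins over the clip range; background excluded by
default so the air peak does not dominate). A helper places the 64×64×20
default ROI at the deepest point of a mask.

Dosimetry: the DVH is the empirical cumulative curve over masked voxels
(equal weight, no partial-volume interpolation), and D_p% is the largest
dose d with V(d) ≥ p/100 — the empirical (100−p)th percentile with the
higher-value tie convention, matching the verbal definitions of D95 (minimum
dose covering 95 % of a target) and D2 (dose to the most exposed 2 %). Plan
comparisons report Δ = recalculated − reference per structure, with relative
error against the prescribed dose for targets and against the reference-plan
metric for organs at risk; zero denominators report the error as missing.

## Numerical and design choices

- Axis convention (slice, row, col), 0-based; resampled in-plane size is
  round-half-away-from-zero of the physical extent ratio (370 px @ 1 mm →
  348 px @ 1.0625 mm); bilinear for scalars, nearest for labels.
- Stride must not exceed patch size in inference tiling (coverage would
  gap); training extraction has no such constraint.
- Model selection by visual inspection is replaced by per-epoch checkpoints
  plus the recorded loss history; any checkpoint can be scored with the
  paired metrics on a held-out phantom.
- NaN in any loss component aborts training naming the component.
- Checkpoints are single-file NPZ containers with the config embedded.
- Degenerate inputs fail loudly: empty masks, empty cohorts, zero-variance
  NCC inputs and empty reference edge maps raise (or are reported missing in
  summaries), never silently coerced to 0.

## Problem sizes in the test suite

The suite trains the desk-scale configuration twice (λ_int 0 vs 100; 16
phantom and 16 degraded 64×64 patches from a 4-slice phantom, 30 epochs,
seed 7) to demonstrate that cycle loss falls below half its first-epoch mean
and that a large intensity weight anchors the translation to the input.
Synthetic fixtures elsewhere use a 6×96×96 phantom. These sizes were chosen
so the entire suite, including both trainings, completes in minutes on a
single CPU while still exercising every code path of the paper-scale
configuration.

## Known limitations

- No GPU path; the numpy implementation is for desk-scale experiments and
  correctness verification, not 150-epoch clinical-resolution training.
- The MRI phantom is an intensity lookup, not a sequence simulation; bias
  handling and MRI standardization across patients are out of scope.
- No DICOM/RT-STRUCT I/O (NIfTI and MetaImage only); no 4D volumes.
- Dose grids are consumed, never computed: treatment-planning recalculation
  lives outside the package.
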