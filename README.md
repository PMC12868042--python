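# phantomforge

Patient-realistic digital phantoms by unpaired style transfer, with the full
evaluation stack needed to trust them.

Digital anthropomorphic phantoms provide perfectly co-registered multimodal
anatomy (CT + MRI from one label map) with known ground truth — ideal
test-beds for cross-modality synthesis models in radiotherapy — but their
images are piecewise-constant and noise-free, with discrete intensity
histograms that look nothing like patient data. `phantomforge` closes that
gap: it trains a CycleGAN (two ResNet generators G: X→Y and F: Y→X, two
70×70 PatchGAN discriminators) on unpaired patches from the phantom domain X
and the patient domain Y, minimizing per generator

```
L(G) = λ_adv·L_GAN + λ_cyc·(L_cyc(XY) + L_cyc(YX)) + λ_int·L_int + λ_gdl·L_gdl
```

with BCE adversarial loss L_GAN = mean(−log D_Y(G(x))), L1 cycle-consistency
in both directions (λ_cyc = 10), an L1 intensity loss anchoring organ
intensities to the phantom, and a gradient-difference loss preserving tissue
boundaries; discriminators minimize L(D_Y) = ½[BCE(1, D_Y(y)) +
BCE(0, D_Y(G(x)))] with fakes drawn from a 50-image history buffer.
Inference is patch-based: each axial slice is tiled deterministically
(a 348×348 slice yields nine 220×220 patches at stride 64), patches are
resized to the 256×256 network input, translated, mapped back to the
physical range ([−1000, +1047] HU for CT) and fused by averaging overlaps.

The networks and their training loop are implemented directly on numpy
arrays with analytic gradients (finite-difference-verified in the test
suite), so desk-scale experiments run reproducibly on one CPU; width, depth
and input size are configurable up to the nominal scale (9 residual blocks,
64 base filters, 256×256 inputs).

Beyond translation, the package provides:

- **synthetic phantoms** — analytic abdominal label maps (body, lungs,
  liver, bones, aorta, bowel) rendered to CT via μ(120 keV) → HU and to MRI
  via tissue lookup, plus patient-like degradations (correlated noise, bias
  field, texture) so every stage is testable without any data download;
- **preprocessing** — CT clipping, body masking (threshold −110 HU, hole
  filling, Sobel boundary refinement, largest component), background
  suppression, invertible [−1, +1] normalization;
- **paired metrics** — MAE, SSIM, FSIM, Canny edge preservation/generation
  ratios (EPR/EGR), center-patch LPIPS (pluggable backend), PSNR/NCC/RMSE
  and per-channel (air/soft/bone) MAE;
- **unpaired metrics** — liver noise magnitude, radial noise power spectrum
  with Pearson comparison, cohort-histogram correlation (HistCC);
- **patient-specific phantoms** — label map + tissue table → piecewise-
  constant CT in patient geometry;
- **dosimetry** — empirical DVH curves and D95% / D2% summaries with
  Δ(recalc − ref) and relative errors.

## Worked example

```python
import numpy as np
from phantomforge.phantoms import (PhantomSpec, DegradationSpec, default_tissue_table,
                                   make_labels, render_ct, degrade, ORGAN_LABELS)
from phantomforge.metrics import evaluate_paired_volumes, noise_magnitude, hist_correlation
from phantomforge.dosimetry import dvh, d_percent
from phantomforge.volumes import DoseGrid

labels = make_labels(PhantomSpec(shape=(6, 96, 96), seed=3))
ct = render_ct(labels, default_tissue_table())          # noise-free phantom CT
patient_like = degrade(ct, DegradationSpec(noise_sigma=25.0), seed=11)

report = evaluate_paired_volumes(patient_like, ct)
for k in ("mae", "ssim", "fsim", "epr", "egr"):
    s = report.summary[k]
    print(f"{k.upper():5s} {s['mean']:7.3f} +/- {s['sd']:.3f}")

liver = labels.labels == ORGAN_LABELS["liver"]
print(f"liver noise magnitude: {noise_magnitude(patient_like, liver):.1f} HU")

dose = DoseGrid(np.clip(np.random.default_rng(0).normal(43.0, 1.0, ct.shape), 0, None),
                ct.spacing_mm)
curve = dvh(dose, liver)
print(f"liver D95%: {d_percent(curve, 95):.2f} Gy   D2%: {d_percent(curve, 2):.2f} Gy")
```

prints

```
MAE    36.717 +/- 2.063
SSIM    0.616 +/- 0.023
FSIM    0.923 +/- 0.020
EPR     0.886 +/- 0.019
EGR     0.997 +/- 0.004
liver noise magnitude: 30.8 HU
liver D95%: 41.33 Gy   D2%: 45.00 Gy
```

Reading the numbers: the degradation added ~25 HU of correlated noise plus a
smooth bias field, so the patient-like volume deviates from the phantom by
37 HU on average while keeping its structure (FSIM 0.92, EPR 0.89); EGR ≈ 1
means almost no spurious edges; the liver's measured noise (30.8 HU) is the
injected noise plus the bias field's contribution; and for a synthetic
1-Gy-wide dose around 43 Gy, 95 % of the liver receives at least 41.3 Gy and
its hottest 2 % receives 45.0 Gy.

The same stages are scriptable from the shell:

```sh
phantomforge simulate --seed 7 --out-dir sim/
phantomforge preprocess --modality ct --in sim/patientlike_ct.nii.gz --out prep.nii.gz
phantomforge train --config cfg.yaml --domain-x sim_x/ --domain-y sim_y/ --out run/
phantomforge predict --ckpt run/epoch_030.npz --in sim/ct.nii.gz --out realistic.nii.gz
phantomforge evaluate paired --gen realistic.nii.gz --ref sim/ct.nii.gz --out report.json
phantomforge dvh --dose dose.nii.gz --mask gtv.nii.gz --out dvh.json
phantomforge run --config examples/demo.yaml --out out/ --seed 1   # end-to-end smoke

```

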