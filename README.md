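# rodentmri

Preprocessing toolkit for small-animal (rodent and other small-mammal)
brain MRI. Preclinical scans are small, anisotropic, heavily
bias-corrupted at high field, and poorly served by human-brain defaults;
this package implements the standard preprocessing chain natively in
Python — no external neuroimaging binaries — and validates every stage on
synthetic head phantoms whose ground truth is known by construction.

What it does:

- **Bias-field correction** — the log-intensity inside the head is fitted
  as a low-order spatial polynomial (the log bias) plus per-tissue-class
  offsets, so the smooth field is separated from the anatomy's own
  contrast; `corrected × field` reconstructs the input exactly.
- **Brain extraction** — histogram-valley thresholding, morphological
  cleanup, largest 6-connected component, hole filling; plus a per-
  threshold **mask-quality report** (volume, right–left /
  antero-posterior / inferior–superior extents, and the Pearson
  correlation of the mask with its reflection across the estimated
  mid-sagittal plane) to tune thresholds without repeated visual checks.
- **Registration** — rigid and full-affine maximisation of normalised
  mutual information, NMI = (H(A)+H(B))/H(A,B), over a multiresolution
  pyramid; multi-level cubic B-spline free-form deformation with a
  0.4×spacing displacement cap guaranteeing a positive-Jacobian
  (diffeomorphic) field; per-slice 2D nonlinear registration for EPI
  distortion; transform composition, inversion, and one-big-step
  application (a single interpolation through an arbitrary chain).
- **Group templates** — iterative averaging/registration with increasing
  degrees of freedom (centroid → rigid → affine → nonlinear), yielding a
  study template and per-subject transform chains.
- **BOLD & coregistration pipelines** — slice-timing correction, rigid
  realignment to the first volume, temporal mean; anatomical↔modality
  alignment with optional rigid step and per-slice distortion correction;
  anatomical-to-template chains and their inverses.
- **FAIR ASL quantification** — per-voxel magnitude inversion-recovery
  fits `|M0 (1 − 2α e^{−TI/T1})|` for paired selective/nonselective
  series, and CBF maps via `CBF = 6000 λ (1/T1_sel − 1/T1_ns)`
  (ml/100g/min, λ = 0.9 ml/g default), with regional boxplot summaries.
- **Evaluation** — Dice similarity `2|A∩B|/(|A|+|B|)`, per-region over
  atlas labels.

All I/O is NIfTI-1 (plain or gzipped), tables are CSV/pandas, transform
chains are JSON manifests. See `docs/methods.md` for the models,
assumptions and numerical choices.

## Worked example

Generate a bias-corrupted phantom head, correct it, extract the brain,
report mask quality, and recover a known rigid motion:

```python
import numpy as np
from rodentmri.phantom import (PhantomSpec, make_head_phantom,
                               make_bias_field, apply_known_transform)
from rodentmri.images import VolumeImage
from rodentmri.preprocess import (correct_bias, extract_brain,
                                  brain_segmentation_report)
from rodentmri.register import register_rigid
from rodentmri.transforms import rigid_from_params, rigid_params_from_matrix
from rodentmri.evaluate import dice

spec = PhantomSpec(seed=0)                      # 64x64x32, 0.2x0.2x0.5 mm
head, truth = make_head_phantom(spec)
bias = make_bias_field(spec, amplitude=0.3)     # smooth multiplicative field
observed = VolumeImage(head.data * bias.data, head.affine)

result = correct_bias(observed, poly_order=3)
mask = extract_brain(result.corrected, "auto")
print(f"brain mask: {mask.count()} voxels, "
      f"Dice vs truth = {dice(mask, truth.brain_mask):.4f}")

report = brain_segmentation_report(result.corrected, [0.3, 0.4, 0.5])
print(report.round(3).to_string(index=False))

center = head.grid.world_center()
true_move = rigid_from_params([0, 0, 7.0, 1.0, -0.6, 0.5], center=center)
moved, _ = apply_known_transform(head, true_move, truth)
estimate = register_rigid(head, moved)
print("recovered:", np.round(rigid_params_from_matrix(estimate, center=center), 3))
```

Output:

```
brain mask: 18448 voxels, Dice vs truth = 0.9993
 threshold  volume_mm3  ap_mm  rl_mm  is_mm  symmetry_r
       0.3      368.96    8.8    8.0   10.0         1.0
       0.4      368.96    8.8    8.0   10.0         1.0
       0.5      348.64    8.8    8.0   10.0         1.0
recovered: [ 2.00e-03 -1.30e-02  6.87e+00  9.98e-01 -6.02e-01  5.00e-01]
```

The extracted mask overlaps the ground-truth brain at Dice 0.999; the
report shows a 369 mm³ brain, 8 mm wide × 8.8 mm long × 10 mm high,
perfectly mirror-symmetric (symmetry_r = 1.0); and the simulated 7° /
(1.0, −0.6, 0.5) mm rigid motion is recovered to about a tenth of a
degree and a few microns.

A command-line interface mirrors the library
(`rodentmri phantom|bias|mask|report|register|template|coregister|`
`template-register|cbf|dice`); run `rodentmri --help`.

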