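# fatnav

Rigid registration and motion quantification for prospective fat-navigator
(FatNav) motion correction in brain MRI — with a fully synthetic,
ground-truthed validation pipeline.

Head motion is a leading cause of unusable brain MRI, and at ultra-high
field only *prospective* correction — updating the scanner's coordinate
frame during the scan — can rescue slice-by-slice acquisitions. FatNavs
make this possible without extra hardware: rapid, low-resolution (2 mm)
images of the head's subcutaneous fat are interleaved into the host
sequence every N k-space lines, registered online to a reference, and the
detected pose update is fed back to the sequence. This package provides
the offline-testable core of such a system, for MR-physics and image-
analysis researchers who want to develop, tune or validate the
registration and evaluation machinery without scanner access:

- **Rigid-transform algebra** (Z-Y-X rotations + translations about the
  volume centre) and motion scores: the worst-case displacement of a point
  on a 64 mm head-radius sphere, `ΔR + √(Δx²+Δy²+Δz²)` with
  `ΔR = 2·64·sin(θ/2)`, and the residual motion score
  `score(T_detected · T_ground_truth⁻¹)` as the registration-error metric.
- **Similarity metrics**: the concordance correlation coefficient
  `ρ_C = 2·s_xy / (s_x² + s_y² + (x̄−ȳ)²)` used as the registration cost,
  plus SSIM and RMSE for comparison, and single-parameter metric profiles.
- **Registration**: a fast scanner-style algorithm — bright sub-volume
  selection, centroid initialisation, coarse-then-fine 1-D grid searches
  around each principal axis in turn, maximising summed CCC — plus an
  exhaustive 6-D grid-search oracle for verification.
- **Synthetic benchmarks**: shell phantoms emulating fat-only head images,
  subjected to uniformly random rigid transforms in ±5/±10/±15
  degree/voxel ranges with exactly known ground truth (330 pairs per range
  at protocol defaults).
- **Image quality**: variance-of-Laplacian sharpness, corrected/uncorrected
  sharpness ratios, and 75%→25% edge-profile widths.
- **A correction-loop simulator**: navigators every N×TR, frame updates per
  policy (every measurement / every other / none), and the alternating
  corrected/uncorrected measurement paradigm.

## Worked example

```python
import numpy as np
from fatnav import (
    RegistrationConfig, RigidTransform, apply_transform_imagespace,
    generate_phantom, motion_score, register, residual_motion_score,
)
from fatnav.synthetic import default_phantom_specs

# a 2 mm navigator-like phantom and a known head movement
phantom = generate_phantom(default_phantom_specs(1, shape=(64, 64, 64), seed=7)[0])
truth = RigidTransform(rot_deg=(4.0, -2.0, 3.0), trans_mm=(6.0, -4.0, 2.0))
moved = apply_transform_imagespace(phantom, truth)

result = register(phantom, moved, RegistrationConfig())
print("true motion score :", round(motion_score(truth).score, 2), "mm")
print("detected transform:", np.round(result.transform.rot_deg, 2),
      np.round(result.transform.trans_mm, 2))
print("residual score    :", round(residual_motion_score(result.transform, truth), 2), "mm")
```

prints

```
true motion score : 13.45 mm
detected transform: [ 3.6 -2.   3. ] [ 6.  -3.9  2. ]
residual score    : 0.55 mm
```

The true movement would displace points on the head by up to ~13.5 mm; the
sequential CCC search recovers the transform to a residual motion score of
0.55 mm — about a quarter of a voxel — and that residual, not the raw
parameter error, is the quantity that matters for how well a prospective
update would re-align the acquisition.

The same machinery is available from the shell:

```bash
fatnav generate-phantom --shape 64,64,64 --seed 7 --out ref.nii.gz
fatnav register --fixed ref.nii.gz --moving moved.nii.gz --out transform.json
fatnav benchmark --n-volumes 5 --n-transforms 4 --ranges 5 --out bench/
fatnav simulate --seed 3 --out sim/
```

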