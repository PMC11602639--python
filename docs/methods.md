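# Methods

## Problem setting

Prospective motion correction keeps a brain acquisition aligned with a
moving head by updating the scanner's coordinate frame *during* the scan.
The pose estimates come from fat navigators (FatNavs): rapid, low-resolution
(2 mm isotropic) 3D images of the head's subcutaneous fat, acquired
interleaved with the host sequence — one navigator every N k-space lines,
i.e. one motion update every N × TR. Because fat-selective excitation
leaves the water signal untouched, the navigators cost only their own
acquisition time (1.23 s each at the protocol defaults).

This package implements everything around that loop that can be built and
validated offline: the rigid-transform algebra and motion scores, the
similarity metrics and the sequential-axis registration algorithm, a
ground-truthed synthetic benchmark, sharpness metrics for judging corrected
images, and a measurement-level simulator of the correction loop itself.

## Rigid transforms

A transform is six parameters: rotations (rz, ry, rx) in degrees and
translations (tx, ty, tz) in mm. The forward action on a point `p` in mm
relative to the volume centre is **translate then rotate**:

    T(p) = R (p + t),   R = Rx · Ry · Rz

with extrinsic rotations applied about Z first, then Y, then X
(counterclockwise positive looking down each axis). This mirrors the way a
benchmark image is produced — shifted first, then rotated axis by axis —
so a perfect registration reproduces the stored ground-truth parameters
identically, with no convention conversion in between. Composition and
inversion go through 4×4 homogeneous matrices (column vectors, left
action); Euler angles are recovered with the same z-y-x convention. The
rotation centre is the volume's geometric centre, tagged on the transform
so transforms with different centre conventions cannot be combined
silently.

### Motion score

A single transform is summarised by the worst-case displacement it causes
on a 64 mm-radius sphere (a proxy for the adult head):

    score = ΔR + sqrt(Δx² + Δy² + Δz²),   ΔR = 2 · 64 mm · sin(θ/2)

where θ is the total rotation angle (from the trace of R). The identity
`max |R·p − p| over |p|=r  =  2r·sin(θ/2)` is exact — the maximum is
attained on the rotation axis's equator — and is verified in the tests
against brute-force maximisation over ≥10⁵ sampled sphere points.
Registration error against a known ground truth is the **residual motion
score**: the motion score of `detected ∘ ground_truth⁻¹`, which is zero iff
the detection is exact.

## Similarity metrics

The registration cost is the concordance correlation coefficient

    ρ_C = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²)

with population (1/n) moments — fixed so the hand-computed test values are
exact. CCC behaves like Pearson correlation additionally penalised for
mean/variance disagreement; empirically its profile along each motion
parameter has a single sharp peak at alignment, with fewer spurious local
extrema than SSIM and a larger dynamic range than RMSE (the package's
`metric_profile` reproduces this comparison on phantoms, and a test asserts
the local-extrema ordering). SSIM is delegated to
`skimage.metrics.structural_similarity` (Gaussian window σ = 1.5, width 11,
C1 = (0.01L)², C2 = (0.03L)² with L the reference's dynamic range — the
one argument asymmetry among the three metrics); RMSE is the plain
root-mean-square voxel difference.

## Synthetic benchmark

Real navigators cannot ship with the repository, so the generator builds a
head phantom that keeps the single property registration depends on: a
bright peripheral fat shell around a dark interior. Concretely: the region
between two concentric ellipsoids (outer semi-axes ≈ 55/45/38 mm, shell
≈ 7 mm thick, jittered per volume), plus 2–4 bright spherical blobs placed
on the shell as stand-ins for facial/neck fat — these break the shell's
near-symmetry and make rotations identifiable. The anatomy is scaled as
min(FOV)/140 so the ~116 mm head diameter sits inside the volume with a
realistic margin. The structure is band-limited with a 2 mm Gaussian
(a reconstructed navigator is not voxel-sharp) and noise, when enabled, is
Rician — the magnitude of signal plus complex Gaussian noise — matching
magnitude MR statistics and keeping intensities non-negative.

The benchmark protocol applies uniformly random rigid transforms to each
phantom: each rotation Uniform(−r, +r) degrees and each translation
Uniform(−r, +r) voxels (converted to mm via the spacing), all six drawn
independently and applied simultaneously, with r ∈ {5, 10, 15}. The
default protocol is 33 volumes × 10 transforms = 330 pairs per range. The
reference of every pair is the untransformed phantom. Transform
application resamples the volume once with a cubic spline under the
composed translate-then-rotate map (sequential per-axis resampling would
realise the same geometry with more interpolation blur), crops to the
input shape, and fills voxels whose source fell outside the grid with
Gaussian noise matched to the mean/SD outside the head in the reference
(head mask: Otsu threshold + one-voxel dilation). Per-pair RNG substreams
are derived from the top-level seed by `SeedSequence(seed, spawn_key)`, so
any single pair is reproducible in isolation.

What the phantom does *not* emulate: reconstruction artefacts (GRAPPA /
partial Fourier), B0- and flip-angle shading, through-volume anatomy
changes, or real fat-distribution anatomy. Passing the benchmark therefore
demonstrates the correctness of the geometry, metrics and optimiser — not
performance on artefact-laden in vivo navigators.

## Registration

The scanner-oriented algorithm:

1. **Sub-volume selection.** The fixed volume is tiled with non-overlapping
   16³ blocks and the 8 brightest-mean blocks are kept (the fat shell
   carries the signal). Blocks stay 5 voxels clear of the volume boundary:
   the moved image's border regions may contain fill noise where content
   left the grid, and including them measurably corrupts the cost at the
   true transform. Falls back to a whole-volume box (with a warning) for
   volumes with no bright block.
2. **Initialisation.** Translation starts at the intensity-centroid
   difference between the volumes; rotations start at zero.
3. **Sequential 1-D searches.** Each parameter in turn — tx, ty, tz, rz,
   ry, rx — is swept on a coarse grid (2 mm / 2°, spanning ±20 mm around
   the initialisation and ±15°) and then a fine grid (0.1 mm / 0.1°, ±one
   coarse step around the coarse optimum), evaluating the summed CCC over
   the sub-volumes with trilinear interpolation. Ties break toward the
   smaller parameter magnitude, which makes results deterministic.
4. **Passes.** The six sweeps repeat (up to 12 passes) until no parameter
   moves by more than 0.02 mm / 0.02°. The fine step and tolerance matter:
   coordinate descent on the correlated rotation axes converges by
   zigzagging, and with a 0.25-step grid and 3 passes it stalls several
   fine steps short of the optimum (measured: 82% of ±5-range pairs under
   2 mm residual, versus 100% with the adopted settings at ~5 s per 64³
   pair on one core).

Convergence is reported honestly: a result whose per-sub-volume CCC falls
below a configurable floor (default 0.5) is flagged `converged=False`
rather than returned as a silent wrong answer — the sequential-axis search
is known to degrade for large rotations about oblique axes, since no single
axis sweep can reduce such an error alone.

`register_oracle` provides the verification path: exhaustive evaluation of
the metric over a full 6-D parameter grid (refused above 10⁷ combinations),
with the same deterministic tie-break. For translation-only problems with
on-grid shifts the sequential search and the oracle must and do agree
exactly.

Interpolation during search is trilinear; cubic was evaluated and gave no
accuracy benefit at four times the cost. The deliberate asymmetry —
benchmark generation uses cubic, search uses trilinear — mirrors the
constraint that an online implementation favours speed.

## Image-quality metrics

**Variance of Laplacian.** The 2D 5-point stencil [[0,1,0],[1,−4,1],[0,1,0]]
is applied per slice; only the interior-valid region enters the variance,
so constant and affine images give exactly 0. The measure is invariant to
intensity offsets and scales quadratically with intensity, and decreases
strictly under Gaussian blur (asserted for σ = 0–3 px). The corrected/
uncorrected ratio (>1 = improvement) is the headline comparison statistic.
Known caveat: severe ghosting can inflate the variance and mask a
sharpness loss; only blur-monotonicity is claimed. A 3D 7-point variant is
provided but not default (host images are 2D multi-slice).

**Edge-profile width.** For a 1-D profile across a thin dark structure, the
dip is the interior minimum; each flank is normalised between its local
plateau and the dip minimum and the 75% / 25% crossings located by linear
interpolation. The steeper flank's width is reported by default (both on
request). For a sigmoid flank with scale s the width is 2·s·ln 3, which the
tests verify by dense sampling.

## Prospective-loop simulator

Head pose is piecewise-constant — one true pose per measurement, matching
an instructed-motion paradigm where the subject repositions between
measurements; intra-measurement motion is out of scope. Per measurement:

1. the navigator is rendered as the phantom resampled under
   `frame⁻¹ ∘ pose` (the head as seen in the current acquisition frame),
   plus optional Gaussian noise;
2. it is registered to the first (reference) navigator;
3. per the update policy, the detection is composed into the acquisition
   frame — updates take effect at the measurement boundary (the real
   sequence's ~2 ms line-boundary delay is below this model's resolution);
4. the host image is rendered in its governing frame: the corrected frame
   for corrected measurements, the original frame for uncorrected ones.

Under `every_other_measurement` the corrected sum is reference + odd
measurements and the uncorrected sum reference + even, reproducing the
alternating display paradigm; under `every_measurement` both sums cover all
measurements (the uncorrected set is rendered in the identity frame). Fill
noise for each measurement's renders comes from a per-measurement
substream shared by the corrected and uncorrected render, so disabling
correction makes the two sums bitwise identical. The loop is validated in
its perfect-registration limit: supplying the true poses recovers the
zero-motion sum to well below 2% mean absolute error, isolating
registration error as the only approximation in the loop.

## Problem sizes and defaults

The shipped experiments use 64³ (registration benchmark; 2 mm voxels,
matching navigator resolution) and 48³ (simulator) phantoms, 50 benchmark
pairs at the ±5 range and 10 simulator seeds; these sizes give stable
statistics on a single core while exercising every code path. The
navigator-resolution study spans 128×128×88 down to 8×8×8 at fixed FOV.
Elapsed-time columns in benchmark outputs are informational only and are
not asserted in tests — they are hardware-dependent.

## Known limitations

- The sequential-axis search is a limited-range method; ±15-range pairs
  may legitimately fail (flagged via `converged=False`), and oblique-axis
  rotations are its worst case.
- The phantom benchmark validates geometry and optimisation, not
  robustness to reconstruction artefacts or anatomy.
- The simulator operates in image space; k-space effects of mid-acquisition
  pose changes (ghosting) are not modelled.
- SSIM uses the first argument's dynamic range and is therefore not exactly
  symmetric; CCC and RMSE are symmetric.
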