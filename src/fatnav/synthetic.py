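"""Phantom generation and ground-truthed rigid-motion benchmarks.

Real fat navigators are low-resolution (2 mm isotropic) fat-only head images:
a bright shell of subcutaneous scalp fat around a dark interior, over a noisy
background.  The phantom generator reproduces that geometry with an
ellipsoidal shell plus optional blobs standing in for facial fat, so that
registration benchmarks with exactly known ground-truth motion can be built
without any subject data.

The benchmark protocol applies uniformly distributed random rigid transforms
to each phantom — rotations and translations drawn simultaneously from
±5, ±10 or ±15 degrees/voxels — pairing each moved volume with its
untransformed reference and the transform that produced it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .transforms import RigidTransform
from .volume import Volume3D

__all__ = [
    "PhantomSpec",
    "SyntheticPair",
    "generate_phantom",
    "sample_random_transform",
    "apply_transform_imagespace",
    "estimate_background_stats",
    "make_synthetic_dataset",
    "default_phantom_specs",
    "save_dataset",
]

#: Motion ranges used by the benchmark protocol, in degrees (rotations) and
#: voxels (translations), applied simultaneously.
MOTION_RANGES = (5.0, 10.0, 15.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise description for a navigator-like head phantom.

    The shell is the region between two concentric ellipsoids (outer minus
    inner semi-axes, in mm, centred in the volume); blobs are spheres given
    as (center_mm, radius_mm, intensity).
    """

    shape: tuple[int, int, int] = (64, 64, 44)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    outer_semiaxes_mm: tuple[float, float, float] = (55.0, 45.0, 38.0)
    inner_semiaxes_mm: tuple[float, float, float] = (48.0, 38.0, 31.0)
    shell_intensity: float = 100.0
    blobs: tuple = ()
    noise_sd: float = 0.0
    smooth_sigma_mm: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(i >= o for i, o in zip(self.inner_semiaxes_mm, self.outer_semiaxes_mm)):
            raise ValueError("inner semi-axes must be strictly inside outer semi-axes")
        if self.noise_sd < 0 or self.smooth_sigma_mm < 0:
            raise ValueError("noise_sd and smooth_sigma_mm must be non-negative")
        if any(n < 1 for n in self.shape) or any(s <= 0 for s in self.spacing):
            raise ValueError("invalid shape or spacing")


@dataclass(frozen=True)
class SyntheticPair:
    """A reference phantom, its rigidly moved copy, and the true transform."""

    reference: Volume3D
    moved: Volume3D
    ground_truth: RigidTransform
    range_label: float
    pair_id: str = ""

    def __post_init__(self):
        if self.moved.shape != self.reference.shape or self.moved.spacing != self.reference.spacing:
            raise ValueError("moved volume must share the reference's shape and spacing")


def generate_phantom(spec: PhantomSpec) -> Volume3D:
    """Render a shell phantom per ``spec``; deterministic for a fixed seed.

    Noise is Rician (magnitude of the signal plus complex Gaussian noise),
    matching the statistics of magnitude MR images; with ``noise_sd=0`` the
    construction is exact (background 0, shell equal to ``shell_intensity``).
    """
    idx = np.indices(spec.shape, dtype=float)
    center = (np.asarray(spec.shape, dtype=float) - 1.0) / 2.0
    mm = [(idx[a] - center[a]) * spec.spacing[a] for a in range(3)]

    def _ellipsoid(semi):
        return sum((mm[a] / semi[a]) ** 2 for a in range(3)) <= 1.0

    shell = _ellipsoid(spec.outer_semiaxes_mm) & ~_ellipsoid(spec.inner_semiaxes_mm)
    data = np.where(shell, float(spec.shell_intensity), 0.0)
    for center_mm, radius_mm, intensity in spec.blobs:
        r2 = sum((mm[a] - center_mm[a]) ** 2 for a in range(3))
        data[r2 <= radius_mm**2] = float(intensity)
    if spec.smooth_sigma_mm > 0:
        # band-limit the structure, as a real reconstructed navigator is
        data = ndimage.gaussian_filter(data, spec.smooth_sigma_mm / np.asarray(spec.spacing))

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        real = data + rng.normal(0.0, spec.noise_sd, spec.shape)
        imag = rng.normal(0.0, spec.noise_sd, spec.shape)
        data = np.hypot(real, imag)
    return Volume3D(data, spec.spacing)


def sample_random_transform(
    range_deg_vox: float,
    spacing,
    rng: np.random.Generator,
) -> RigidTransform:
    """Draw a uniform random rigid transform from ±range degrees/voxels.

    Each of the three rotation angles is Uniform(−range, +range) degrees and
    each translation Uniform(−range, +range) voxels, converted to mm with the
    per-axis spacing; all six parameters are drawn independently.
    """
    if range_deg_vox <= 0:
        raise ValueError("motion range must be positive")
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
    rot = rng.uniform(-range_deg_vox, range_deg_vox, 3)
    trans_vox = rng.uniform(-range_deg_vox, range_deg_vox, 3)
    return RigidTransform(tuple(rot), tuple(trans_vox * spacing))


def apply_transform_imagespace(
    vol: Volume3D,
    t: RigidTransform,
    bg_mean: float = 0.0,
    bg_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Volume3D:
    """Resample ``vol`` under the rigid motion ``t`` on the same grid.

    The image content is translated and then rotated about Z, Y and X about
    the volume centre (the composed map is applied in a single cubic-spline
    resampling pass), and the output is cropped to the input shape.  Voxels
    whose source location falls outside the input grid are filled with
    Gaussian noise of the given mean and SD, emulating the background outside
    the head in a real navigator.
    """
    if bg_sd < 0:
        raise ValueError("bg_sd must be non-negative")
    spacing = np.asarray(vol.spacing)
    c = vol.center_index
    Rt = t.rotation.as_matrix().T
    # inverse map in index coordinates: in_idx = A @ out_idx + offset
    A = (Rt * spacing[np.newaxis, :]) / spacing[:, np.newaxis]
    offset = c - A @ c - np.asarray(t.trans_mm) / spacing
    out = ndimage.affine_transform(vol.data, A, offset=offset, order=3, mode="constant", cval=0.0)
    outside = (
        ndimage.affine_transform(
            np.ones(vol.shape), A, offset=offset, order=0, mode="constant", cval=0.0
        )
        == 0.0
    )
    if np.any(outside):
        if bg_sd > 0:
            if rng is None:
                rng = np.random.default_rng()
            out[outside] = rng.normal(bg_mean, bg_sd, int(outside.sum()))
        else:
            out[outside] = bg_mean
    return vol.copy_with(out)


def estimate_background_stats(vol: Volume3D) -> tuple[float, float]:
    """Mean and SD of the intensities outside the head.

    The head mask is an Otsu threshold followed by a one-voxel dilation; the
    background is its complement.  Raises if no foreground/background
    separation exists (constant volume) or the background is empty.
    """
    data = vol.data
    if np.ptp(data) == 0:
        raise ValueError("volume is constant; no foreground/background separation")
    mask = data > threshold_otsu(data)
    mask = ndimage.binary_dilation(mask, iterations=1)
    background = data[~mask]
    if background.size == 0:
        raise ValueError("background region is empty")
    return float(background.mean()), float(background.std())


def default_phantom_specs(
    n_volumes: int,
    shape=(64, 64, 44),
    spacing=(2.0, 2.0, 2.0),
    noise_sd: float = 0.0,
    smooth_sigma_mm: float = 2.0,
    seed: int = 0,
) -> list[PhantomSpec]:
    """Per-volume phantom specs with jittered anatomy (head size and blobs).

    Emulates navigators from different subjects/sessions: semi-axes vary a
    few mm between volumes and each head carries 2–4 facial-fat blobs at
    jittered positions, so every reference image is distinct but all share
    the bright-shell/dark-interior structure.
    """
    rng = np.random.default_rng(seed)
    extent = np.asarray(shape) * np.asarray(spacing)
    specs = []
    for i in range(n_volumes):
        # scale the ~116 mm head diameter to sit inside the FOV with margin
        scale = min(extent) / 140.0
        outer = (np.array([55.0, 45.0, 38.0]) + rng.uniform(-3, 3, 3)) * scale
        thickness = (7.0 + rng.uniform(-1.5, 1.5, 3)) * scale
        blobs = []
        for _ in range(rng.integers(2, 5)):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            center_mm = tuple(direction * outer * 0.85)
            blobs.append((center_mm, float(4.0 * scale + rng.uniform(0, 2 * scale)), 120.0))
        specs.append(
            PhantomSpec(
                shape=tuple(shape),
                spacing=tuple(spacing),
                outer_semiaxes_mm=tuple(outer),
                inner_semiaxes_mm=tuple(outer - thickness),
                blobs=tuple(blobs),
                noise_sd=noise_sd,
                smooth_sigma_mm=smooth_sigma_mm,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def make_synthetic_dataset(
    n_volumes: int = 33,
    n_transforms_per_volume: int = 10,
    ranges=MOTION_RANGES,
    base_specs: list[PhantomSpec] | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
    smooth_sigma_mm: float = 2.0,
    shape=(64, 64, 44),
    spacing=(2.0, 2.0, 2.0),
) -> list[SyntheticPair]:
    """Build the randomized-transform benchmark dataset.

    For every motion range, each of ``n_volumes`` reference phantoms is
    subjected to ``n_transforms_per_volume`` independent random transforms,
    giving ``n_volumes × n_transforms_per_volume`` ground-truthed pairs per
    range (330 per range at the protocol defaults of 33 × 10).  The reference
    of each pair is always the untransformed phantom.  Per-pair RNG
    substreams are derived from the top-level seed so any single pair is
    reproducible in isolation.
    """
    if n_volumes < 1 or n_transforms_per_volume < 1:
        raise ValueError("n_volumes and n_transforms_per_volume must be >= 1")
    if base_specs is None:
        base_specs = default_phantom_specs(
            n_volumes, shape=shape, spacing=spacing, noise_sd=noise_sd,
            smooth_sigma_mm=smooth_sigma_mm, seed=seed,
        )
    if len(base_specs) != n_volumes:
        raise ValueError("base_specs length must equal n_volumes")

    references = [generate_phantom(spec) for spec in base_specs]
    pairs: list[SyntheticPair] = []
    for ri, rng_label in enumerate(ranges):
        for vi, ref in enumerate(references):
            try:
                bg_mean, bg_sd = estimate_background_stats(ref)
            except ValueError:
                bg_mean, bg_sd = 0.0, 0.0
            for ti in range(n_transforms_per_volume):
                sub = np.random.default_rng(
                    np.random.SeedSequence(seed, spawn_key=(ri, vi, ti))
                )
                t = sample_random_transform(rng_label, ref.spacing, sub)
                moved = apply_transform_imagespace(ref, t, bg_mean, bg_sd, sub)
                pairs.append(
                    SyntheticPair(
                        reference=ref,
                        moved=moved,
                        ground_truth=t,
                        range_label=float(rng_label),
                        pair_id=f"r{rng_label:g}_v{vi:03d}_t{ti:03d}",
                    )
                )
    return pairs


def save_dataset(pairs: list[SyntheticPair], out_dir: str | Path, seed: int = 0) -> Path:
    """Write a dataset to disk: NIfTI volumes, JSON transforms, CSV manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    seen_refs: dict[int, str] = {}
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["pair_id", "range_label", "reference_path", "moved_path", "transform_path", "seed"]
        )
        for pair in pairs:
            key = id(pair.reference)
            if key not in seen_refs:
                ref_path = f"ref_{len(seen_refs):03d}.nii.gz"
                pair.reference.save(out_dir / ref_path)
                seen_refs[key] = ref_path
            moved_path = f"{pair.pair_id}_moved.nii.gz"
            tfm_path = f"{pair.pair_id}_transform.json"
            pair.moved.save(out_dir / moved_path)
            pair.ground_truth.save(out_dir / tfm_path)
            writer.writerow(
                [pair.pair_id, pair.range_label, seen_refs[key], moved_path, tfm_path, seed]
            )
    return manifest
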