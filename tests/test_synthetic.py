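"""Phantom generation and the randomized rigid-motion benchmark protocol."""

import numpy as np
import pytest
from scipy import ndimage

from fatnav.synthetic import (
    PhantomSpec,
    apply_transform_imagespace,
    default_phantom_specs,
    estimate_background_stats,
    generate_phantom,
    make_synthetic_dataset,
    sample_random_transform,
    save_dataset,
)
from fatnav.transforms import RigidTransform, invert
from fatnav.volume import Volume3D


class TestPhantom:
    def test_noiseless_phantom_is_exact(self, hard_shell_spec):
        vol = generate_phantom(hard_shell_spec)
        values = np.unique(vol.data)
        assert set(values) <= {0.0, hard_shell_spec.shell_intensity}
        assert (vol.data == hard_shell_spec.shell_intensity).any()
        assert (vol.data == 0.0).any()

    def test_same_seed_is_bitwise_deterministic(self):
        spec = PhantomSpec(shape=(24, 24, 18), noise_sd=3.0, seed=11)
        assert np.array_equal(generate_phantom(spec).data, generate_phantom(spec).data)

    def test_fov_to_spacing(self):
        """A 256x256x176 mm FOV sampled on a 128x128x88 grid is 2 mm isotropic."""
        fov = np.array([256.0, 256.0, 176.0])
        shape = (128, 128, 88)
        spacing = tuple(fov / np.asarray(shape))
        assert spacing == (2.0, 2.0, 2.0)
        vol = Volume3D(np.zeros(shape, dtype=np.float32), spacing)
        assert vol.spacing == (2.0, 2.0, 2.0)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="inner"):
            PhantomSpec(outer_semiaxes_mm=(40, 40, 40), inner_semiaxes_mm=(45, 30, 30))
        with pytest.raises(ValueError, match="noise"):
            PhantomSpec(noise_sd=-1.0)

    def test_intensities_non_negative_with_noise(self):
        spec = PhantomSpec(shape=(24, 24, 18), noise_sd=5.0, seed=2)
        assert generate_phantom(spec).data.min() >= 0


class TestRandomTransform:
    def test_parameters_within_range_and_units(self, rng):
        """±5 deg/voxel at 2 mm spacing bounds angles by 5° and shifts by 10 mm."""
        for _ in range(200):
            t = sample_random_transform(5.0, (2.0, 2.0, 2.0), rng)
            assert np.all(np.abs(t.rot_deg) <= 5.0)
            assert np.all(np.abs(t.trans_mm) <= 10.0)

    def test_small_range_approaches_identity(self, rng):
        t = sample_random_transform(1e-9, (2.0, 2.0, 2.0), rng)
        assert t.is_identity(1e-8)

    def test_fixed_rng_state_reproduces(self):
        a = sample_random_transform(5.0, 2.0, np.random.default_rng(9))
        b = sample_random_transform(5.0, 2.0, np.random.default_rng(9))
        assert a == b

    def test_nonpositive_range_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_random_transform(0.0, 2.0, rng)


class TestApplyTransform:
    def test_identity_is_exact(self, small_phantom):
        out = apply_transform_imagespace(small_phantom, RigidTransform.identity())
        assert np.allclose(out.data, small_phantom.data, atol=1e-9)

    def test_shape_and_spacing_conserved(self, small_phantom, rng):
        t = sample_random_transform(10.0, small_phantom.spacing, rng)
        out = apply_transform_imagespace(small_phantom, t, 0.0, 1.0, rng)
        assert out.shape == small_phantom.shape
        assert out.spacing == small_phantom.spacing

    def test_integer_voxel_translation_is_exact_shift(self, hard_shell_spec):
        vol = generate_phantom(hard_shell_spec)
        t = RigidTransform(trans_mm=(2 * vol.spacing[0], 0, 0))
        out = apply_transform_imagespace(vol, t)
        expected = np.roll(vol.data, 2, axis=0)
        expected[:2] = 0.0
        assert np.allclose(out.data, expected, atol=1e-7)

    def test_quarter_turn_about_z_is_axis_permutation(self, rng):
        """A 90° Z rotation of an asymmetric block equals the exact array rotation."""
        block = np.zeros((9, 9, 5))
        block[2:5, 3:8, 1:4] = rng.uniform(1, 2, (3, 5, 3))
        vol = Volume3D(block)
        out = apply_transform_imagespace(vol, RigidTransform((90, 0, 0), (0, 0, 0)))
        assert np.allclose(out.data, np.rot90(block, k=1, axes=(0, 1)), atol=1e-7)

    def test_corner_fill_uses_requested_noise(self, small_phantom, rng):
        t = RigidTransform(trans_mm=(20.0, 0, 0))
        out = apply_transform_imagespace(small_phantom, t, bg_mean=5.0, bg_sd=0.5, rng=rng)
        n_fill = 10 * small_phantom.shape[1] * small_phantom.shape[2]  # 20 mm = 10 voxels
        filled = out.data[:10]
        assert filled.size == n_fill
        assert abs(filled.mean() - 5.0) < 0.05
        assert abs(filled.std() - 0.5) < 0.05

    def test_roundtrip_recovers_interior(self, shell_phantom, rng):
        """Applying t then t⁻¹ to a smooth phantom is near-lossless inside the head."""
        t = RigidTransform((4.0, -3.0, 2.0), (3.0, -2.0, 1.5))
        back = apply_transform_imagespace(
            apply_transform_imagespace(shell_phantom, t), invert(t)
        )
        mask = ndimage.binary_erosion(shell_phantom.data > 10, iterations=2)
        mae = np.abs(back.data - shell_phantom.data)[mask].mean()
        assert mae < 0.02 * 100.0  # < 2% of shell intensity


class TestBackgroundStats:
    def test_noiseless_phantom_background_is_zero(self, hard_shell_spec):
        mean, sd = estimate_background_stats(generate_phantom(hard_shell_spec))
        assert mean == 0.0 and sd == 0.0

    def test_recovers_known_background_noise(self, rng):
        spec = PhantomSpec(shape=(40, 40, 30))
        vol = generate_phantom(spec)
        sigma = 2.5
        noisy = vol.data.copy()
        background = vol.data == 0
        assert background.sum() >= 10_000
        noisy[background] += rng.normal(10.0, sigma, int(background.sum()))
        mean, sd = estimate_background_stats(vol.copy_with(noisy))
        assert abs(sd - sigma) / sigma < 0.05
        assert abs(mean - 10.0) < 0.5

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            estimate_background_stats(Volume3D(np.zeros((8, 8, 8))))


class TestDataset:
    def test_protocol_counts(self):
        pairs = make_synthetic_dataset(
            n_volumes=2, n_transforms_per_volume=3, ranges=(5.0, 10.0), shape=(16, 16, 12)
        )
        assert len(pairs) == 12
        per_range = {r: sum(p.range_label == r for p in pairs) for r in (5.0, 10.0)}
        assert per_range == {5.0: 6, 10.0: 6}

    def test_single_pair(self):
        pairs = make_synthetic_dataset(1, 1, ranges=(5.0,), shape=(16, 16, 12))
        assert len(pairs) == 1

    def test_ground_truth_in_labelled_range(self):
        pairs = make_synthetic_dataset(3, 4, ranges=(5.0, 15.0), shape=(16, 16, 12), seed=3)
        for p in pairs:
            assert np.all(np.abs(p.ground_truth.rot_deg) <= p.range_label)
            max_trans = p.range_label * max(p.reference.spacing)
            assert np.all(np.abs(p.ground_truth.trans_mm) <= max_trans)

    def test_reference_is_untransformed_phantom(self):
        specs = default_phantom_specs(1, shape=(16, 16, 12), seed=4)
        pairs = make_synthetic_dataset(1, 2, ranges=(5.0,), base_specs=specs, shape=(16, 16, 12))
        assert np.array_equal(pairs[0].reference.data, generate_phantom(specs[0]).data)
        assert pairs[0].reference is pairs[1].reference

    def test_dataset_seed_determinism(self):
        kw = dict(n_volumes=2, n_transforms_per_volume=2, ranges=(5.0,), shape=(16, 16, 12), seed=7)
        a, b = make_synthetic_dataset(**kw), make_synthetic_dataset(**kw)
        for pa, pb in zip(a, b):
            assert pa.ground_truth == pb.ground_truth
            assert np.array_equal(pa.moved.data, pb.moved.data)

    def test_save_dataset_roundtrip(self, tmp_path):
        import pandas as pd

        pairs = make_synthetic_dataset(1, 2, ranges=(5.0,), shape=(16, 16, 12))
        manifest = save_dataset(pairs, tmp_path, seed=0)
        table = pd.read_csv(manifest)
        assert len(table) == 2
        first = table.iloc[0]
        moved = Volume3D.load(tmp_path / first["moved_path"])
        assert moved.shape == (16, 16, 12)
        t = RigidTransform.load(tmp_path / first["transform_path"])
        assert np.allclose(t.rot_deg, pairs[0].ground_truth.rot_deg, atol=1e-6)
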