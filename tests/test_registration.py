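"""Sub-volume CCC registration: recovery, oracle agreement, bookkeeping."""

import numpy as np
import pytest

from fatnav.registration import (
    GridSearchBackend,
    RegistrationConfig,
    benchmark_registration,
    register,
    register_oracle,
    select_subvolumes,
    summarize_benchmark,
)
from fatnav.synthetic import (
    PhantomSpec,
    apply_transform_imagespace,
    default_phantom_specs,
    generate_phantom,
    make_synthetic_dataset,
)
from fatnav.transforms import RigidTransform, motion_score, residual_motion_score
from fatnav.volume import Volume3D

FAST_CFG = RegistrationConfig(max_passes=4)


def tiny_phantom(seed=0, shape=(16, 16, 16)):
    return generate_phantom(default_phantom_specs(1, shape=shape, seed=seed)[0])


class TestSelectSubvolumes:
    def test_single_blob_box_contains_blob(self):
        spec = PhantomSpec(
            shape=(32, 32, 32),
            outer_semiaxes_mm=(20, 20, 20),
            inner_semiaxes_mm=(19.5, 19.5, 19.5),
            shell_intensity=0.01,
            blobs=(((0.0, 0.0, 0.0), 10.0, 100.0),),
        )
        vol = generate_phantom(spec)
        cfg = RegistrationConfig(n_subvolumes=1, subvolume_edge=8, subvolume_margin=0)
        (box,) = select_subvolumes(vol, cfg)
        center = tuple(int(c) for c in vol.center_index)
        assert all(b.start <= c < b.stop for b, c in zip(box, center))

    def test_empty_volume_falls_back_with_warning(self):
        vol = Volume3D(np.zeros((16, 16, 16)))
        with pytest.warns(UserWarning, match="whole-volume"):
            boxes = select_subvolumes(vol, RegistrationConfig(subvolume_edge=8))
        assert boxes == [tuple(slice(0, 16) for _ in range(3))]

    def test_boxes_intersect_shell(self, shell_phantom):
        cfg = RegistrationConfig()
        shell_mask = shell_phantom.data > 0.5 * shell_phantom.data.max()
        for box in select_subvolumes(shell_phantom, cfg):
            assert shell_mask[box].any()

    def test_deterministic(self, shell_phantom):
        cfg = RegistrationConfig()
        assert select_subvolumes(shell_phantom, cfg) == select_subvolumes(shell_phantom, cfg)


class TestRegister:
    def test_self_registration_is_identity(self, shell_phantom):
        res = register(shell_phantom, shell_phantom, FAST_CFG)
        assert res.converged
        assert motion_score(res.transform).score < 0.5

    def test_translation_recovery(self, shell_phantom):
        gt = RigidTransform(trans_mm=(4.0, -6.0, 2.0))
        moved = apply_transform_imagespace(shell_phantom, gt)
        res = register(shell_phantom, moved, FAST_CFG)
        assert np.all(np.abs(np.subtract(res.transform.trans_mm, gt.trans_mm)) < 1.0)
        assert residual_motion_score(res.transform, gt) < 2.0

    def test_rotation_recovery(self, shell_phantom):
        gt = RigidTransform((5.0, 0, 0), (0, 0, 0))
        moved = apply_transform_imagespace(shell_phantom, gt)
        res = register(shell_phantom, moved, FAST_CFG)
        assert abs(res.transform.rot_deg[0] - 5.0) < 0.5
        assert residual_motion_score(res.transform, gt) < 2.0

    def test_final_metric_matches_recomputation(self, shell_phantom):
        from fatnav.registration import _WarpEvaluator

        gt = RigidTransform((2.0, 0, 0), (3.0, 0, 0))
        moved = apply_transform_imagespace(shell_phantom, gt)
        res = register(shell_phantom, moved, FAST_CFG)
        ev = _WarpEvaluator(
            shell_phantom, moved, select_subvolumes(shell_phantom, FAST_CFG), FAST_CFG.metric
        )
        assert res.final_metric == pytest.approx(ev(res.transform), abs=1e-9)

    def test_degenerate_images_rejected(self):
        flat = Volume3D(np.ones((16, 16, 16)))
        with pytest.raises(ValueError, match="degenerate"):
            register(flat, flat, FAST_CFG)

    def test_low_metric_flags_non_convergence(self, rng):
        """Unrelated images must not be reported as a confident registration."""
        a = tiny_phantom(seed=1, shape=(24, 24, 24))
        b = Volume3D(rng.uniform(0, 100, (24, 24, 24)), a.spacing)
        res = register(a, b, RegistrationConfig(max_passes=2))
        assert not res.converged

    def test_parameters_within_bounds(self, shell_phantom):
        cfg = RegistrationConfig(rotation_bound_deg=3.0, max_passes=2)
        moved = apply_transform_imagespace(shell_phantom, RigidTransform((8.0, 0, 0), (0, 0, 0)))
        res = register(shell_phantom, moved, cfg)
        assert np.all(np.abs(res.transform.rot_deg) <= 3.0 + 1e-9)


class TestOracle:
    def test_on_grid_shift_recovered_exactly(self):
        vol = tiny_phantom(seed=2)
        step = vol.spacing[0]
        gt = RigidTransform(trans_mm=(2 * step, -step, 0.0))
        moved = apply_transform_imagespace(vol, gt)
        grid = {k: np.arange(-3, 4) * step for k in ("tx", "ty", "tz")}
        res = register_oracle(vol, moved, grid)
        assert res.transform.trans_mm == gt.trans_mm

    def test_sequential_search_matches_oracle_on_translations(self):
        """register() finds the oracle's global optimum for on-grid pure shifts."""
        vol = tiny_phantom(seed=3)
        step = vol.spacing[0]
        gt = RigidTransform(trans_mm=(step, 2 * step, -step))
        moved = apply_transform_imagespace(vol, gt)
        grid = {k: np.arange(-3, 4) * step for k in ("tx", "ty", "tz")}
        oracle = register_oracle(vol, moved, grid)
        cfg = RegistrationConfig(
            subvolume_edge=8, subvolume_margin=0, n_subvolumes=8,
            coarse_step_mm=step, fine_step_mm=step, max_passes=3,
            search_params=("tx", "ty", "tz"),
        )
        res = register(vol, moved, cfg)
        assert np.allclose(res.transform.trans_mm, oracle.transform.trans_mm, atol=1e-9)
        assert np.allclose(res.transform.rot_deg, 0.0, atol=1e-9)

    def test_tie_breaks_toward_smaller_magnitude(self):
        """On a symmetric volume, equal-scoring shifts resolve to the smallest."""
        data = np.zeros((8, 8, 8))
        data[3:5, 3:5, 3:5] = 1.0
        vol = Volume3D(data)
        res = register_oracle(vol, vol, {"tx": [-8.0, 0.0, 8.0]})
        assert res.transform.trans_mm == (0.0, 0.0, 0.0)

    def test_oversized_grid_refused(self):
        vol = tiny_phantom(seed=4)
        grid = {k: np.arange(50) for k in ("tx", "ty", "tz", "rz", "ry", "rx")}
        with pytest.raises(ValueError, match="too large"):
            register_oracle(vol, vol, grid)

    def test_empty_grid_refused(self):
        vol = tiny_phantom(seed=4)
        with pytest.raises(ValueError, match="empty"):
            register_oracle(vol, vol, {"tx": []})


@pytest.fixture(scope="module")
def small_dataset():
    return make_synthetic_dataset(
        n_volumes=2, n_transforms_per_volume=2, ranges=(5.0,), shape=(32, 32, 24), seed=5
    )


class TestBenchmark:
    def test_row_bookkeeping(self, small_dataset):
        cfg = RegistrationConfig(subvolume_edge=8, max_passes=2)
        results = benchmark_registration(small_dataset, [cfg])
        assert len(results) == 4
        summary = summarize_benchmark(results)
        assert len(summary) == 1
        assert summary.loc[0, "n_pairs"] == 4

    def test_registration_reduces_motion(self, small_dataset):
        cfg = RegistrationConfig(subvolume_edge=8, max_passes=4)
        results = benchmark_registration(small_dataset, [GridSearchBackend(cfg)])
        assert (
            results["residual_motion_score_mm"].mean() < results["gt_motion_score_mm"].mean()
        )

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            benchmark_registration([], [RegistrationConfig()])
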