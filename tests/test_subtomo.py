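"""Subvolume extraction, grid alignment, iterative averaging and FSC."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import tomopack as tp
from tomopack.subtomo import _rotate_grid_about_centre, apply_transform


class TestExtractSubvolumes:
    def test_box_edge_voxel_count(self, rng):
        vol = tp.DensityVolume(rng.normal(size=(60, 60, 60)), 1.14)
        centre = np.full(3, 30 * 1.14)
        stack = tp.extract_subvolumes(vol, tp.ParticleSet([centre]),
                                      box_edge=45.6)
        assert stack.boxes.shape[1:] == (40, 40, 40)
        assert stack.box_edge == pytest.approx(45.6)

    def test_centering(self, rng):
        vol = tp.DensityVolume(rng.normal(size=(21, 21, 21)), 1.0)
        centre_pos = vol.index_to_position((10, 10, 10))
        stack = tp.extract_subvolumes(vol, tp.ParticleSet([centre_pos]),
                                      box_edge=9.0)
        assert stack.boxes[0][4, 4, 4] == vol.grid[10, 10, 10]

    def test_boundary_particles_dropped(self, rng):
        vol = tp.DensityVolume(rng.normal(size=(30, 30, 30)), 1.0)
        near_face = np.array([1.5, 15.0, 15.0])     # 1 voxel from the face
        inside = np.full(3, 15.0)
        stack = tp.extract_subvolumes(
            vol, tp.ParticleSet([near_face, inside]), box_edge=10.0)
        assert len(stack) == 1
        assert stack.particle_ids.tolist() == [1]

    def test_empty_stack_raises(self, rng):
        vol = tp.DensityVolume(rng.normal(size=(12, 12, 12)), 1.0)
        with pytest.raises(tp.EmptyStackError):
            tp.extract_subvolumes(vol, tp.ParticleSet([[1.0, 1.0, 1.0]]),
                                  box_edge=10.0)


class TestAlignPair:
    def test_self_alignment(self, asymmetric_volume):
        tr, score = tp.align_pair(asymmetric_volume, asymmetric_volume,
                                  angular_step=30.0, max_shift=3.0)
        assert score == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(tr.rotation.as_matrix(), np.eye(3), atol=1e-12)
        assert np.allclose(tr.translation, 0.0)

    def test_pure_shift_recovered_exactly(self, asymmetric_volume):
        moved = tp.DensityVolume(np.roll(asymmetric_volume.grid, 3, axis=0),
                                 1.0)
        tr, score = tp.align_pair(moved, asymmetric_volume,
                                  angular_step=30.0, max_shift=4.0)
        assert np.allclose(tr.translation, [-3.0, 0.0, 0.0], atol=1e-9)
        assert score > 0.95

    def test_grid_rotation_recovered(self, asymmetric_volume):
        true = Rotation.from_euler("z", 60.0, degrees=True)
        moved = tp.DensityVolume(
            _rotate_grid_about_centre(asymmetric_volume.grid, true), 1.0)
        tr, score = tp.align_pair(moved, asymmetric_volume,
                                  angular_step=30.0, max_shift=2.0)
        # recovered rotation within one grid step of the truth
        residual = (tr.rotation * true.inv()).magnitude()
        assert np.degrees(residual) <= 30.0 + 1e-6
        assert score > 0.8

    def test_invalid_angular_step(self, asymmetric_volume):
        with pytest.raises(tp.ParameterError):
            tp.align_pair(asymmetric_volume, asymmetric_volume,
                          angular_step=0.0)


class TestIterativeAverage:
    def _stack_of(self, boxes, voxel=1.0):
        return tp.SubvolumeStack(np.asarray(boxes), voxel,
                                 boxes[0].shape[0] * voxel,
                                 np.arange(len(boxes)))

    def test_identical_boxes_average_is_member(self, asymmetric_volume):
        stack = self._stack_of([asymmetric_volume.grid] * 4)
        avg, transforms, scores = tp.iterative_average(
            stack, angular_schedule=(30.0,), max_shift=2.0)
        assert np.allclose(avg.grid, asymmetric_volume.grid, atol=1e-6)
        for tr in transforms:
            assert np.allclose(tr.rotation.as_matrix(), np.eye(3),
                               atol=1e-9)

    def test_single_box(self, asymmetric_volume):
        stack = self._stack_of([asymmetric_volume.grid])
        avg, transforms, _ = tp.iterative_average(
            stack, angular_schedule=(45.0,), max_shift=2.0)
        assert np.allclose(avg.grid, asymmetric_volume.grid, atol=1e-9)
        assert np.allclose(transforms[0].rotation.as_matrix(), np.eye(3),
                           atol=1e-9)

    def test_transforms_reproduce_average(self, asymmetric_volume, rng):
        grids = [asymmetric_volume.grid,
                 np.roll(asymmetric_volume.grid, 2, axis=1),
                 _rotate_grid_about_centre(
                     asymmetric_volume.grid,
                     Rotation.from_euler("z", 90, degrees=True))]
        stack = self._stack_of(grids)
        avg, transforms, _ = tp.iterative_average(
            stack, angular_schedule=(45.0, 45.0), max_shift=3.0)
        rebuilt = np.mean([apply_transform(b, tr, 1.0)
                           for b, tr in zip(stack.boxes, transforms)],
                          axis=0)
        assert np.allclose(rebuilt, avg.grid, atol=1e-6)

    def test_known_rotations_recovered(self, asymmetric_volume):
        """Boxes made by rotating one object by grid rotations are
        brought back into a single common frame (up to a global
        rotation) within one grid step."""
        step = 30.0
        true_rots = [Rotation.identity(),
                     Rotation.from_euler("z", 60, degrees=True),
                     Rotation.from_euler("y", 30, degrees=True)]
        grids = [_rotate_grid_about_centre(asymmetric_volume.grid, r)
                 for r in true_rots]
        stack = self._stack_of(grids)
        avg, transforms, scores = tp.iterative_average(
            stack, angular_schedule=(step, step, step), max_shift=2.0)
        # undoing each generating rotation must land every box in a
        # common global frame G: T_i = G * R_i^-1
        composed = [tr.rotation * r.inv()
                    for tr, r in zip(transforms, true_rots)]
        for c in composed[1:]:
            residual = (c * composed[0].inv()).magnitude()
            assert np.degrees(residual) <= step + 1e-6

    def test_mean_score_non_decreasing(self, asymmetric_volume, rng):
        grids = [_rotate_grid_about_centre(
            asymmetric_volume.grid,
            Rotation.from_euler("z", a, degrees=True))
            + rng.normal(0, 0.001, asymmetric_volume.grid.shape)
            for a in (0.0, 30.0, 60.0, 90.0)]
        stack = self._stack_of(grids)
        _, _, scores = tp.iterative_average(
            stack, angular_schedule=(60.0, 30.0, 30.0), max_shift=2.0)
        assert np.all(np.diff(scores) >= -1e-6)

    def test_empty_stack_rejected(self):
        with pytest.raises(tp.EmptyStackError):
            tp.iterative_average(
                tp.SubvolumeStack(np.empty((0, 4, 4, 4)), 1.0, 4.0,
                                  np.empty(0, int)))


class TestFSC:
    def test_self_fsc_is_unity(self, rng):
        vol = tp.DensityVolume(rng.normal(size=(20, 20, 20)), 1.0)
        curve = tp.fourier_shell_correlation(vol, vol)
        assert np.allclose(curve.correlations, 1.0, atol=1e-9)
        assert np.all(np.diff(curve.frequencies) > 0)

    def test_independent_noise_decorrelated(self, rng):
        a = tp.DensityVolume(rng.normal(size=(32, 32, 32)), 1.0)
        b = tp.DensityVolume(rng.normal(size=(32, 32, 32)), 1.0)
        curve = tp.fourier_shell_correlation(a, b)
        # null distribution: |mean shell correlation| ~ 1/sqrt(n_shell)
        n_shell = 4 * np.pi * np.arange(1, len(curve.correlations) + 1) ** 2
        assert np.all(np.abs(curve.correlations) < 3.0 / np.sqrt(n_shell)
                      + 0.05)

    def test_symmetry(self, rng):
        a = tp.DensityVolume(rng.normal(size=(16, 16, 16)), 1.0)
        b = tp.DensityVolume(rng.normal(size=(16, 16, 16)), 1.0)
        ab = tp.fourier_shell_correlation(a, b)
        ba = tp.fourier_shell_correlation(b, a)
        assert np.array_equal(ab.correlations, ba.correlations)

    def test_shape_mismatch_rejected(self, rng):
        a = tp.DensityVolume(rng.normal(size=(16, 16, 16)), 1.0)
        b = tp.DensityVolume(rng.normal(size=(12, 12, 12)), 1.0)
        with pytest.raises(tp.GeometryError):
            tp.fourier_shell_correlation(a, b)


class TestResolutionAt:
    def test_interpolated_crossing(self):
        freqs = np.array([0.1, 0.2, 0.3, 0.4])
        curve = tp.FSCCurve(freqs, np.array([1.0, 1.0, 0.6, 0.4]), 1.0)
        est = tp.resolution_at(curve, 0.5)
        assert est.crossed
        # linear interpolation between shells 3 and 4
        f_cross = 0.3 + (0.6 - 0.5) / (0.6 - 0.4) * 0.1
        assert est.resolution_nm == pytest.approx(1.0 / f_cross)

    def test_exact_threshold_tie_rule(self):
        freqs = np.array([0.1, 0.2, 0.3])
        curve = tp.FSCCurve(freqs, np.array([0.5, 0.5, 0.5]), 1.0)
        est = tp.resolution_at(curve, 0.5)
        assert est.crossed
        assert est.resolution_nm == pytest.approx(10.0)

    def test_never_crossing_returns_nyquist(self, rng):
        vol = tp.DensityVolume(rng.normal(size=(20, 20, 20)), 1.3)
        curve = tp.fourier_shell_correlation(vol, vol)
        est = tp.resolution_at(curve, 0.5)
        assert not est.crossed
        assert est.resolution_nm == pytest.approx(2.6)


def test_half_set_fsc_on_noisy_stack(rng):
    """Even/odd half-set averages of noisy copies of one object stay
    highly correlated at low frequency, and the estimated resolution is
    finite and coarser than Nyquist."""
    base = np.zeros((16, 16, 16))
    base[5:9, 6:11, 7:10] = 1.0
    base[9:12, 7:9, 7:9] = 0.6
    boxes = np.stack([base + rng.normal(0, 0.5, base.shape)
                      for _ in range(20)])
    even = tp.DensityVolume(boxes[::2].mean(axis=0), 1.0)
    odd = tp.DensityVolume(boxes[1::2].mean(axis=0), 1.0)
    curve = tp.fourier_shell_correlation(even, odd)
    assert curve.correlations[0] > 0.9
    est = tp.resolution_at(curve, 0.5)
    assert est.crossed
    assert est.resolution_nm > 2.0
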