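"""Generator properties: lattice geometry, rendering, stacks, fixtures."""

import numpy as np
import pytest
from scipy.stats import norm

import tomopack as tp
from tomopack.latticegen import RANDOM_PACKING_FRACTION

from conftest import distance_census, interior_positions


@pytest.mark.parametrize("model", [tp.LatticeModel.HCP, tp.LatticeModel.CCP,
                                   tp.LatticeModel.BCC])
def test_minimal_center_distance_equals_diameter(model):
    spec = tp.LatticeSpec(model, 13.0)
    scene = tp.generate_lattice_points(spec, (80.0, 80.0, 80.0))
    assert len(scene) > 20
    assert tp.minimal_center_distance(scene) == pytest.approx(13.0, rel=1e-9)
    assert np.all(scene.positions >= 0) and np.all(
        scene.positions <= scene.extent)


@pytest.mark.parametrize("model,coordination", [
    (tp.LatticeModel.HCP, 12), (tp.LatticeModel.CCP, 12),
    (tp.LatticeModel.BCC, 8)])
def test_interior_coordination_number(model, coordination):
    d = 14.0
    spec = tp.LatticeSpec(model, d)
    scene = tp.generate_lattice_points(spec, (90.0, 90.0, 90.0))
    centre = scene.positions[
        np.argmin(np.linalg.norm(scene.positions - 45.0, axis=1))]
    census = distance_census(scene.positions, centre)
    first_class = min(census)
    assert first_class == pytest.approx(d, rel=1e-9)
    assert census[first_class] == coordination


def test_hcp_second_shell_at_sqrt2():
    """The next distance class beyond contact sits at sqrt(2)*d, which is
    why a 22.8 nm query at ~15 nm spacing admits second-shell points."""
    d = 15.05
    scene = tp.generate_lattice_points(
        tp.LatticeSpec(tp.LatticeModel.HCP, d), (100.0,) * 3)
    centre = scene.positions[
        np.argmin(np.linalg.norm(scene.positions - 50.0, axis=1))]
    census = distance_census(scene.positions, centre)
    classes = sorted(census)
    assert classes[0] == pytest.approx(d, rel=1e-9)
    assert classes[1] == pytest.approx(np.sqrt(2.0) * d, rel=1e-9)
    assert classes[1] < 22.8 < classes[2]


class TestIdealUnitCell:
    def test_hcp_thirteen_points_aba_layering(self):
        d = 15.05
        cell = tp.ideal_unit_cell(tp.LatticeSpec(tp.LatticeModel.HCP, d))
        assert cell.shape == (13, 3)
        dists = np.linalg.norm(cell[1:], axis=1)
        assert np.allclose(dists, d, rtol=1e-12)
        z = cell[:, 2]
        assert (np.isclose(z, 0).sum(), (z > 1).sum(), (z < -1).sum()) \
            == (7, 3, 3)
        # A-B-A: the triangle below is the mirror image of the one above
        above = cell[cell[:, 2] > 1]
        below = cell[cell[:, 2] < -1]
        mirrored = above * np.array([1.0, 1.0, -1.0])
        assert np.allclose(np.sort(mirrored, axis=0),
                           np.sort(below, axis=0), atol=1e-12)

    def test_ccp_abc_stacking_differs_from_hcp(self):
        d = 10.0
        ccp = tp.ideal_unit_cell(tp.LatticeSpec(tp.LatticeModel.CCP, d))
        assert ccp.shape == (13, 3)
        assert np.allclose(np.linalg.norm(ccp[1:], axis=1), d, rtol=1e-12)
        above = ccp[ccp[:, 2] > 1]
        below = ccp[ccp[:, 2] < -1]
        # A-B-C: bottom triangle is the point-inverted top, not its mirror
        assert np.allclose(np.sort(-above, axis=0), np.sort(below, axis=0),
                           atol=1e-12)
        mirrored = above * np.array([1.0, 1.0, -1.0])
        assert not np.allclose(np.sort(mirrored, axis=0),
                               np.sort(below, axis=0), atol=1e-6)

    def test_bcc_nine_points(self):
        d = 12.0
        cell = tp.ideal_unit_cell(tp.LatticeSpec(tp.LatticeModel.BCC, d))
        assert cell.shape == (9, 3)
        assert np.allclose(np.linalg.norm(cell[1:], axis=1), d, rtol=1e-12)

    def test_random_model_rejected(self):
        with pytest.raises(tp.ParameterError):
            tp.ideal_unit_cell(tp.LatticeSpec(tp.LatticeModel.RANDOM, 10.0))


def test_degenerate_box_yields_single_point():
    spec = tp.LatticeSpec(tp.LatticeModel.HCP, 15.0)
    scene = tp.generate_lattice_points(spec, (10.0, 10.0, 10.0))
    assert len(scene) == 1


def test_seed_reproducibility():
    spec = tp.LatticeSpec(tp.LatticeModel.HCP, 13.0)
    a = tp.generate_lattice_points(spec, (70.0,) * 3, jitter_sd=0.7, seed=5)
    b = tp.generate_lattice_points(spec, (70.0,) * 3, jitter_sd=0.7, seed=5)
    assert np.array_equal(a.positions, b.positions)
    r = tp.LatticeSpec(tp.LatticeModel.RANDOM, 13.0)
    a = tp.generate_lattice_points(r, (60.0,) * 3, seed=9)
    b = tp.generate_lattice_points(r, (60.0,) * 3, seed=9)
    assert np.array_equal(a.positions, b.positions)


def test_random_model_respects_minimum_distance():
    spec = tp.LatticeSpec(tp.LatticeModel.RANDOM, 12.0)
    scene = tp.generate_lattice_points(spec, (80.0,) * 3, seed=2)
    expected = int(RANDOM_PACKING_FRACTION * 80.0 ** 3
                   / (np.pi / 6 * 12.0 ** 3))
    assert len(scene) == expected
    assert tp.minimal_center_distance(scene) >= 12.0


def test_random_model_placement_failure():
    spec = tp.LatticeSpec(tp.LatticeModel.RANDOM, 20.0)
    with pytest.raises(tp.PlacementError):
        tp.generate_lattice_points(spec, (30.0,) * 3, n_points=50, seed=0)


def test_invalid_parameters_rejected():
    with pytest.raises(tp.ParameterError):
        tp.LatticeSpec(tp.LatticeModel.HCP, -1.0)
    spec = tp.LatticeSpec(tp.LatticeModel.HCP, 10.0)
    with pytest.raises(tp.ParameterError):
        tp.generate_lattice_points(spec, (50.0,) * 3, jitter_sd=-0.1)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _single_particle_scene(pos, extent=(40.0,) * 3, d=13.0):
    from scipy.spatial.transform import Rotation
    return tp.SyntheticScene(np.asarray([pos]), Rotation.identity(1),
                             tp.LatticeSpec(tp.LatticeModel.HCP, d),
                             0.0, np.asarray(extent), 0)


def test_render_single_particle_peak_at_centre():
    scene = _single_particle_scene((20.0, 20.0, 20.0))
    vol = tp.render_scene(scene, 1.0, particle_diameter=12.0)
    assert np.unravel_index(np.argmax(vol.grid), vol.grid.shape) \
        == (19, 19, 19) or vol.grid[19, 19, 19] == vol.grid.max()


def test_render_deterministic():
    scene = _single_particle_scene((20.0, 20.0, 20.0))
    a = tp.render_scene(scene, 1.0, noise_sd=0.0)
    b = tp.render_scene(scene, 1.0, noise_sd=0.0)
    assert np.array_equal(a.grid, b.grid)
    c = tp.render_scene(scene, 1.0, noise_sd=0.5, seed=3)
    d = tp.render_scene(scene, 1.0, noise_sd=0.5, seed=3)
    assert np.array_equal(c.grid, d.grid)


def test_render_mass_additivity_and_linearity(hcp_scene):
    """Total rendered density is n_particles times one sphere's mass
    (particles sharing the same sub-voxel phase), and rendering a union
    of scenes equals the voxelwise sum of renders."""
    from scipy.spatial.transform import Rotation
    vx = 1.14
    one = tp.render_scene(_single_particle_scene((20 * vx,) * 3,
                                                 extent=(100.0,) * 3), vx)
    # 27 particles on a voxel-aligned grid: identical sampling phase
    g = (np.arange(3) * 20 + 20) * vx
    pos = np.array(np.meshgrid(g, g, g, indexing="ij")).reshape(3, -1).T
    scene = tp.SyntheticScene(pos, Rotation.identity(len(pos)),
                              hcp_scene.spec, 0.0, np.full(3, 100.0), 0)
    vol = tp.render_scene(scene, vx)
    assert vol.grid.sum() == pytest.approx(len(pos) * one.grid.sum(),
                                           rel=1e-6)
    # linearity: split the scene in two and sum the renders
    interior = interior_positions(hcp_scene, 10.0)
    full = tp.SyntheticScene(interior, Rotation.identity(len(interior)),
                             hcp_scene.spec, 0.0, hcp_scene.extent, 0)
    half_a = tp.SyntheticScene(interior[::2],
                               Rotation.identity(len(interior[::2])),
                               full.spec, 0.0, full.extent, 0)
    half_b = tp.SyntheticScene(interior[1::2],
                               Rotation.identity(len(interior[1::2])),
                               full.spec, 0.0, full.extent, 0)
    summed = tp.render_scene(half_a, vx).grid + tp.render_scene(
        half_b, vx).grid
    assert np.allclose(tp.render_scene(full, vx).grid, summed, atol=1e-9)


def test_missing_wedge_removes_wedge_frequencies():
    scene = _single_particle_scene((20.0, 20.0, 20.0))
    tilt = tp.TiltGeometry(tilt_increment=2.0, tilt_range=60.0)
    vol = tp.render_scene(scene, 1.0, tilt=tilt)
    ft = np.fft.fftn(vol.grid)
    kx = np.fft.fftfreq(vol.grid.shape[0])[:, None, None]
    kz = np.fft.fftfreq(vol.grid.shape[2])[None, None, :]
    missing = (np.abs(kz) * np.cos(np.radians(60.0))
               > np.abs(kx) * np.sin(np.radians(60.0)))
    missing &= ~((kx == 0) & (kz == 0))
    missing3 = np.broadcast_to(missing, ft.shape)
    assert np.abs(ft[missing3]).max() < 1e-8 * np.abs(ft).max()
    # wedge-free render differs
    plain = tp.render_scene(scene, 1.0)
    assert not np.allclose(plain.grid, vol.grid)


# ---------------------------------------------------------------------------
# Membrane stacks
# ---------------------------------------------------------------------------

def test_layer_model_repeat():
    model = tp.LayerModel(membrane_width=4.9, lumen_width=9.0,
                          stromal_gap=3.6)
    assert model.lateral_repeat == pytest.approx(22.4)


def test_stack_profile_lumen_brighter_than_gap():
    model = tp.LayerModel()
    pos, vals = tp.membrane_stack_profile(model, 0.25)
    # sample levels well inside known layers: first lumen vs first gap
    lumen_centre = 12.0 + 4.9 + 4.5
    gap_centre = 12.0 + 2 * 4.9 + 9.0 + 1.8
    lum = vals[np.argmin(np.abs(pos - lumen_centre))]
    gap = vals[np.argmin(np.abs(pos - gap_centre))]
    assert lum > gap


def test_stack_two_layers_single_gap():
    model = tp.LayerModel(n_layers=2)
    pos, vals = tp.membrane_stack_profile(model, 0.25)
    membrane_idx = np.nonzero(np.isclose(vals, model.membrane_level))[0]
    inner = vals[membrane_idx[0]:membrane_idx[-1] + 1]
    stroma_runs = 0
    in_run = False
    for v in inner:
        if np.isclose(v, model.stroma_level):
            if not in_run:
                stroma_runs += 1
                in_run = True
        else:
            in_run = False
    assert stroma_runs == 1


def test_stack_resolution_guard():
    model = tp.LayerModel()
    with pytest.raises(tp.ResolutionError):
        tp.generate_membrane_stack(model, voxel_size=2.0)


# ---------------------------------------------------------------------------
# Invagination fixtures
# ---------------------------------------------------------------------------

def test_invagination_counting_rule_boundaries():
    big = norm(loc=50.0, scale=1.0)
    small = norm(loc=5.0, scale=1.0)
    tips = norm(loc=30.0, scale=5.0)
    records = tp.generate_invagination_fixture(20, big, tips, 15.0, 1.0,
                                               seed=1)
    assert all(r.counted for r in records)
    records = tp.generate_invagination_fixture(20, small, tips, 15.0, 1.0,
                                               seed=1)
    assert not any(r.counted for r in records)


def test_invagination_ground_truth_density():
    sizes = norm(loc=50.0, scale=5.0)
    tips = norm(loc=30.0, scale=5.0)
    records = tp.generate_invagination_fixture(12, sizes, tips, 15.0, 1.0,
                                               seed=4)
    stats = tp.invagination_stats(records, membrane_area=1.0)
    assert stats["density_per_um2"] == pytest.approx(12.0)
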