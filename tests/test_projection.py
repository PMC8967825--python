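"""Mercator grid geometry, volume sampling and shell unwrapping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import embryomap as em

LN_TAN_75 = math.log(math.tan(math.radians(75.0)))  # closed-form y(60°, R=1)


class TestMercator:
    def test_equator_maps_to_zero(self):
        assert em.mercator_y(0.0, 123.0) == 0.0

    def test_sixty_degrees_unit_radius(self):
        assert em.mercator_y(60.0, 1.0) == pytest.approx(LN_TAN_75, abs=1e-12)

    @given(st.floats(-89.0, 89.0))
    @settings(max_examples=50, deadline=None)
    def test_odd_in_latitude_and_invertible(self, lat):
        R = 50.0
        y = em.mercator_y(lat, R)
        assert em.mercator_y(-lat, R) == pytest.approx(-y, abs=1e-9)
        assert em.inverse_mercator_latitude(y, R) == pytest.approx(lat, abs=1e-9)

    @pytest.mark.parametrize("lat", [90.0, -90.0, 95.0])
    def test_pole_singularity_rejected(self, lat):
        with pytest.raises(ValueError, match="singular"):
            em.mercator_y(lat, 1.0)


class TestMakeGrid:
    def test_odd_row_count_centres_equator(self):
        grid = em.make_grid(11, 8, truncation_latitude=80.0)
        assert grid.latitudes[5] == pytest.approx(0.0, abs=1e-12)

    def test_four_columns(self):
        grid = em.make_grid(4, 4)
        assert np.allclose(grid.longitudes, [45.0, 135.0, 225.0, 315.0])

    def test_rows_symmetric_and_monotone(self):
        grid = em.make_grid(20, 8, truncation_latitude=85.0, reference_radius=10.0)
        assert np.allclose(grid.latitudes, -grid.latitudes[::-1], atol=1e-9)
        assert np.all(np.diff(grid.latitudes) < 0)  # row 0 is the +lat side
        # rows are uniform in Mercator y
        y = em.mercator_y(grid.latitudes, 10.0)
        assert np.allclose(np.diff(y), np.diff(y)[0])

    def test_equirect_rows_uniform_in_latitude(self):
        grid = em.make_grid(9, 4, truncation_latitude=90.0, mode="equirect")
        assert np.allclose(np.diff(grid.latitudes), np.diff(grid.latitudes)[0])
        assert grid.latitudes[0] == pytest.approx(80.0)

    def test_mercator_mode_cannot_reach_pole(self):
        with pytest.raises(ValueError, match="pole singularity"):
            em.make_grid(4, 4, truncation_latitude=90.0)


class TestSphericalCoordinates:
    def test_axis_points(self):
        assert np.allclose(em.latlon_to_cartesian(0.0, 0.0, 50.0), [0.0, 0.0, 50.0])
        assert np.allclose(em.latlon_to_cartesian(90.0, 123.0, 50.0), [50.0, 0.0, 0.0])
        assert np.allclose(em.latlon_to_cartesian(0.0, 90.0, 50.0), [0.0, 50.0, 0.0])

    def test_roundtrip_on_random_points(self):
        rng = np.random.default_rng(0)
        center = (10.0, -20.0, 5.0)
        pts = rng.normal(size=(100, 3)) * 40 + center
        lat, lon, r = em.cartesian_to_latlon(pts, center)
        back = em.latlon_to_cartesian(lat, lon, r, center)
        assert np.allclose(back, pts, atol=1e-9)
        assert np.all((lon >= 0) & (lon < 360))


class TestSampleVolume:
    @pytest.fixture
    def ramp(self):
        data = np.zeros((3, 3, 4))
        data[1, 1, 1] = 10.0
        data[1, 1, 2] = 20.0
        return em.VoxelVolume(data, (2.0, 1.0, 0.5))

    @pytest.mark.parametrize("sampler", ["trilinear", "nearest"])
    def test_voxel_centre_returns_exact_value(self, ramp, sampler):
        assert em.sample_volume(ramp, (2.0, 1.0, 0.5), sampler) == 10.0

    def test_midpoint_trilinear_average(self, ramp):
        assert em.sample_volume(ramp, (2.0, 1.0, 0.75), "trilinear") == 15.0

    def test_midpoint_anisotropic_z(self, ramp):
        ramp.data[2, 1, 1] = 30.0
        assert em.sample_volume(ramp, (3.0, 1.0, 0.5), "trilinear") == 20.0

    def test_outside_returns_fill(self, ramp):
        assert em.sample_volume(ramp, (-0.5, 0.0, 0.0), fill_value=-7.0) == -7.0
        assert em.sample_volume(ramp, (0.0, 0.0, 99.0), fill_value=-7.0) == -7.0

    def test_unknown_sampler_rejected(self, ramp):
        with pytest.raises(ValueError, match="sampler"):
            em.sample_volume(ramp, (0, 0, 0), "cubic")


SHELL_SHAPE = (96, 96, 96)
SHELL_CENTER = (47.5, 47.5, 47.5)
SHELL_R = 32.0


@pytest.fixture(scope="module")
def shell_sphere():
    return em.SphereModel(center=SHELL_CENTER, radius=SHELL_R, rms_residual=0.0, n_points=6)


@pytest.fixture(scope="module")
def shell_grid(shell_sphere):
    return em.default_grid(shell_sphere, 1.0)


class TestProjectLayer:
    def test_zero_volume_projects_to_zero(self, shell_sphere, shell_grid):
        v = em.VoxelVolume(np.zeros(SHELL_SHAPE), (1.0, 1.0, 1.0))
        img = em.project_layer(v, shell_sphere, 0.0, shell_grid)
        assert img.shape == (shell_grid.n_rows, shell_grid.n_cols)
        assert not img.any()

    def test_single_cell_lands_at_its_latlon(self, shell_sphere, shell_grid):
        spec = em.EmbryoSpec(
            volume_shape=SHELL_SHAPE, voxel_spacing=(1.0, 1.0, 1.0),
            sphere_center=SHELL_CENTER, sphere_radius=SHELL_R, n_cells=1,
            cell_sigma=1.5, background=0.0, noise=em.NoiseModel("none"), seed=123,
        )
        v, truth = em.generate_volume(spec)
        img = em.project_layer(v, shell_sphere, 0.0, shell_grid)
        i, j = np.unravel_index(np.argmax(img), img.shape)
        lat0, lon0 = truth.cell_latlon[0]
        di = np.abs(shell_grid.latitudes - lat0).argmin()
        dj = np.abs(shell_grid.longitudes - lon0).argmin()
        assert abs(i - di) <= 1 and min(abs(j - dj), shell_grid.n_cols - abs(j - dj)) <= 1

    def test_nonpositive_sampling_radius_rejected(self, shell_sphere, shell_grid):
        v = em.VoxelVolume(np.zeros(SHELL_SHAPE), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="not positive"):
            em.project_layer(v, shell_sphere, -40.0, shell_grid)


class TestMultilayer:
    def test_single_offset_matches_project_layer(self, shell_sphere, shell_grid):
        v = em.make_shell_volume(SHELL_SHAPE, (1, 1, 1), SHELL_CENTER, SHELL_R)
        stack = em.project_multilayer(v, shell_sphere, [0.0], shell_grid)
        assert np.array_equal(
            stack.layers[0], em.project_layer(v, shell_sphere, 0.0, shell_grid)
        )

    def test_default_step_layer_count(self):
        # 2 µm steps spanning 10 µm inward: 6 layers (−10 … 0)
        offsets = em.layer_offsets(step=2.0, depth_in=10.0, depth_out=0.0)
        assert len(offsets) == 6 and offsets[0] == -10.0 and offsets[-1] == 0.0

    def test_brightest_layer_is_the_shell_offset(self, shell_sphere, shell_grid):
        v = em.make_shell_volume(SHELL_SHAPE, (1, 1, 1), SHELL_CENTER, SHELL_R - 4.0,
                                 radial_sigma=1.5)
        stack = em.project_multilayer(
            v, shell_sphere, [-8.0, -6.0, -4.0, -2.0, 0.0], shell_grid
        )
        totals = stack.layers.sum(axis=(1, 2))
        assert stack.offsets[np.argmax(totals)] == -4.0

    def test_offset_error_names_the_offset(self, shell_sphere, shell_grid):
        v = em.VoxelVolume(np.zeros(SHELL_SHAPE), (1, 1, 1))
        with pytest.raises(ValueError, match=r"-40\.0"):
            em.project_multilayer(v, shell_sphere, [0.0, -40.0], shell_grid)


class TestMaxProjection:
    def test_single_layer_identity(self, shell_sphere):
        grid = em.make_grid(8, 8)
        layers = np.random.default_rng(0).random((1, 8, 8))
        stack = em.MapLayerStack(np.array([0.0]), layers, grid, shell_sphere)
        assert np.array_equal(em.max_project_layers(stack), layers[0])

    def test_dominant_layer_wins_and_bounds_all(self, shell_sphere):
        grid = em.make_grid(8, 8)
        rng = np.random.default_rng(1)
        base = rng.random((8, 8))
        layers = np.stack([base, base + 5.0, rng.random((8, 8))])
        stack = em.MapLayerStack(np.array([0.0, 2.0, 4.0]), layers, grid, shell_sphere)
        mx = em.max_project_layers(stack)
        assert np.array_equal(mx, layers.max(axis=0))
        assert np.all(mx[None] >= layers)


class TestMapMetric:
    def test_longitude_seam_splits_disc_without_losing_intensity(
        self, shell_sphere, shell_grid
    ):
        kwargs = dict(center=SHELL_CENTER, radius=SHELL_R, disc_lat=0.0,
                      disc_radius=6.0, radial_sigma=2.0)
        zeros = em.VoxelVolume(np.zeros(SHELL_SHAPE), (1, 1, 1))
        at_seam = em.paint_geodesic_disc(zeros, disc_lon=0.0, **kwargs)
        away = em.paint_geodesic_disc(zeros, disc_lon=180.0, **kwargs)
        img_seam = em.project_layer(at_seam, shell_sphere, 0.0, shell_grid)
        img_away = em.project_layer(away, shell_sphere, 0.0, shell_grid)
        # the seam splits the blob across the image edges
        third = shell_grid.n_cols // 3
        assert img_seam[:, :third].sum() > 0 and img_seam[:, -third:].sum() > 0
        assert img_seam.sum() == pytest.approx(img_away.sum(), rel=0.01)

    def test_equator_arc_length_per_column(self, shell_sphere, shell_grid):
        # a geodesic disc of known radius must span 2·radius of physical
        # arc along the equator row
        disc_radius = 8.0
        v = em.paint_geodesic_disc(
            em.VoxelVolume(np.zeros(SHELL_SHAPE), (1, 1, 1)),
            SHELL_CENTER, SHELL_R, 0.0, 180.0, disc_radius, radial_sigma=2.0,
        )
        img = em.project_layer(v, shell_sphere, 0.0, shell_grid)
        row = img[np.abs(shell_grid.latitudes).argmin()]
        um_per_col = 2 * np.pi * SHELL_R / shell_grid.n_cols
        width_cols = np.count_nonzero(row > row.max() / 2.0)
        assert width_cols * um_per_col == pytest.approx(2 * disc_radius, abs=2 * um_per_col)
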