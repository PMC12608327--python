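import numpy as np
import pytest

from standgrowth.pointcloud import PointCloud
from standgrowth.surfaces import (
    SMOOTHING_KERNEL,
    GridSpec,
    RasterGrid,
    build_tin_raster,
    compute_chm,
    gaussian_smooth,
    make_dsm,
    make_dtm,
    mask_below,
    read_ascii_grid,
    write_ascii_grid,
)


def grid(values, resolution=1.0, origin=(0.0, None)):
    values = np.asarray(values, dtype=np.float64)
    oy = origin[1] if origin[1] is not None else values.shape[0] * resolution
    spec = GridSpec(origin[0], oy, resolution, *values.shape)
    return RasterGrid(spec, values)


class TestGridSpec:
    def test_snapped_origin(self):
        spec = GridSpec.from_bounds(1.3, 2.1, 9.9, 8.7, 0.5)
        assert spec.origin_x == 1.0
        assert spec.origin_y == 9.0
        # both epochs snap to the same lattice
        spec2 = GridSpec.from_bounds(1.4, 2.0, 9.8, 8.6, 0.5)
        assert (spec2.origin_x - spec.origin_x) % 0.5 == 0

    def test_invalid(self):
        with pytest.raises(ValueError):
            GridSpec.from_bounds(5, 5, 5, 8, 0.5)
        with pytest.raises(ValueError):
            GridSpec(0, 10, -1.0, 5, 5)


class TestBuildTinRaster:
    def test_affine_field_reproduced_exactly(self, rng):
        pts = rng.uniform(0, 20, size=(60, 2))
        z = 2.0 * pts[:, 0] + 3.0 * pts[:, 1] + 1.0
        spec = GridSpec.from_bounds(0, 0, 20, 20, 1.0)
        raster = build_tin_raster(np.column_stack([pts, z]), spec)
        X, Y = spec.cell_centers()
        expected = 2.0 * X + 3.0 * Y + 1.0
        interior = ~np.isnan(raster.values)
        assert interior.sum() > 50
        np.testing.assert_allclose(raster.values[interior],
                                   expected[interior], atol=1e-9)

    def test_single_triangle_barycentric(self):
        # triangle (0,0,z=0), (4,0,z=8), (0,4,z=4); cell center (1.5, 1.5)
        # barycentric weights (1/8, 3/8, 3/8, ...): z = l1*0 + l2*8 + l3*4
        pts = np.array([[0, 0, 0], [4, 0, 8], [0, 4, 4]], dtype=float)
        spec = GridSpec(0.0, 4.0, 1.0, 4, 4)
        raster = build_tin_raster(pts, spec)
        # hand computation at (1.5, 1.5): l2 = x/4 = 0.375, l3 = y/4 = 0.375
        expected = 0.375 * 8 + 0.375 * 4
        i, j = 2, 1  # cell center (1.5, 1.5)
        assert raster.cell_center(i, j) == (1.5, 1.5)
        assert raster.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_outside_hull_is_na(self):
        pts = np.array([[5, 5, 1], [6, 5, 1], [5, 6, 1]], dtype=float)
        spec = GridSpec.from_bounds(0, 0, 20, 20, 1.0)
        raster = build_tin_raster(pts, spec)
        assert np.isnan(raster.values[0, 0])

    def test_too_few_or_collinear_points(self):
        spec = GridSpec(0, 10, 1.0, 10, 10)
        with pytest.raises(ValueError):
            build_tin_raster(np.array([[0, 0, 1], [1, 1, 2]], dtype=float), spec)
        collinear = np.array([[i, i, 1.0] for i in range(5)])
        with pytest.raises(ValueError):
            build_tin_raster(collinear, spec)


class TestDsmDtm:
    def flat_cloud(self, z=5.0, n=400, two_returns=False):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 20, n)
        y = rng.uniform(0, 20, n)
        if two_returns:
            return PointCloud(x, y, np.full(n, z), np.full(n, 2),
                              np.full(n, 2), np.full(n, 5))
        return PointCloud(x, y, np.full(n, z), np.ones(n, dtype=int),
                          np.ones(n, dtype=int), np.full(n, 2))

    def test_flat_ground_dsm_equals_dtm(self):
        cloud = self.flat_cloud()
        dsm = make_dsm(cloud, 1.0)
        dtm = make_dtm(cloud, 1.0, spec=dsm.spec)
        valid = ~np.isnan(dsm.values)
        np.testing.assert_allclose(dsm.values[valid], dtm.values[valid],
                                   atol=1e-9)

    def test_dtm_falls_back_to_last_returns(self, caplog):
        cloud = self.flat_cloud(two_returns=True)  # no class-2 points
        with caplog.at_level("WARNING"):
            dtm = make_dtm(cloud, 1.0)
        assert "last returns" in caplog.text
        assert np.nanmax(dtm.values) == pytest.approx(5.0)

    def test_single_tree_peak_height(self, noiseless_single_tree_cloud):
        config, tree, cloud = noiseless_single_tree_cloud
        dsm = make_dsm(cloud, 0.5)
        dtm = make_dtm(cloud, 0.5, spec=dsm.spec)
        peak = np.nanmax(dsm.values - dtm.values)
        assert 19.0 <= peak <= 20.0

    def test_no_qualifying_points(self):
        empty = PointCloud.empty()
        with pytest.raises(ValueError):
            make_dsm(empty, 1.0)


class TestComputeChm:
    def test_subtraction(self):
        dsm = grid([[22.0]])
        dtm = grid([[2.0]])
        assert compute_chm(dsm, dtm).values[0, 0] == 20.0

    def test_na_propagation(self):
        dsm = grid([[np.nan, 22.0]])
        dtm = grid([[2.0, np.nan]])
        chm = compute_chm(dsm, dtm)
        assert np.isnan(chm.values).all()

    def test_negative_clamped_to_zero(self):
        chm = compute_chm(grid([[1.9]]), grid([[2.0]]))
        assert chm.values[0, 0] == 0.0

    def test_geometry_mismatch(self):
        with pytest.raises(ValueError, match="geometr"):
            compute_chm(grid(np.zeros((3, 3))), grid(np.zeros((4, 3))))

    def test_treeless_noiseless_cloud_gives_zero_chm(self):
        from standgrowth.synthetic import (SceneConfig, generate_terrain,
                                           simulate_point_cloud)

        config = SceneConfig(extent=(0, 0, 40, 40), pulse_density=4.0,
                             vertical_noise_sd=0.0, relief_amplitude=2.0,
                             seed=5)
        cloud = simulate_point_cloud([], generate_terrain(config), config,
                                     np.random.default_rng(5))
        dsm = make_dsm(cloud, 1.0)
        dtm = make_dtm(cloud, 1.0, spec=dsm.spec)
        chm = compute_chm(dsm, dtm)
        valid = ~np.isnan(chm.values)
        np.testing.assert_allclose(chm.values[valid], 0.0, atol=1e-9)


class TestGaussianSmooth:
    def test_kernel_contract(self):
        assert SMOOTHING_KERNEL.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_array_equal(SMOOTHING_KERNEL,
                                      np.rot90(SMOOTHING_KERNEL))

    def test_constant_preserved(self):
        out = gaussian_smooth(grid(np.full((5, 7), 10.0)))
        np.testing.assert_allclose(out.values, 10.0, atol=1e-12)

    def test_impulse_response(self):
        vals = np.zeros((5, 5))
        vals[2, 2] = 16.0
        out = gaussian_smooth(grid(vals))
        assert out.values[2, 2] == pytest.approx(16 * 0.25)
        assert out.values[2, 1] == pytest.approx(16 * 0.125)
        assert out.values[1, 1] == pytest.approx(16 * 0.0625)

    def test_border_renormalized(self):
        out = gaussian_smooth(grid(np.full((4, 4), 10.0)))
        assert out.values[0, 0] == pytest.approx(10.0, abs=1e-12)

    def test_na_aware(self):
        vals = np.full((3, 3), 5.0)
        vals[1, 1] = np.nan
        out = gaussian_smooth(grid(vals))
        assert out.values[0, 0] == pytest.approx(5.0, abs=1e-12)
        # NA cell gets the renormalized neighborhood value, all 5s
        assert out.values[1, 1] == pytest.approx(5.0, abs=1e-12)

    def test_bounded_by_input_range(self, rng):
        vals = rng.uniform(3, 9, size=(20, 20))
        out = gaussian_smooth(grid(vals))
        assert out.values.min() >= vals.min() - 1e-12
        assert out.values.max() <= vals.max() + 1e-12

    def test_mean_preserved_on_constant_extended_interior(self, rng):
        # zero margin of 2 cells: no mass leaves the raster, sum is conserved
        vals = np.zeros((24, 24))
        vals[2:-2, 2:-2] = rng.uniform(0, 20, size=(20, 20))
        out = gaussian_smooth(grid(vals))
        assert out.values.mean() == pytest.approx(vals.mean(), abs=1e-9)


class TestMaskBelow:
    def test_below_threshold_is_na(self):
        out = mask_below(grid([[6.99]]), 7.0)
        assert np.isnan(out.values[0, 0])

    def test_boundary_retained(self):
        out = mask_below(grid([[7.0]]), 7.0)
        assert out.values[0, 0] == 7.0

    def test_identity_when_all_above(self):
        vals = np.full((3, 3), 12.0)
        out = mask_below(grid(vals), 7.0)
        np.testing.assert_array_equal(out.values, vals)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            mask_below(grid([[1.0]]), 0.0)


class TestAsciiGridIO:
    def test_round_trip(self, tmp_path, rng):
        vals = rng.uniform(0, 30, size=(6, 8))
        vals[0, 0] = np.nan
        raster = grid(vals, resolution=0.5, origin=(10.0, 25.0))
        path = tmp_path / "r.asc"
        write_ascii_grid(raster, path)
        again = read_ascii_grid(path)
        assert again.spec == raster.spec
        np.testing.assert_allclose(again.values, raster.values,
                                   atol=1e-4, equal_nan=True)
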