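import hashlib
import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

from standgrowth.synthetic import (
    CROWN_BASE_FRACTION,
    SceneConfig,
    SyntheticTree,
    _crown_surface_height,
    build_scene,
    generate_inventory,
    generate_stand,
    generate_terrain,
    grow_stand,
    simulate_point_cloud,
    true_stand_heights,
    write_scene,
)


class TestSceneConfig:
    def test_invalid_extent(self):
        with pytest.raises(ValueError):
            SceneConfig(extent=(0, 0, 0, 10))

    def test_invalid_noise(self):
        with pytest.raises(ValueError):
            SceneConfig(vertical_noise_sd=0.9)

    def test_species_mix_normalized(self):
        config = SceneConfig(species_mix={"pine": 2.0, "birch": 2.0})
        assert config.species_mix == {"pine": 0.5, "birch": 0.5}


class TestTerrain:
    def test_zero_amplitude_flat(self):
        terrain = generate_terrain(SceneConfig(relief_amplitude=0.0))
        xs = np.linspace(0, 100, 50)
        np.testing.assert_array_equal(terrain(xs, xs), np.zeros(50))

    def test_deterministic_for_seed(self, rng):
        config = SceneConfig(seed=42, relief_amplitude=3.0)
        t1, t2 = generate_terrain(config), generate_terrain(config)
        xs, ys = rng.uniform(0, 100, 100), rng.uniform(0, 100, 100)
        np.testing.assert_array_equal(t1(xs, ys), t2(xs, ys))

    def test_amplitude_bounds_deviation_from_mean(self):
        amp = 5.0
        config = SceneConfig(seed=9, relief_amplitude=amp)
        terrain = generate_terrain(config)
        # dense-grid scan oracle
        X, Y = np.meshgrid(np.linspace(0, 100, 400), np.linspace(0, 100, 400))
        z = terrain(X, Y)
        tol = amp * 1e-3
        assert z.max() - z.mean() <= amp + tol
        assert z.mean() - z.min() <= amp + tol

    def test_smoothness(self):
        terrain = generate_terrain(SceneConfig(seed=1, relief_amplitude=3.0,
                                               relief_scale=60.0))
        # gradient over 10 cm steps stays small for 60 m correlation length
        z0 = terrain(np.array([50.0]), np.array([50.0]))[0]
        z1 = terrain(np.array([50.1]), np.array([50.0]))[0]
        assert abs(z1 - z0) < 0.1


class TestGenerateStand:
    def test_zero_density_empty(self, rng):
        config = SceneConfig(stem_density=0.0)
        assert generate_stand(box(0, 0, 100, 100), "U", config, rng) == []

    def test_all_pine_config(self, rng):
        config = SceneConfig(species_mix={"pine": 1.0})
        trees = generate_stand(box(0, 0, 100, 100), "U", config, rng)
        assert trees and all(t.species == "pine" for t in trees)

    def test_poisson_count_reproducible(self):
        config = SceneConfig(stem_density=400.0)
        poly = box(0, 0, 100, 100)  # 1 ha
        a = generate_stand(poly, "U", config, np.random.default_rng(5))
        b = generate_stand(poly, "U", config, np.random.default_rng(5))
        assert len(a) == len(b)
        assert [(t.x, t.y, t.apex_height) for t in a] == \
               [(t.x, t.y, t.apex_height) for t in b]
        # Poisson(400): count within 5 sigma of the mean
        assert abs(len(a) - 400) < 5 * math.sqrt(400)

    def test_positions_inside_polygon(self, rng):
        poly = Polygon([(0, 0), (60, 0), (30, 50)])
        config = SceneConfig(stem_density=300.0)
        trees = generate_stand(poly, "U", config, rng)
        from shapely.geometry import Point
        assert all(poly.contains(Point(t.x, t.y)) for t in trees)

    def test_degenerate_polygon_warns_empty(self, rng):
        line = Polygon([(0, 0), (1, 0), (0, 0)])
        with pytest.warns(UserWarning, match="degenerate"):
            assert generate_stand(line, "U", SceneConfig(), rng) == []


class TestGrowStand:
    def tree(self, h=18.0):
        return SyntheticTree(0, 5.0, 5.0, h, 3.0, "pine", "U")

    def test_zero_years_identity(self):
        trees = [self.tree()]
        grown = grow_stand(trees, 0.0, {"pine": 0.3})
        assert grown[0].apex_height == trees[0].apex_height

    def test_linear_growth(self):
        grown = grow_stand([self.tree(18.0)], 9.0, {"pine": 2.0 / 9.0})
        assert grown[0].apex_height == pytest.approx(20.0)

    def test_positions_unchanged(self):
        grown = grow_stand([self.tree()], 5.0, {"pine": 0.3})
        assert (grown[0].x, grown[0].y) == (5.0, 5.0)

    def test_negative_years_rejected(self):
        with pytest.raises(ValueError):
            grow_stand([self.tree()], -1.0, {})

    def test_dieback_clamped_at_zero(self):
        grown = grow_stand([self.tree(2.0)], 9.0, {"pine": -5.0})
        assert grown[0].apex_height == 0.0


class TestSimulatePointCloud:
    def test_open_ground_counts_and_moments(self):
        config = SceneConfig(extent=(0, 0, 100, 100), pulse_density=4.0,
                             vertical_noise_sd=0.2, relief_amplitude=0.0,
                             seed=0)
        cloud = simulate_point_cloud([], generate_terrain(config), config,
                                     np.random.default_rng(0))
        assert set(cloud.class_code) == {2}
        ratio = len(cloud) / (config.area_m2 * config.pulse_density)
        assert 0.95 <= ratio <= 1.05
        assert cloud.z.mean() == pytest.approx(0.0, abs=0.01)
        assert cloud.z.std() == pytest.approx(0.2, rel=0.05)

    def test_cone_first_returns_match_geometric_oracle(
            self, noiseless_single_tree_cloud):
        config, tree, cloud = noiseless_single_tree_cloud
        first = cloud.select((cloud.return_number == 1)
                             & (cloud.number_of_returns == 2))
        # oracle: recompute the cone surface at the sampled pulse positions
        dist = np.hypot(first.x - tree.x, first.y - tree.y)
        base = CROWN_BASE_FRACTION * tree.apex_height
        expected = tree.apex_height - (tree.apex_height - base) * dist / tree.crown_radius
        np.testing.assert_allclose(first.z, expected, atol=1e-9)
        # apex sampled to within the cone slope over one pulse spacing
        spacing = 1.0 / math.sqrt(config.pulse_density)
        slope = (tree.apex_height - base) / tree.crown_radius
        assert first.z.max() >= tree.apex_height - slope * spacing * math.sqrt(2)

    def test_canopy_pulses_have_ground_last_return(
            self, noiseless_single_tree_cloud):
        config, tree, cloud = noiseless_single_tree_cloud
        last = cloud.select((cloud.return_number == 2))
        assert len(last) > 0
        np.testing.assert_allclose(last.z, 0.0, atol=1e-9)
        assert set(last.class_code) == {2}

    def test_vegetation_class_bands(self):
        # a return 1.5 m above ground is medium vegetation (class 4)
        config = SceneConfig(extent=(0, 0, 20, 20), pulse_density=25.0,
                             vertical_noise_sd=0.0, relief_amplitude=0.0,
                             seed=2)
        shrub = SyntheticTree(0, 10.0, 10.0, 1.5, 2.0, "pine", "U")
        cloud = simulate_point_cloud([shrub], generate_terrain(config), config,
                                     np.random.default_rng(2))
        first = cloud.select(cloud.number_of_returns == 2)
        first = first.select(first.return_number == 1)
        h = first.z  # flat terrain at 0
        assert len(h) > 0
        np.testing.assert_array_equal(
            first.class_code,
            np.where(h <= 0.4, 3, np.where(h <= 2.0, 4, 5)))
        assert (first.class_code == 4).any()

    def test_noise_fraction_adds_class7(self):
        config = SceneConfig(extent=(0, 0, 50, 50), noise_fraction=0.01,
                             relief_amplitude=0.0, seed=1)
        cloud = simulate_point_cloud([], generate_terrain(config), config,
                                     np.random.default_rng(1))
        n_noise = (cloud.class_code == 7).sum()
        assert n_noise == int(0.01 * 50 * 50 * 4)

    def test_paraboloid_flatter_than_cone_near_apex(self):
        tree_c = SyntheticTree(0, 0, 0, 20.0, 4.0, "pine", "U")
        tree_d = SyntheticTree(0, 0, 0, 20.0, 4.0, "birch", "U")
        d = np.array([1.0])
        assert _crown_surface_height(tree_d, d) > _crown_surface_height(tree_c, d)


class TestInventory:
    def trees(self, heights, unit="U", species="pine"):
        return [SyntheticTree(i, 1.0, 1.0, h, 2.0, species, unit)
                for i, h in enumerate(heights)]

    def test_noiseless_uniform(self, rng):
        inv = generate_inventory(self.trees([18.0] * 20), ["U"],
                                 height_noise_sd=0.0, rng=rng)
        assert inv.iloc[0]["height"] == 18

    def test_empty_unit_missing_not_zero(self, rng):
        inv = generate_inventory([], ["EMPTY"], rng=rng)
        row = inv.iloc[0]
        assert np.isnan(row["height"]) and row["n_trees"] == 0

    def test_sampling_spread_matches_closed_form(self):
        # sd of the raw mean over repeated surveys ~ sigma / sqrt(n)
        trees = self.trees([20.0] * 10)
        raws = [generate_inventory(trees, ["U"], n_sample=10,
                                   height_noise_sd=0.3,
                                   rng=np.random.default_rng(s)
                                   ).iloc[0]["height_raw"]
                for s in range(400)]
        assert np.std(raws) == pytest.approx(0.3 / math.sqrt(10), rel=0.15)

    def test_dominant_species_reported(self, rng):
        trees = (self.trees([18.0] * 8, species="pine")
                 + self.trees([12.0] * 2, species="birch"))
        inv = generate_inventory(trees, ["U"], height_noise_sd=0.0, rng=rng)
        assert inv.iloc[0]["species"] == "pine"
        assert inv.iloc[0]["height"] == 18


class TestSceneAssembly:
    def test_truth_sidecar(self, small_scene):
        truth = small_scene.truth
        assert set(truth.columns) >= {"forest_address", "true_mean_a",
                                      "true_mean_b", "true_growth"}
        # growth applied uniformly per unit: mean_b - mean_a == true growth
        np.testing.assert_allclose(truth["true_mean_b"] - truth["true_mean_a"],
                                   truth["true_growth"], atol=1e-9)

    def test_trees_inside_their_units(self, small_scene):
        from shapely.geometry import Point

        units = {u.forest_address: u.geometry for u in small_scene.units_a}
        for tree in small_scene.trees_a[::25]:
            assert units[tree.unit_id].contains(Point(tree.x, tree.y))

    def test_fixed_seed_byte_identical_outputs(self, tmp_path):
        config = SceneConfig(extent=(0, 0, 60, 60), seed=11,
                             vertical_noise_sd=0.15)

        def digest(outdir):
            scene = build_scene(config, units_nx=1, units_ny=1)
            paths = write_scene(scene, outdir)
            return {name: hashlib.sha256(p.read_bytes()).hexdigest()
                    for name, p in paths.items()}

        assert digest(tmp_path / "a") == digest(tmp_path / "b")
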