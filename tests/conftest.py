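import numpy as np
import pytest

from standgrowth.synthetic import SceneConfig, build_scene


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scene():
    """A 120 m two-epoch scene with 2x2 units, reused across test modules."""
    config = SceneConfig(extent=(0, 0, 120, 120), seed=7,
                         vertical_noise_sd=0.2)
    return build_scene(config, units_nx=2, units_ny=2)


@pytest.fixture(scope="session")
def noiseless_single_tree_cloud():
    """One 20 m cone-crowned pine on flat ground, zero noise, dense pulses."""
    from standgrowth.synthetic import (SceneConfig, SyntheticTree,
                                       generate_terrain, simulate_point_cloud)

    # apex placed on a 0.5 m cell center so the DSM samples the cone tip
    config = SceneConfig(extent=(0, 0, 30, 30), pulse_density=100.0,
                         vertical_noise_sd=0.0, relief_amplitude=0.0, seed=3)
    tree = SyntheticTree(id=0, x=15.25, y=15.25, apex_height=20.0,
                         crown_radius=4.0, species="pine", unit_id="U")
    terrain = generate_terrain(config)
    cloud = simulate_point_cloud([tree], terrain, config,
                                 np.random.default_rng(3))
    return config, tree, cloud
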