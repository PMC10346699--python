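import numpy as np
import pytest

from rhizoprobe.synthetic_scene import (
    RenderConfig, SceneConfig, generate_root_system, generate_sampling_plan,
    sense_roots,
)


@pytest.fixture(scope="session")
def desk_scene() -> SceneConfig:
    """Reduced-viewpoint scene used throughout the suite."""
    return SceneConfig(n_tunnels=20, viewpoints_per_tunnel=10)


@pytest.fixture(scope="session")
def render_config() -> RenderConfig:
    return RenderConfig()


@pytest.fixture(scope="session")
def sensed_plant(desk_scene):
    """One control plant with its plan and per-viewpoint visibility."""
    system = generate_root_system(desk_scene, "control", plant_seed=424242, plant_id=0)
    plan = generate_sampling_plan(desk_scene, seed=515151)
    visible = sense_roots(plan, system, desk_scene.sense_radius)
    return desk_scene, plan, system, visible
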