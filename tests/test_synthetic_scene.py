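"""Scene generator: determinism, geometry, Poisson thinning, rendering."""

import numpy as np
import pytest
from scipy import ndimage, stats

from rhizoprobe.synthetic_scene import (
    CONTROL, INOCULATED, RenderConfig, SceneConfig,
    constant_rate_profile, generate_root_system, generate_sampling_plan,
    on_image_width_px, point_segment_distances, render_root_image,
    render_shoot_image, sample_shoot_params, sense_roots,
)


def _system_arrays(system):
    return (np.array([np.concatenate([s.start, s.end]) for s in system.segments]),
            np.array([s.thickness for s in system.segments]),
            np.array([s.color for s in system.segments]),
            [s.true_class for s in system.segments])


class TestRootSystem:
    def test_seeded_determinism_is_bitwise(self, desk_scene):
        a = generate_root_system(desk_scene, INOCULATED, plant_seed=7)
        b = generate_root_system(desk_scene, INOCULATED, plant_seed=7)
        ga, gb = _system_arrays(a), _system_arrays(b)
        assert np.array_equal(ga[0], gb[0])
        assert np.array_equal(ga[1], gb[1])
        assert np.array_equal(ga[2], gb[2])
        assert ga[3] == gb[3]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SceneConfig(damage_depth=150.0)
        with pytest.raises(ValueError):
            SceneConfig(shallow_damage_fraction=1.5)
        with pytest.raises(ValueError):
            SceneConfig(thin_surface_rate_per_cm3=-1.0)
        cfg = SceneConfig(thin_rate_profile=lambda z: np.full_like(z, -0.1))
        with pytest.raises(ValueError):
            generate_root_system(cfg, CONTROL, plant_seed=1)

    def test_zero_damage_gives_equal_count_distributions(self, desk_scene):
        """With no damage effect, thin counts of the two groups come from the
        same distribution (Monte Carlo null check over 200 replicates)."""
        cfg = SceneConfig(n_tunnels=1, viewpoints_per_tunnel=1,
                          shallow_damage_fraction=0.0)
        counts = {g: [] for g in (CONTROL, INOCULATED)}
        for g in (CONTROL, INOCULATED):
            for i in range(200):
                sys_i = generate_root_system(cfg, g, plant_seed=900_000 + i
                                             + (500_000 if g == INOCULATED else 0))
                counts[g].append(sum(s.true_class == "thin" for s in sys_i.segments))
        p = stats.ttest_ind(counts[CONTROL], counts[INOCULATED], equal_var=False).pvalue
        assert p > 0.05

    def test_poisson_thinning_ratio(self):
        """Expected shallow thin-count ratio inoculated/control equals
        1 - shallow_damage_fraction (tolerance 3 Monte Carlo SEs)."""
        cfg = SceneConfig(n_tunnels=1, viewpoints_per_tunnel=1,
                          shallow_damage_fraction=0.4, damage_depth=40.0)
        shallow = {CONTROL: [], INOCULATED: []}
        for g in (CONTROL, INOCULATED):
            for i in range(500):
                system = generate_root_system(cfg, g, plant_seed=10_000 + i
                                              + (1_000_000 if g == INOCULATED else 0))
                shallow[g].append(sum(
                    s.true_class == "thin" and s.midpoint[2] < cfg.damage_depth
                    for s in system.segments))
        mc = np.mean(shallow[CONTROL])
        mi = np.mean(shallow[INOCULATED])
        ratio = mi / mc
        # delta-method SE of the ratio of two independent means
        se = ratio * np.sqrt(np.var(shallow[CONTROL]) / (500 * mc**2)
                             + np.var(shallow[INOCULATED]) / (500 * mi**2))
        assert abs(ratio - 0.6) < 3 * se

    def test_inoculated_roots_are_darker(self, desk_scene):
        vals = {}
        for g in (CONTROL, INOCULATED):
            brightness = []
            for i in range(50):
                system = generate_root_system(desk_scene, g, plant_seed=500 + i)
                brightness.append(np.mean([np.mean(s.color) for s in system.segments]))
            vals[g] = np.mean(brightness)
        assert vals[INOCULATED] < vals[CONTROL]


class TestSamplingPlan:
    def test_default_plan_yields_4550_viewpoints_inside_cylinder(self):
        cfg = SceneConfig()
        plan = generate_sampling_plan(cfg, seed=3)
        assert plan.n_viewpoints == 4550
        r = np.hypot(plan.coords[:, 0], plan.coords[:, 1])
        assert np.all(r <= cfg.cylinder_radius)
        assert np.all((plan.coords[:, 2] >= 0) & (plan.coords[:, 2] <= cfg.cylinder_depth))

    def test_single_tunnel_single_viewpoint(self):
        cfg = SceneConfig(n_tunnels=1, viewpoints_per_tunnel=1)
        plan = generate_sampling_plan(cfg, seed=11)
        assert plan.n_viewpoints == 1
        assert np.hypot(*plan.coords[0, :2]) <= cfg.cylinder_radius
        assert 0 <= plan.coords[0, 2] <= cfg.cylinder_depth

    def test_plan_determinism(self, desk_scene):
        p1 = generate_sampling_plan(desk_scene, seed=5)
        p2 = generate_sampling_plan(desk_scene, seed=5)
        assert np.array_equal(p1.coords, p2.coords)
        assert np.array_equal(p1.tunnel_id, p2.tunnel_id)


class TestSenseRoots:
    def test_empty_system_sees_nothing(self, desk_scene):
        from rhizoprobe.synthetic_scene import RootSystem
        plan = generate_sampling_plan(desk_scene, seed=2)
        empty = RootSystem(0, CONTROL, [])
        assert all(len(v) == 0 for v in sense_roots(plan, empty, 6.0))

    def test_segment_through_viewpoint_is_visible(self, desk_scene):
        from rhizoprobe.synthetic_scene import RootSegment, RootSystem
        plan = generate_sampling_plan(desk_scene, seed=2)
        vp = plan.coords[17]
        seg = RootSegment(0, vp - np.array([5.0, 0, 0]), vp + np.array([5.0, 0, 0]),
                          1.0, (200.0, 200.0, 200.0), "thin")
        vis = sense_roots(plan, RootSystem(0, CONTROL, [seg]), 1e-9)
        assert 0 in vis[17]

    def test_matches_brute_force_all_pairs(self, sensed_plant):
        """Vectorized sensing equals an exhaustive per-pair distance loop."""
        scene, plan, system, visible = sensed_plant
        r = scene.sense_radius
        for i in range(plan.n_viewpoints):
            p = plan.coords[i]
            expect = []
            for j, seg in enumerate(system.segments):
                a, b = seg.start, seg.end
                ab = b - a
                t = float(np.dot(p - a, ab) / np.dot(ab, ab))
                t = min(max(t, 0.0), 1.0)
                if np.linalg.norm(p - (a + t * ab)) <= r:
                    expect.append(j)
            assert list(visible[i]) == expect


class TestRootRender:
    def test_no_segments_no_truth_boxes(self, render_config):
        img = render_root_image(np.array([0.0, 0, 50.0]), [], render_config, seed=1)
        assert img.ground_truth == []
        assert img.pixels.shape == (render_config.height, render_config.width, 3)

    def test_single_thin_segment_one_truth_box(self, render_config):
        from rhizoprobe.synthetic_scene import RootSegment
        vp = np.array([0.0, 0.0, 50.0])
        seg = RootSegment(0, vp + np.array([-6.0, 2.0, 0]), vp + np.array([6.0, 2.0, 0]),
                          0.8, (210.0, 202.0, 188.0), "thin")
        img = render_root_image(vp, [seg], render_config, seed=9)
        assert len(img.ground_truth) == 1
        (box, klass), = img.ground_truth
        assert klass == "thin"
        x0, y0, x1, y1 = box
        assert 0 <= x0 < x1 <= render_config.width
        assert 0 <= y0 < y1 <= render_config.height

    @pytest.mark.parametrize("thickness,distance", [(1.0, 6.0), (0.8, 4.0), (3.0, 6.0)])
    def test_projected_width_matches_documented_scale(self, render_config,
                                                      thickness, distance):
        """On-image width of a rendered root matches the projection model
        within a pixel."""
        from rhizoprobe.synthetic_scene import RootSegment
        vp = np.array([0.0, 0.0, 50.0])
        offset = np.array([0.0, distance, 0.0])
        seg = RootSegment(0, vp + offset + np.array([-8.0, 0, 0]),
                          vp + offset + np.array([8.0, 0, 0]),
                          thickness, (210.0, 202.0, 188.0), "thin")
        img = render_root_image(vp, [seg], render_config, seed=21)
        measured = 2.0 * ndimage.distance_transform_edt(np.pad(img.root_mask, 1)).max()
        assert abs(measured - on_image_width_px(thickness, distance, render_config)) <= 1.5

    def test_render_determinism(self, sensed_plant, render_config):
        scene, plan, system, visible = sensed_plant
        i = next(k for k in range(plan.n_viewpoints) if len(visible[k]))
        segs = [system.segments[int(j)] for j in visible[i]]
        a = render_root_image(plan.coords[i], segs, render_config, seed=77)
        b = render_root_image(plan.coords[i], segs, render_config, seed=77)
        assert np.array_equal(a.pixels, b.pixels)
        assert a.ground_truth == b.ground_truth


class TestShootRender:
    def test_unit_gain_board_at_true_color(self):
        p = sample_shoot_params(np.random.default_rng(0))
        img = render_shoot_image(p, (1.0, 1.0, 1.0), seed=4)
        r0, r1, c0, c1 = img.board_region
        board_mean = img.pixels[r0:r1, c0:c1].reshape(-1, 3).mean(axis=0)
        assert np.allclose(board_mean, img.board_true_color, atol=1.0)

    def test_mask_height_matches_parameter_scale(self):
        p = sample_shoot_params(np.random.default_rng(1))
        img = render_shoot_image(p, seed=5)
        rows = np.flatnonzero(img.plant_mask.any(axis=1))
        height = rows[-1] - rows[0] + 1
        assert height == round(p.height_mm * p.px_per_mm)

    def test_board_and_plant_disjoint(self):
        p = sample_shoot_params(np.random.default_rng(2))
        img = render_shoot_image(p, seed=6)
        r0, r1, c0, c1 = img.board_region
        assert not img.plant_mask[r0:r1, c0:c1].any()

    def test_gain_bounds_enforced(self):
        p = sample_shoot_params(np.random.default_rng(3))
        with pytest.raises(ValueError):
            render_shoot_image(p, (0.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            render_shoot_image(p, (1.0, 2.5, 1.0))


def test_identical_shoot_distributions_rarely_significant():
    """With both groups drawn from the same shoot distribution, shoot-feature
    t-tests are non-significant in >= 90% of simulated cohorts.

    The nominal level is 5%, so each feature's rejection count over 100
    cohorts is Binomial(100, 0.05); the per-feature check uses a 3.5-sigma
    binomial band around that level, and the 90% figure is checked on the
    whole battery (pooled over the eight features).
    """
    import math
    from rhizoprobe.shoot_features import shoot_feature_vector
    from scipy.stats import ttest_ind

    n_cohorts = 100
    features = ["R", "G", "B", "H", "S", "V", "leaf_area_px", "height_px"]
    ns_cohorts = {f: 0 for f in features}
    for c in range(n_cohorts):
        rows = {f: {"a": [], "b": []} for f in features}
        for k in range(16):
            for arm in ("a", "b"):
                seed = 40_000 + 1000 * c + 2 * k + (1 if arm == "b" else 0)
                rng = np.random.default_rng(seed)
                params = sample_shoot_params(rng)
                gain = tuple(rng.uniform(0.75, 1.2, 3))
                img = render_shoot_image(params, gain, seed=seed)
                fv, _ = shoot_feature_vector(img.pixels, img.board_region)
                for f in features:
                    rows[f][arm].append(getattr(fv, f))
        for f in features:
            p = ttest_ind(rows[f]["a"], rows[f]["b"], equal_var=False).pvalue
            ns_cohorts[f] += p > 0.05
    band = 3.5 * math.sqrt(0.05 * 0.95 / n_cohorts)
    for f, n_ns in ns_cohorts.items():
        rate = 1.0 - n_ns / n_cohorts
        assert rate <= 0.05 + band, f"feature {f} rejection rate {rate}"
    pooled_ns = sum(ns_cohorts.values()) / (len(features) * n_cohorts)
    assert pooled_ns >= 0.9
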