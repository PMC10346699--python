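"""Rule-based detector: segmentation, width estimate, class rule, splits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rhizoprobe.root_detection import (
    DetectorConfig, classify_root, detect_roots, estimate_thickness_px,
    extract_root_color, segment_root_pixels, split_train_validation,
)
from rhizoprobe.pipeline import box_iou
from rhizoprobe.synthetic_scene import (
    RenderConfig, RootSegment, render_root_image,
)


def _thin_segment(vp, thickness=0.8, color=(210.0, 202.0, 188.0)):
    return RootSegment(0, vp + np.array([-6.0, 1.0, 0.0]),
                       vp + np.array([6.0, 1.0, 0.0]), thickness, color, "thin")


class TestSegmentRootPixels:
    def test_pure_soil_gives_empty_mask(self, render_config):
        img = render_root_image(np.zeros(3), [], render_config, seed=13)
        assert not segment_root_pixels(img.pixels).any()

    def test_mask_iou_against_render_truth(self, sensed_plant, render_config):
        """Segmented root pixels overlap the renderer's non-specular root
        mask with IoU >= 0.9."""
        scene, plan, system, visible = sensed_plant
        checked = 0
        for i in range(plan.n_viewpoints):
            if len(visible[i]) == 0:
                continue
            segs = [system.segments[int(j)] for j in visible[i]]
            img = render_root_image(plan.coords[i], segs, render_config,
                                    seed=600 + i)
            truth = img.root_mask & ~img.specular_mask
            if truth.sum() < 500:
                continue
            mask = segment_root_pixels(img.pixels)
            iou = (mask & truth).sum() / (mask | truth).sum()
            assert iou >= 0.9
            checked += 1
            if checked >= 10:
                break
        assert checked >= 5

    def test_specular_highlights_excluded(self, render_config):
        vp = np.array([0.0, 0.0, 50.0])
        img = render_root_image(vp, [_thin_segment(vp, thickness=1.2)],
                                render_config, seed=41)
        assert img.specular_mask.any()
        mask = segment_root_pixels(img.pixels)
        overlap = (mask & img.specular_mask).sum() / img.specular_mask.sum()
        assert overlap < 0.05


class TestThicknessEstimate:
    def test_solid_bar(self):
        mask = np.zeros((60, 80), dtype=bool)
        mask[20:41, 5:75] = True  # height 21
        assert abs(estimate_thickness_px(mask) - 21) <= 1

    def test_single_pixel(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        t = estimate_thickness_px(mask)
        assert 1.0 <= t <= 2.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            estimate_thickness_px(np.zeros((4, 4), dtype=bool))


class TestClassRule:
    @pytest.mark.parametrize("width,hue,sat,expect", [
        (61.0, 35.0, 0.4, "thick"),   # just wide enough, brown, saturated
        (60.0, 35.0, 0.4, "thin"),    # strictly "wider than 60"
        (120.0, 110.0, 0.4, "thin"),  # green hue fails the color condition
        (120.0, 35.0, 0.05, "thin"),  # whitish: saturation floor fails
    ])
    def test_rule_points(self, width, hue, sat, expect):
        assert classify_root(width, hue, sat) == expect

    @given(st.floats(0.1, 200.0), st.floats(0.0, 359.9), st.floats(0.0, 1.0))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_rule_is_pure_conjunction(self, width, hue, sat):
        cfg = DetectorConfig()
        expect = ("thick" if (width > cfg.thick_width_px
                              and cfg.hue_band[0] <= hue <= cfg.hue_band[1]
                              and sat >= cfg.s_min) else "thin")
        assert classify_root(width, hue, sat, cfg) == expect


class TestDetect:
    def test_blank_soil_no_detections(self, render_config):
        img = render_root_image(np.zeros(3), [], render_config, seed=55)
        assert detect_roots(img.pixels) == []

    def test_single_thin_root_detected_with_overlap(self, render_config):
        vp = np.array([0.0, 0.0, 40.0])
        img = render_root_image(vp, [_thin_segment(vp)], render_config, seed=56)
        dets = detect_roots(img.pixels)
        assert len(dets) == 1
        assert dets[0].klass == "thin"
        (tbox, _), = img.ground_truth
        assert box_iou(dets[0].box, tbox) >= 0.5

    def test_thick_root_detected_as_thick(self, render_config):
        vp = np.array([0.0, 0.0, 40.0])
        seg = RootSegment(0, vp + np.array([-8.0, 2.0, 0.0]),
                          vp + np.array([8.0, 2.0, 0.0]),
                          3.5, (176.0, 138.0, 76.0), "thick")
        img = render_root_image(vp, [seg], render_config, seed=57)
        dets = detect_roots(img.pixels)
        assert len(dets) == 1
        assert dets[0].klass == "thick"
        assert dets[0].thickness_px > 60

    def test_detection_determinism(self, render_config):
        vp = np.array([0.0, 0.0, 40.0])
        img = render_root_image(vp, [_thin_segment(vp)], render_config, seed=58)
        assert detect_roots(img.pixels) == detect_roots(img.pixels)


class TestRootColor:
    def test_uniform_region_exact(self):
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        img[2:8, 2:8] = (204, 153, 51)
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:8, 2:8] = True
        c = extract_root_color(img, mask)
        assert (c.R, c.G, c.B) == pytest.approx((0.8, 0.6, 0.2))
        assert c.n_pixels == 36

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 256, (9, 7, 3)).astype(np.uint8)
        mask = rng.uniform(size=(9, 7)) > 0.5
        c = extract_root_color(img, mask)
        sums, n = np.zeros(3), 0
        for r in range(9):
            for col in range(7):
                if mask[r, col]:
                    sums += img[r, col]
                    n += 1
        assert np.allclose((c.R, c.G, c.B), sums / n / 255.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_root_color(np.zeros((5, 5, 3)), np.zeros((5, 5), dtype=bool))

    def test_inoculated_roots_have_lower_value(self, desk_scene):
        """The darkening effect propagates to extracted V (render + detect
        round trip over small cohorts)."""
        import dataclasses
        from rhizoprobe.synthetic_scene import (generate_root_system,
                                                generate_sampling_plan,
                                                sense_roots)
        from rhizoprobe.root_detection import analyze_root_image

        scene = dataclasses.replace(desk_scene, n_tunnels=6,
                                    viewpoints_per_tunnel=5)
        vals = {"control": [], "inoculated": []}
        for grp in vals:
            for k in range(6):
                system = generate_root_system(scene, grp, plant_seed=800 + k)
                plan = generate_sampling_plan(scene, seed=900 + k)
                visible = sense_roots(plan, system, scene.sense_radius)
                for i in range(plan.n_viewpoints):
                    if len(visible[i]) == 0:
                        continue
                    segs = [system.segments[int(j)] for j in visible[i]]
                    img = render_root_image(plan.coords[i], segs, seed=1000 + i)
                    for _, c in analyze_root_image(img.pixels):
                        vals[grp].append(c.V)
        assert np.mean(vals["inoculated"]) < np.mean(vals["control"])


class TestSplit:
    def test_study_split_sizes(self):
        tr, va = split_train_validation(135, 0.7, seed=0)
        assert (len(tr), len(va)) == (95, 40)

    def test_small_split_sizes(self):
        tr, va = split_train_validation(10, 0.7, seed=1)
        assert (len(tr), len(va)) == (7, 3)

    @given(st.integers(2, 300), st.floats(0.05, 0.95), st.integers(0, 2**31 - 1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_partition_property(self, n, frac, seed):
        tr, va = split_train_validation(n, frac, seed)
        union = np.union1d(tr, va)
        assert len(np.intersect1d(tr, va)) == 0
        assert np.array_equal(union, np.arange(n))

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_train_validation(10, 1.0, 0)
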