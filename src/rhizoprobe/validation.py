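"""Cohort-scale validation experiments.

These routines recompute, from scratch, the package's headline quantities:
the sampling-design arithmetic, the flat-density property of the volume
normalization, closed-form/textbook oracle agreement, the type-I error of
the feature screens under a null cohort, recovery of the inoculation effect
under the default study conditions, and detector quality on rendered
batches.  They are deliberately independent of stored results: everything is
simulated and measured at call time from a seed.
"""

from __future__ import annotations

import math

import numpy as np

from .group_stats import two_tailed_t_test
from .pipeline import (ExperimentConfig, derive_seed, evaluate_detector,
                       run_cohort)
from .root_detection import detect_roots, split_train_validation
from .shoot_features import rgb_to_hsv
from .spatial_density import (build_density_profile, make_bins,
                              observations_frame, sphere_volume_cm3)
from .root_detection import Detection
from .synthetic_scene import (SceneConfig, constant_rate_profile,
                              generate_root_system, generate_sampling_plan,
                              render_root_image, sense_roots)

DESK_TUNNELS = 20
DESK_VIEWPOINTS = 10

STRUCTURE_HEADLINE_FEATURES = ("n_thin", "mean_depth_thin")


def desk_scene(**overrides) -> SceneConfig:
    kwargs = dict(n_tunnels=DESK_TUNNELS, viewpoints_per_tunnel=DESK_VIEWPOINTS)
    kwargs.update(overrides)
    return SceneConfig(**kwargs)


# ---------------------------------------------------------------------------
# Design arithmetic
# ---------------------------------------------------------------------------

def sampling_plan_summary(seed: int = 0) -> dict:
    """Viewpoint count and cylinder containment of the full sampling design."""
    cfg = SceneConfig()
    plan = generate_sampling_plan(cfg, seed=seed)
    r = np.hypot(plan.coords[:, 0], plan.coords[:, 1])
    inside = np.all(r <= cfg.cylinder_radius) and np.all(
        (plan.coords[:, 2] >= 0) & (plan.coords[:, 2] <= cfg.cylinder_depth))
    return {
        "n_viewpoints": int(plan.n_viewpoints),
        "fraction_inside_cylinder":
            float(np.mean((r <= cfg.cylinder_radius)
                          & (plan.coords[:, 2] >= 0)
                          & (plan.coords[:, 2] <= cfg.cylinder_depth))),
        "all_inside": bool(inside),
    }


def split_summary(seed: int = 0) -> dict:
    tr, va = split_train_validation(135, 0.7, seed=seed)
    return {"n_train": int(len(tr)), "n_validation": int(len(va))}


def bin_summary() -> dict:
    return {
        "n_depth_bins": len(make_bins(100.0, 20.0)) - 1,
        "n_radius_bins": len(make_bins(50.0, 10.0)) - 1,
    }


# ---------------------------------------------------------------------------
# Flat-density property of the volume normalization
# ---------------------------------------------------------------------------

def flat_density_uniform(n_plants: int = 200, seed: int = 0) -> dict:
    """Uniform random roots must give a flat radius-density profile even
    though raw counts grow with radius.

    Returns the per-bin densities, the maximum |z| of any bin mean against
    the across-bin mean (Monte Carlo standard errors), and whether raw
    counts increase monotonically over the annuli.
    """
    scene = desk_scene(thin_rate_profile=constant_rate_profile(0.3),
                       thick_root_count=0, shallow_damage_fraction=0.0)
    edges = make_bins(scene.cylinder_radius, 10.0)
    v = sphere_volume_cm3(scene.sense_radius)
    dens = np.zeros((n_plants, len(edges) - 1))
    counts = np.zeros(len(edges) - 1)
    for k in range(n_plants):
        system = generate_root_system(scene, "control",
                                      derive_seed(seed, "uplant", k), k)
        plan = generate_sampling_plan(scene, derive_seed(seed, "uplan", k))
        visible = sense_roots(plan, system, scene.sense_radius)
        dets = [Detection(int(plan.viewpoint_id[i]), (0, 0, 1, 1), "thin", 1.0, 1.0)
                for i in range(plan.n_viewpoints) for _ in visible[i]]
        obs = observations_frame(dets, plan, plant_id=k)
        prof = build_density_profile(obs, plan, "radius", edges, v)
        dens[k] = prof.density
        counts += prof.counts
    bin_means = np.nanmean(dens, axis=0)
    bin_se = np.nanstd(dens, axis=0, ddof=1) / math.sqrt(n_plants)
    grand = bin_means.mean()
    z = (bin_means - grand) / bin_se
    return {
        "n_plants": n_plants,
        "bin_mean_density": bin_means.tolist(),
        "raw_counts": counts.tolist(),
        "counts_increase_with_radius": bool(np.all(np.diff(counts) > 0)),
        "max_abs_z": float(np.max(np.abs(z))),
    }


# ---------------------------------------------------------------------------
# Oracle agreement
# ---------------------------------------------------------------------------

def _welch_closed_form(a, b):
    from scipy.stats import t as tdist
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df, 2.0 * tdist.sf(abs(t), df)


def oracle_summary(seed: int = 0, n_random: int = 200) -> dict:
    """Max deviations from independent recomputations: Welch t vs the
    closed form, HSV vs the matplotlib conversion, sensing vs the
    brute-force all-pairs loop."""
    rng = np.random.default_rng(derive_seed(seed, "oracle"))

    welch_diff = 0.0
    for _ in range(50):
        a = rng.normal(0, 1 + rng.uniform(), rng.integers(4, 20))
        b = rng.normal(rng.uniform(-1, 1), 1 + rng.uniform(), rng.integers(4, 20))
        r = two_tailed_t_test(a, b)
        t, df, p = _welch_closed_form(a, b)
        welch_diff = max(welch_diff, abs(r.t_statistic - t),
                         abs(r.degrees_of_freedom - df), abs(r.p_value - p))

    from matplotlib.colors import rgb_to_hsv as mpl_rgb_to_hsv
    hsv_diff = 0.0
    for _ in range(n_random):
        rgb = rng.uniform(0, 1, 3)
        h, s, v = rgb_to_hsv(*rgb)
        oh, os_, ov = mpl_rgb_to_hsv(rgb)
        dh = abs(h - oh * 360.0)
        hsv_diff = max(hsv_diff, min(dh, 360.0 - dh) / 360.0,
                       abs(s - os_), abs(v - ov))

    scene = desk_scene()
    system = generate_root_system(scene, "control", derive_seed(seed, "oplant"))
    plan = generate_sampling_plan(scene, derive_seed(seed, "oplan"))
    visible = sense_roots(plan, system, scene.sense_radius)
    mismatches = 0
    for i in range(plan.n_viewpoints):
        p = plan.coords[i]
        expect = []
        for j, seg in enumerate(system.segments):
            ab = seg.end - seg.start
            t = min(max(float(np.dot(p - seg.start, ab) / np.dot(ab, ab)), 0.0), 1.0)
            if np.linalg.norm(p - (seg.start + t * ab)) <= scene.sense_radius:
                expect.append(j)
        if list(visible[i]) != expect:
            mismatches += 1
    return {
        "welch_max_abs_diff": welch_diff,
        "hsv_max_abs_diff": hsv_diff,
        "sense_roots_mismatched_viewpoints": mismatches,
    }


# ---------------------------------------------------------------------------
# Null calibration and effect recovery
# ---------------------------------------------------------------------------

def null_type_i(n_cohorts: int = 500, seed: int = 0) -> dict:
    """Per-feature rejection rate at alpha = 0.05 with all effects zeroed."""
    rej: dict[str, int] = {}
    for c in range(n_cohorts):
        scene = SceneConfig(n_tunnels=10, viewpoints_per_tunnel=5,
                            shallow_damage_fraction=0.0, root_darkening=0.0)
        cfg = ExperimentConfig(scene=scene, mccv_iterations=2,
                               master_seed=derive_seed(seed, "null", c))
        res = run_cohort(cfg)
        for _, row in res.report.iterrows():
            rej[row["feature"]] = rej.get(row["feature"], 0) \
                + (row["p_value"] < 0.05)
    rates = {k: v / n_cohorts for k, v in rej.items()}
    return {
        "n_cohorts": n_cohorts,
        "rates": rates,
        "mean_rate": float(np.mean(list(rates.values()))),
        "min_rate": float(min(rates.values())),
        "max_rate": float(max(rates.values())),
    }


def effect_recovery(n_cohorts: int = 50, seed: int = 0,
                    mccv_iterations: int = 200) -> dict:
    """Default effect config over repeated cohorts: how often the smallest
    p-value is a thin-root structure feature, how often all ten vegetation
    indices stay non-significant, and the mean PLS-DA test accuracy."""
    winners = 0
    veg_ns = 0
    acc = []
    smallest = []
    for c in range(n_cohorts):
        cfg = ExperimentConfig(mccv_iterations=mccv_iterations,
                               master_seed=derive_seed(seed, "effect", c))
        res = run_cohort(cfg)
        row = res.report.loc[res.report["p_value"].idxmin()]
        winners += row["feature"] in STRUCTURE_HEADLINE_FEATURES
        smallest.append(float(row["p_value"]))
        veg_ns += all(p > 0.05
                      for p in res.p_values("shoot_vegetation_indices").values())
        acc.append(res.plsda.mean_test_accuracy)
    return {
        "n_cohorts": n_cohorts,
        "structure_smallest_p_fraction": winners / n_cohorts,
        "all_vegetation_ns_fraction": veg_ns / n_cohorts,
        "plsda_mean_test_accuracy": float(np.mean(acc)),
        "median_smallest_p": float(np.median(smallest)),
    }


# ---------------------------------------------------------------------------
# Detector quality
# ---------------------------------------------------------------------------

def detector_batch(n_images: int = 200, seed: int = 0) -> dict:
    """Precision/recall of the rule-based detector against renderer ground
    truth over a mixed-group rendered batch."""
    scene = desk_scene()
    truth: dict[str, list] = {}
    dets = []
    n_img = 0
    pid = 0
    while n_img < n_images:
        group = "inoculated" if pid % 2 else "control"
        system = generate_root_system(scene, group,
                                      derive_seed(seed, "dplant", pid), pid)
        plan = generate_sampling_plan(scene, derive_seed(seed, "dplan", pid))
        visible = sense_roots(plan, system, scene.sense_radius)
        for i in range(plan.n_viewpoints):
            if n_img >= n_images:
                break
            image_id = f"{pid}_{i}"
            segs = [system.segments[int(j)] for j in visible[i]]
            img = render_root_image(plan.coords[i], segs,
                                    seed=derive_seed(seed, "drender", pid, i),
                                    viewpoint_id=image_id)
            truth[image_id] = img.ground_truth
            dets.extend(detect_roots(img.pixels, image_id=image_id))
            n_img += 1
        pid += 1
    m = evaluate_detector(truth, dets, overlap_threshold=0.5)
    return {
        "n_images": n_images,
        "n_truth_boxes": int(sum(len(v) for v in truth.values())),
        "n_detections": len(dets),
        "precision": m.precision,
        "recall": m.recall,
    }
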