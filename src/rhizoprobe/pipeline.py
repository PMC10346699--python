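"""End-to-end seeded cohort pipeline and detector evaluation.

``run_cohort`` reproduces the study design at a configurable scale:
generate a cohort of plants (half inoculated), probe each with the sampling
plan, derive per-root observations either by rendering and detecting probe
images (``mode="full"``) or directly from the sensed ground-truth segments
with observation-level color noise (``mode="direct"``), build the shoot
branch from rendered side-view images, and run both statistical screens.

The default experiment scale is 20 tunnels x 10 viewpoints per plant, which
keeps a 32-plant cohort fast while preserving every statistical property;
``full_viewpoints()`` restores the full 130 x 35 design.

The master seed fans out to per-plant and per-stage seeds through a stable
hash of ``seed/plant/stage`` strings, so any stage is reproducible in
isolation and reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import shoot_features as sf
from . import spatial_density as sd
from .group_stats import MCCVResult, build_comparison_report, plsda_mccv, ttest_table
from .root_detection import (
    Detection, DetectorConfig, RootColorFeatures, analyze_root_image,
    THIN, THICK,
)
from .synthetic_scene import (
    CONTROL, INOCULATED, RenderConfig, SceneConfig, SamplingPlan, RootSystem,
    generate_root_system, generate_sampling_plan, render_root_image,
    render_shoot_image, sample_shoot_params, sense_roots,
)

Array = np.ndarray

SHOOT_PLSDA_FEATURES = ["R", "G", "B", "H", "S", "V", "leaf_area_px", "height_px"]


def derive_seed(master_seed: int, *parts: object) -> int:
    """Stable sub-seed from the master seed and a path of stage labels."""
    key = "/".join([str(master_seed), *map(str, parts)])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31 - 1)


@dataclass
class ExperimentConfig:
    """Full configuration of one simulated cohort experiment."""

    scene: SceneConfig = field(default_factory=lambda: SceneConfig(
        n_tunnels=20, viewpoints_per_tunnel=10))
    render: RenderConfig = field(default_factory=RenderConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    depth_bin_mm: float = 20.0
    radius_bin_mm: float = 10.0
    mccv_iterations: int = 1000
    mccv_train_fraction: float = 0.7
    plsda_components: int = 2
    mode: str = "direct"              # "direct" or "full"
    observation_color_sigma: float = 4.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("direct", "full"):
            raise ValueError("mode must be 'direct' or 'full'")

    def full_viewpoints(self) -> "ExperimentConfig":
        """Copy of this config at the full 130 x 35 sampling design."""
        scene = dataclasses.replace(self.scene, n_tunnels=130,
                                    viewpoints_per_tunnel=35)
        return dataclasses.replace(self, scene=scene)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scene"].pop("thin_rate_profile", None)  # callables are not serialized
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        scene = SceneConfig(**d.pop("scene", {}))
        render_d = d.pop("render", {})
        for k in ("distance_factor_bounds", "soil_rgb"):
            if k in render_d and isinstance(render_d[k], list):
                render_d[k] = tuple(render_d[k])
        render = RenderConfig(**render_d)
        det_d = d.pop("detector", {})
        if isinstance(det_d.get("hue_band"), list):
            det_d["hue_band"] = tuple(det_d["hue_band"])
        detector = DetectorConfig(**det_d)
        return cls(scene=scene, render=render, detector=detector, **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    mode: str
    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, outputs: list[str], status: str = "ok") -> None:
        self.stages.append({"stage": name, "outputs": outputs, "status": status})

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclass
class CohortResult:
    config: ExperimentConfig
    groups: dict[int, str]
    shoot_features: pd.DataFrame
    root_color_features: pd.DataFrame
    root_structure_features: pd.DataFrame
    observations: pd.DataFrame
    depth_profiles: dict[int, sd.DensityProfile]
    radius_profiles: dict[int, sd.DensityProfile]
    depth_summary: pd.DataFrame
    radius_summary: pd.DataFrame
    ttests: dict[str, pd.DataFrame]
    plsda: MCCVResult
    report: pd.DataFrame
    manifest: RunManifest

    def p_values(self, approach: str) -> dict[str, float]:
        t = self.ttests[approach]
        return dict(zip(t["feature"], t["p"]))


def assign_groups(config: SceneConfig, seed: int) -> dict[int, str]:
    """Random half/half (by ``inoculated_fraction``) group assignment."""
    n = config.n_plants
    n_inoc = int(round(n * config.inoculated_fraction))
    perm = np.random.default_rng(seed).permutation(n)
    groups = {int(pid): CONTROL for pid in perm}
    for pid in perm[:n_inoc]:
        groups[int(pid)] = INOCULATED
    return {pid: groups[pid] for pid in sorted(groups)}


def _direct_observations(plan: SamplingPlan, system: RootSystem,
                         visible: list[Array], rng: np.random.Generator,
                         color_sigma: float, plant_id: int,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ground-truth observations with per-observation color jitter."""
    obs_rows, color_rows = [], []
    for i in range(plan.n_viewpoints):
        vid = int(plan.viewpoint_id[i])
        x, y, z = plan.coords[i]
        for j in visible[i]:
            seg = system.segments[int(j)]
            rgb = np.clip(np.asarray(seg.color)
                          + rng.normal(0.0, color_sigma, 3), 0, 255) / 255.0
            h, s, v = sf.rgb_to_hsv(*rgb)
            obs_rows.append({
                "plant_id": plant_id, "viewpoint_id": vid,
                "x_mm": float(x), "y_mm": float(y), "z_mm": float(z),
                "class": seg.true_class, "depth_mm": float(z),
                "radius_mm": math.hypot(float(x), float(y)),
                "segment_id": int(seg.segment_id),
            })
            color_rows.append({"plant_id": plant_id, "class": seg.true_class,
                               "R": rgb[0], "G": rgb[1], "B": rgb[2],
                               "H": h, "S": s, "V": v})
    cols = ["plant_id", "viewpoint_id", "x_mm", "y_mm", "z_mm",
            "class", "depth_mm", "radius_mm", "segment_id"]
    return (pd.DataFrame(obs_rows, columns=cols),
            pd.DataFrame(color_rows,
                         columns=["plant_id", "class", "R", "G", "B", "H", "S", "V"]))


def _full_observations(plan: SamplingPlan, system: RootSystem,
                       visible: list[Array], config: ExperimentConfig,
                       plant_id: int, image_dir: Path | None = None,
                       ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Render every viewpoint, detect, and map detections to 3D."""
    detections: list[Detection] = []
    colors: list[tuple[str, RootColorFeatures]] = []
    truth: dict[int, list] = {}
    for i in range(plan.n_viewpoints):
        vid = int(plan.viewpoint_id[i])
        segs = [system.segments[int(j)] for j in visible[i]]
        img = render_root_image(
            plan.coords[i], segs, config.render,
            seed=derive_seed(config.master_seed, "render", plant_id, vid),
            viewpoint_id=vid)
        truth[vid] = img.ground_truth
        for det, col in analyze_root_image(img.pixels, config.detector, image_id=vid):
            detections.append(det)
            colors.append((det.klass, col))
        if image_dir is not None:
            from PIL import Image
            Image.fromarray(img.pixels).save(
                image_dir / f"plant{plant_id:03d}_vp{vid:05d}.png")
    obs = sd.observations_frame(detections, plan, plant_id=plant_id)
    color_rows = [{"plant_id": plant_id, "class": klass,
                   "R": c.R, "G": c.G, "B": c.B, "H": c.H, "S": c.S, "V": c.V}
                  for klass, c in colors]
    return (obs,
            pd.DataFrame(color_rows,
                         columns=["plant_id", "class", "R", "G", "B", "H", "S", "V"]),
            truth)


def _per_class_color_features(color_obs: pd.DataFrame, plant_id: int,
                              group: str) -> dict:
    """Per-plant mean root color per class; HSV of the mean RGB."""
    row: dict = {"plant_id": plant_id, "group": group}
    for klass in (THIN, THICK):
        sub = color_obs[color_obs["class"] == klass]
        if len(sub):
            r, g, b = sub["R"].mean(), sub["G"].mean(), sub["B"].mean()
            h, s, v = sf.rgb_to_hsv(r, g, b)
            vals = {"R": r, "G": g, "B": b, "H": h, "S": s, "V": v}
        else:
            vals = {k: math.nan for k in ("R", "G", "B", "H", "S", "V")}
        row.update({f"{klass}_{k}": float(val) for k, val in vals.items()})
    return row


def run_cohort(config: ExperimentConfig, out_dir: str | Path | None = None,
               write_images: bool = False) -> CohortResult:
    """Simulate and analyze one full cohort.

    Runs the root branch (probe sampling, observation extraction, density
    profiles, root color and structure t-tests) and the shoot branch
    (side-view render, calibration, segmentation, color/morphology/index
    features, vegetation-index t-tests, PLS-DA with MCCV), and merges all
    p-values into the cross-approach comparison report.  Deterministic under
    a fixed ``config.master_seed``.
    """
    scene = config.scene
    seed = config.master_seed
    manifest = RunManifest(config.config_hash(), seed, config.mode)
    groups = assign_groups(scene, derive_seed(seed, "groups"))

    out = Path(out_dir) if out_dir is not None else None
    image_dir = None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        if write_images and config.mode == "full":
            image_dir = out / "images"
            image_dir.mkdir(exist_ok=True)

    v_sense = sd.sphere_volume_cm3(scene.sense_radius)
    depth_edges = sd.make_bins(scene.cylinder_depth, config.depth_bin_mm)
    radius_edges = sd.make_bins(scene.cylinder_radius, config.radius_bin_mm)

    obs_frames, color_feature_rows, structure_rows, shoot_rows = [], [], [], []
    depth_profiles: dict[int, sd.DensityProfile] = {}
    radius_profiles: dict[int, sd.DensityProfile] = {}

    for pid, group in groups.items():
        plan = generate_sampling_plan(scene, derive_seed(seed, "plan", pid))
        system = generate_root_system(scene, group, derive_seed(seed, "plant", pid),
                                      plant_id=pid)
        visible = sense_roots(plan, system, scene.sense_radius)
        if config.mode == "direct":
            rng = np.random.default_rng(derive_seed(seed, "obs", pid))
            obs, color_obs = _direct_observations(
                plan, system, visible, rng, config.observation_color_sigma, pid)
        else:
            obs, color_obs, _ = _full_observations(
                plan, system, visible, config, pid, image_dir)
        obs_frames.append(obs)
        color_feature_rows.append(_per_class_color_features(color_obs, pid, group))
        structure_rows.append({"plant_id": pid, "group": group,
                               **sd.per_plant_root_features(obs)})
        thin_obs = obs[obs["class"] == THIN]
        depth_profiles[pid] = sd.build_density_profile(
            thin_obs, plan, "depth", depth_edges, v_sense)
        radius_profiles[pid] = sd.build_density_profile(
            thin_obs, plan, "radius", radius_edges, v_sense)

        # shoot branch: identical parameter distribution for both groups
        srng = np.random.default_rng(derive_seed(seed, "shoot", pid))
        params = sample_shoot_params(srng)
        gain = tuple(srng.uniform(0.75, 1.2, 3))
        shoot_img = render_shoot_image(params, gain,
                                       seed=derive_seed(seed, "shootimg", pid))
        fv, indices = sf.shoot_feature_vector(shoot_img.pixels,
                                              shoot_img.board_region)
        shoot_rows.append({"plant_id": pid, "group": group,
                           **dataclasses.asdict(fv), **indices})

    observations = pd.concat(obs_frames, ignore_index=True)
    shoot_df = pd.DataFrame(shoot_rows)
    color_df = pd.DataFrame(color_feature_rows)
    structure_df = pd.DataFrame(structure_rows)

    depth_summary = sd.profile_summary_per_group(depth_profiles, groups)
    radius_summary = sd.profile_summary_per_group(radius_profiles, groups)

    ttests = {
        "shoot_vegetation_indices": ttest_table(
            shoot_df, feature_cols=list(sf.VEGETATION_INDEX_NAMES)),
        "root_color": ttest_table(
            color_df, feature_cols=[f"{k}_{c}" for k in (THIN, THICK)
                                    for c in ("R", "G", "B", "H", "S", "V")]),
        "root_structure": ttest_table(
            structure_df,
            feature_cols=["n_thin", "n_thick", "mean_depth_thin",
                          "mean_depth_thick", "mean_radius_thin",
                          "mean_radius_thick"]),
    }

    X = shoot_df[SHOOT_PLSDA_FEATURES].to_numpy(dtype=float)
    y = shoot_df["group"].to_numpy()
    plsda = plsda_mccv(X, y, train_fraction=config.mccv_train_fraction,
                       n_iterations=config.mccv_iterations,
                       n_components=config.plsda_components,
                       seed=derive_seed(seed, "plsda"))

    report = build_comparison_report({
        name: dict(zip(t["feature"], t["p"])) for name, t in ttests.items()})

    result = CohortResult(
        config=config, groups=groups, shoot_features=shoot_df,
        root_color_features=color_df, root_structure_features=structure_df,
        observations=observations, depth_profiles=depth_profiles,
        radius_profiles=radius_profiles, depth_summary=depth_summary,
        radius_summary=radius_summary, ttests=ttests, plsda=plsda,
        report=report, manifest=manifest)

    if out is not None:
        _write_artifacts(result, out)
    return result


def _write_artifacts(result: CohortResult, out: Path) -> None:
    cfg = result.config
    cfg.to_yaml(out / "config.yaml")
    written = ["config.yaml"]

    def save(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, index=False)
        written.append(name)

    save(result.shoot_features, "shoot_features.csv")
    save(result.root_color_features, "root_color_features.csv")
    save(result.root_structure_features, "root_structure_features.csv")
    save(result.observations, "observations.csv")
    profiles = []
    for axis, profs in (("depth", result.depth_profiles),
                        ("radius", result.radius_profiles)):
        for pid, prof in profs.items():
            f = prof.to_frame()
            f.insert(0, "plant_id", pid)
            f.insert(1, "group", result.groups[pid])
            profiles.append(f)
    save(pd.concat(profiles, ignore_index=True), "density_profiles.csv")
    save(result.depth_summary, "density_depth_summary.csv")
    save(result.radius_summary, "density_radius_summary.csv")
    for name, t in result.ttests.items():
        save(t, f"ttests_{name}.csv")
    save(result.report, "comparison_report.csv")
    (out / "plsda.json").write_text(json.dumps({
        "n_iterations": result.plsda.n_iterations,
        "train_fraction": result.plsda.train_fraction,
        "mean_train_accuracy": result.plsda.mean_train_accuracy,
        "mean_test_accuracy": result.plsda.mean_test_accuracy,
    }, indent=2))
    written.append("plsda.json")
    result.manifest.add("run_cohort", written)
    (out / "run_manifest.json").write_text(result.manifest.to_json())


# ---------------------------------------------------------------------------
# Detector evaluation
# ---------------------------------------------------------------------------

def box_iou(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> float:
    """Intersection-over-union of two half-open pixel boxes."""
    ix = max(0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    union = area_a + area_b - inter
    return inter / union if union > 0 else 0.0


@dataclass
class DetectionMetrics:
    precision: float
    recall: float
    true_positives: int
    false_positives: int
    false_negatives: int
    confusion: pd.DataFrame          # rows: true class, cols: predicted class
    precision_defined: bool = True


def evaluate_detector(ground_truth: dict, detections: list[Detection],
                      overlap_threshold: float = 0.5) -> DetectionMetrics:
    """Greedy one-to-one matching of detections to ground-truth boxes.

    ``ground_truth`` maps image_id to a list of (box, class) entries (the
    renderer's format).  Detections are matched in order of descending score
    to the unmatched truth box of highest overlap at or above the threshold;
    matching is class-agnostic, and matched pairs feed the per-class
    confusion table.  With no detections, precision is undefined and
    reported as 0 with ``precision_defined=False``.
    """
    dets_by_image: dict = {}
    for det in detections:
        dets_by_image.setdefault(det.image_id, []).append(det)

    tp = fp = 0
    confusion = {(t, p): 0 for t in (THIN, THICK) for p in (THIN, THICK)}
    n_truth = sum(len(v) for v in ground_truth.values())
    for image_id, truth in ground_truth.items():
        dets = sorted(dets_by_image.pop(image_id, []),
                      key=lambda d: -d.score)
        matched = [False] * len(truth)
        for det in dets:
            best, best_iou = -1, overlap_threshold
            for i, (tbox, _) in enumerate(truth):
                if matched[i]:
                    continue
                iou = box_iou(det.box, tbox)
                if iou >= best_iou:
                    best, best_iou = i, iou
            if best >= 0:
                matched[best] = True
                tp += 1
                confusion[(truth[best][1], det.klass)] += 1
            else:
                fp += 1
    # detections on images absent from the truth set are false positives
    for dets in dets_by_image.values():
        fp += len(dets)
    fn = n_truth - tp

    precision_defined = (tp + fp) > 0
    precision = tp / (tp + fp) if precision_defined else 0.0
    recall = tp / n_truth if n_truth > 0 else 1.0
    conf = pd.DataFrame(
        [[confusion[(t, p)] for p in (THIN, THICK)] for t in (THIN, THICK)],
        index=[THIN, THICK], columns=[THIN, THICK])
    return DetectionMetrics(precision, recall, tp, fp, fn, conf,
                            precision_defined)
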