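"""Plain-text artifact IO for pipeline stages.

Scenes, sampling plans, ground truth and detections are exchanged between
stages as CSV/JSON/PNG so every stage can run standalone on files:

* ``segments.csv``   - plant_id, segment_id, endpoints, thickness, color, class
* ``viewpoints.csv`` - plant_id, viewpoint_id, tunnel_id, x_mm, y_mm, z_mm
                       (plus image_path after rendering)
* ``groups.csv``     - plant_id, group
* ``ground_truth.json`` - image_path -> boxes (half-open pixel coords) + classes
* ``detections.csv`` - image/viewpoint ids, box, class, thickness, score, color
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .root_detection import Detection, RootColorFeatures
from .synthetic_scene import RootSegment, RootSystem, SamplingPlan


def segments_frame(systems: dict[int, RootSystem]) -> pd.DataFrame:
    rows = []
    for pid, system in systems.items():
        for s in system.segments:
            rows.append({
                "plant_id": pid, "segment_id": s.segment_id,
                "x0": s.start[0], "y0": s.start[1], "z0": s.start[2],
                "x1": s.end[0], "y1": s.end[1], "z1": s.end[2],
                "thickness_mm": s.thickness,
                "r": s.color[0], "g": s.color[1], "b": s.color[2],
                "class": s.true_class,
            })
    return pd.DataFrame(rows, columns=[
        "plant_id", "segment_id", "x0", "y0", "z0", "x1", "y1", "z1",
        "thickness_mm", "r", "g", "b", "class"])


def systems_from_frame(df: pd.DataFrame,
                       groups: dict[int, str]) -> dict[int, RootSystem]:
    systems: dict[int, RootSystem] = {}
    for pid, sub in df.groupby("plant_id"):
        segments = [RootSegment(
            segment_id=int(r.segment_id),
            start=np.array([r.x0, r.y0, r.z0]),
            end=np.array([r.x1, r.y1, r.z1]),
            thickness=float(r.thickness_mm),
            color=(float(r.r), float(r.g), float(r.b)),
            true_class=str(r["class"]),
        ) for _, r in sub.iterrows()]
        systems[int(pid)] = RootSystem(int(pid), groups.get(int(pid), ""), segments)
    return systems


def viewpoints_frame(plans: dict[int, SamplingPlan]) -> pd.DataFrame:
    frames = []
    for pid, plan in plans.items():
        frames.append(pd.DataFrame({
            "plant_id": pid,
            "viewpoint_id": plan.viewpoint_id,
            "tunnel_id": plan.tunnel_id,
            "x_mm": plan.coords[:, 0],
            "y_mm": plan.coords[:, 1],
            "z_mm": plan.coords[:, 2],
        }))
    return pd.concat(frames, ignore_index=True)


def plans_from_frame(df: pd.DataFrame) -> dict[int, SamplingPlan]:
    plans: dict[int, SamplingPlan] = {}
    for pid, sub in df.groupby("plant_id"):
        plans[int(pid)] = SamplingPlan(
            tunnels=[],
            viewpoint_id=sub["viewpoint_id"].to_numpy(dtype=int),
            tunnel_id=sub["tunnel_id"].to_numpy(dtype=int),
            coords=sub[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
        )
    return plans


def save_ground_truth(path: str | Path, truth: dict[str, list]) -> None:
    """``truth`` maps image_path to a list of (box, class) pairs."""
    payload = {img: {"boxes": [list(map(int, box)) for box, _ in entries],
                     "classes": [klass for _, klass in entries]}
               for img, entries in truth.items()}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_ground_truth(path: str | Path) -> dict[str, list]:
    payload = json.loads(Path(path).read_text())
    return {img: list(zip(map(tuple, d["boxes"]), d["classes"]))
            for img, d in payload.items()}


def detections_frame(results: list[tuple[Detection, RootColorFeatures]],
                     plant_ids: list[int] | None = None) -> pd.DataFrame:
    rows = []
    for i, (det, col) in enumerate(results):
        rows.append({
            "plant_id": plant_ids[i] if plant_ids else 0,
            "image_id": det.image_id,
            "x_min": det.box[0], "y_min": det.box[1],
            "x_max": det.box[2], "y_max": det.box[3],
            "class": det.klass, "thickness_px": det.thickness_px,
            "score": det.score,
            "R": col.R, "G": col.G, "B": col.B,
            "H": col.H, "S": col.S, "V": col.V,
        })
    return pd.DataFrame(rows, columns=[
        "plant_id", "image_id", "x_min", "y_min", "x_max", "y_max",
        "class", "thickness_px", "score", "R", "G", "B", "H", "S", "V"])


def detections_from_frame(df: pd.DataFrame) -> list[Detection]:
    return [Detection(
        image_id=r.image_id,
        box=(int(r.x_min), int(r.y_min), int(r.x_max), int(r.y_max)),
        klass=str(r["class"]),
        thickness_px=float(r.thickness_px),
        score=float(r.score),
    ) for _, r in df.iterrows()]
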