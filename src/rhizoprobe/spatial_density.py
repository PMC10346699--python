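"""Volume-normalized spatial root-density profiles.

Each detection inherits the 3D coordinate of the viewpoint it was imaged
from; depth is the distance below the soil surface (z) and radius the
horizontal distance from the stem axis.  Raw counts per spatial bin are
misleading because the probe plan places far more viewpoints in the outer
annuli than near the stem, so densities are reported per cm^3 of sampled
volume: each viewpoint senses a nominal volume ``v_sense`` and a bin's
sampled volume is (viewpoints in bin) x v_sense.  Overlap between nearby
sensing regions is ignored in this model (a documented, group-symmetric
bias); the defining property preserved is that uniformly distributed roots
yield a flat density profile even though raw counts grow with radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .root_detection import Detection, THIN, THICK
from .synthetic_scene import SamplingPlan

Array = np.ndarray


def sphere_volume_cm3(radius_mm: float) -> float:
    """Nominal per-viewpoint sensed volume: a sphere of the sensing radius."""
    return (4.0 / 3.0) * math.pi * (radius_mm / 10.0) ** 3


@dataclass
class DensityProfile:
    axis: str                 # "depth" or "radius"
    bin_edges: Array          # mm, len n_bins + 1
    counts: Array             # roots per bin
    viewpoints_per_bin: Array
    sampled_volume_cm3: Array
    density: Array            # roots per cm^3; NaN where no viewpoints

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "axis": self.axis,
            "bin_lo": self.bin_edges[:-1],
            "bin_hi": self.bin_edges[1:],
            "count": self.counts,
            "n_viewpoints": self.viewpoints_per_bin,
            "volume_cm3": self.sampled_volume_cm3,
            "density_per_cm3": self.density,
        })


def map_detection_to_3d(detection: Detection, viewpoint_coord: Array,
                        plant_id: int = 0) -> dict:
    """Tag a detection with its viewpoint's 3D coordinate, depth and radius."""
    x, y, z = (float(c) for c in np.asarray(viewpoint_coord, dtype=float))
    return {
        "plant_id": plant_id,
        "viewpoint_id": detection.image_id,
        "x_mm": x,
        "y_mm": y,
        "z_mm": z,
        "class": detection.klass,
        "depth_mm": z,
        "radius_mm": math.hypot(x, y),
    }


def observations_frame(detections: list[Detection], plan: SamplingPlan,
                       plant_id: int = 0) -> pd.DataFrame:
    """Batch-map detections to 3D observations via the sampling plan.

    Each detection's ``image_id`` must be a viewpoint id of the plan.
    """
    coord_by_id = {int(v): plan.coords[i]
                   for i, v in enumerate(plan.viewpoint_id)}
    rows = []
    for det in detections:
        vid = int(det.image_id)
        if vid not in coord_by_id:
            raise KeyError(f"unknown viewpoint_id {vid}")
        rows.append(map_detection_to_3d(det, coord_by_id[vid], plant_id))
    cols = ["plant_id", "viewpoint_id", "x_mm", "y_mm", "z_mm",
            "class", "depth_mm", "radius_mm"]
    return pd.DataFrame(rows, columns=cols)


def make_bins(extent_mm: float, bin_width_mm: float) -> Array:
    """Half-open bins [e_i, e_{i+1}) covering [0, extent]; the last bin is
    closed at the extent (and absorbs any remainder if the width does not
    divide the extent)."""
    if bin_width_mm <= 0:
        raise ValueError("bin width must be positive")
    if extent_mm <= 0:
        raise ValueError("extent must be positive")
    edges = list(np.arange(0.0, extent_mm, bin_width_mm))
    if extent_mm - edges[-1] < 1e-9 * extent_mm:
        edges[-1] = extent_mm
    else:
        edges.append(extent_mm)
    return np.asarray(edges)


def build_density_profile(observations: pd.DataFrame, plan: SamplingPlan,
                          axis: str, bin_edges: Array,
                          v_sense_cm3: float) -> DensityProfile:
    """Bin observations on depth or radius and normalize by sampled volume.

    counts = observations per bin; sampled volume = viewpoints in bin times
    ``v_sense_cm3``; density = counts / volume, NaN for bins holding no
    viewpoints.  numpy's histogram convention closes the final bin.
    """
    if v_sense_cm3 <= 0:
        raise ValueError("v_sense_cm3 must be positive")
    if axis == "depth":
        values = observations["depth_mm"].to_numpy(dtype=float)
        vp_values = plan.coords[:, 2]
    elif axis == "radius":
        values = observations["radius_mm"].to_numpy(dtype=float)
        vp_values = np.hypot(plan.coords[:, 0], plan.coords[:, 1])
    else:
        raise ValueError(f"axis must be 'depth' or 'radius', got {axis!r}")
    edges = np.asarray(bin_edges, dtype=float)
    if len(values) and (values.min() < edges[0] or values.max() > edges[-1]):
        raise ValueError("observation outside the binned extent")
    counts, _ = np.histogram(values, bins=edges)
    vp_counts, _ = np.histogram(vp_values, bins=edges)
    volume = vp_counts * v_sense_cm3
    with np.errstate(divide="ignore", invalid="ignore"):
        density = np.where(vp_counts > 0, counts / volume, np.nan)
    return DensityProfile(
        axis=axis,
        bin_edges=edges,
        counts=counts.astype(int),
        viewpoints_per_bin=vp_counts.astype(int),
        sampled_volume_cm3=volume,
        density=density,
    )


def profile_summary_per_group(profiles: dict[int, DensityProfile],
                              group_labels: dict[int, str]) -> pd.DataFrame:
    """Bin-wise mean and standard deviation of density per treatment group.

    ``profiles`` maps plant_id to a per-plant profile (all on identical
    edges); ``group_labels`` maps plant_id to its group.  Requires at least
    two plants per group.
    """
    groups = sorted(set(group_labels.values()))
    ref_edges = None
    rows = []
    for grp in groups:
        ids = [pid for pid, g in group_labels.items() if g == grp]
        if len(ids) < 2:
            raise ValueError(f"need at least 2 plants in group {grp!r}")
        dens = np.stack([profiles[pid].density for pid in ids])
        edges = profiles[ids[0]].bin_edges
        if ref_edges is None:
            ref_edges = edges
        elif not np.allclose(edges, ref_edges):
            raise ValueError("profiles use different bin edges")
        rows.append(pd.DataFrame({
            "group": grp,
            "axis": profiles[ids[0]].axis,
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "mean_density": np.nanmean(dens, axis=0),
            "sd_density": np.nanstd(dens, axis=0, ddof=1),
            "n_plants": len(ids),
        }))
    return pd.concat(rows, ignore_index=True)


def deduplicate_observations(observations: pd.DataFrame) -> pd.DataFrame:
    """Collapse repeated sightings of one physical segment to a single
    observation (first sighting kept).

    Requires a ``segment_id`` column, which only ground-truth-derived
    observations carry; detections from real or rendered images have no
    segment identity.  The default pipeline counts per sighting (the raw
    "number of roots detected" convention); this variant supports
    sensitivity analyses on synthetic truth.
    """
    if "segment_id" not in observations.columns:
        raise ValueError("observations carry no segment_id; deduplication "
                         "is only defined for ground-truth observations")
    return observations.drop_duplicates(
        subset=["plant_id", "segment_id"], keep="first").reset_index(drop=True)


def per_plant_root_features(observations: pd.DataFrame) -> dict[str, float]:
    """The six per-plant structure scalars: thin/thick counts and mean depth
    and radius per class (NaN means for absent classes)."""
    out: dict[str, float] = {}
    for klass in (THIN, THICK):
        sub = observations[observations["class"] == klass]
        out[f"n_{klass}"] = float(len(sub))
        out[f"mean_depth_{klass}"] = float(sub["depth_mm"].mean()) if len(sub) else math.nan
        out[f"mean_radius_{klass}"] = float(sub["radius_mm"].mean()) if len(sub) else math.nan
    return out
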