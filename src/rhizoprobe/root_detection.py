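"""Rule-based root detection in probe images.

The detector replaces a learned object detector with a deterministic,
config-driven rule pipeline behind the same interface: color segmentation of
root pixels (soil background, soil particles and specular highlights
removed), connected components, an inscribed-disk width estimate, and the
width + color thin/thick rule: a section is "thick" iff it is wider than 60
pixels on the image AND its mean color falls in the yellow/brown hue band
with sufficient saturation; otherwise it is "thin".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label, regionprops
from skimage.morphology import closing, disk

from .shoot_features import rgb_to_hsv

Array = np.ndarray

THIN = "thin"
THICK = "thick"


@dataclass
class DetectorConfig:
    """Thresholds of the rule-based detector.

    ``v_min``/``v_spec`` bound the brightness (HSV value) of root pixels:
    soil sits well below ``v_min`` and specular highlights above ``v_spec``.
    ``min_area`` removes soil particles and fragments.  The class rule uses
    ``thick_width_px`` (strict inequality), the yellow/brown ``hue_band`` in
    degrees, and the saturation floor ``s_min`` (whitish thin roots fail it).
    """

    v_min: float = 0.48
    v_spec: float = 0.96
    min_area: int = 150
    closing_radius: int = 2
    thick_width_px: float = 60.0
    hue_band: tuple[float, float] = (15.0, 55.0)
    s_min: float = 0.2


@dataclass
class Detection:
    image_id: int | str
    box: tuple[int, int, int, int]   # (x_min, y_min, x_max, y_max), half-open
    klass: str
    thickness_px: float
    score: float


@dataclass
class RootColorFeatures:
    R: float
    G: float
    B: float
    H: float
    S: float
    V: float
    n_pixels: int


def segment_root_pixels(image: Array, config: DetectorConfig | None = None) -> Array:
    """Binary mask of root pixels.

    Pixels are retained by brightness separation from the dark soil
    background, specular pixels (value above ``v_spec``) are dropped, small
    gaps are closed, and components below ``min_area`` (soil particles,
    fragments) are removed.
    """
    cfg = config or DetectorConfig()
    img = np.asarray(image, dtype=float) / 255.0
    v = img.max(axis=2)
    mask = (v >= cfg.v_min) & (v <= cfg.v_spec)
    if cfg.closing_radius > 0:
        mask = closing(mask, disk(cfg.closing_radius))
        # closing may re-annex specular interiors; keep them excluded
        mask &= img.max(axis=2) <= cfg.v_spec
    lab = label(mask)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return sizes[lab] >= cfg.min_area


def estimate_thickness_px(component_mask: Array) -> float:
    """Root width as the diameter of the widest inscribed disk.

    Computed as twice the maximum of the Euclidean distance transform inside
    the component (the array border counts as background).
    """
    m = np.asarray(component_mask, dtype=bool)
    if not m.any():
        raise ValueError("component mask is empty")
    padded = np.pad(m, 1)
    return float(2.0 * ndimage.distance_transform_edt(padded).max())


def classify_root(thickness_px: float, mean_hue: float, mean_sat: float,
                  config: DetectorConfig | None = None) -> str:
    """Width + color rule: thick iff strictly wider than the threshold and
    yellow/brown; thin otherwise."""
    cfg = config or DetectorConfig()
    if thickness_px <= 0:
        raise ValueError("thickness_px must be positive")
    lo, hi = cfg.hue_band
    is_thick = (thickness_px > cfg.thick_width_px
                and lo <= mean_hue <= hi
                and mean_sat >= cfg.s_min)
    return THICK if is_thick else THIN


def extract_root_color(image: Array, component_mask: Array) -> RootColorFeatures:
    """Mean color over the segmented root pixels of one component.

    RGB means are scaled to [0, 1]; H, S, V are the hexcone conversion of
    the mean color.  Soil, particles and specular pixels must already have
    been excluded by the segmentation mask.
    """
    m = np.asarray(component_mask, dtype=bool)
    if not m.any():
        raise ValueError("component mask is empty")
    px = np.asarray(image, dtype=float)[m] / 255.0
    r, g, b = (float(c) for c in px.mean(axis=0))
    h, s, v = rgb_to_hsv(r, g, b)
    return RootColorFeatures(r, g, b, h, s, v, int(m.sum()))


def analyze_root_image(image: Array, config: DetectorConfig | None = None,
                       image_id: int | str = 0,
                       ) -> list[tuple[Detection, RootColorFeatures]]:
    """Detect, classify and color-featurize every root section in an image.

    Connected components of the root-pixel mask become detections with tight
    bounding boxes; class from :func:`classify_root` on the component's
    estimated width and mean color; score is the component solidity.
    Deterministic: identical image, identical output.
    """
    cfg = config or DetectorConfig()
    mask = segment_root_pixels(image, cfg)
    if not mask.any():
        return []
    lab = label(mask)
    results: list[tuple[Detection, RootColorFeatures]] = []
    for region in regionprops(lab):
        if region.area < cfg.min_area:
            continue
        comp = lab == region.label
        thickness = estimate_thickness_px(comp)
        color = extract_root_color(image, comp)
        klass = classify_root(thickness, color.H, color.S, cfg)
        r0, c0, r1, c1 = region.bbox
        results.append((Detection(
            image_id=image_id,
            box=(int(c0), int(r0), int(c1), int(r1)),
            klass=klass,
            thickness_px=thickness,
            score=float(region.solidity),
        ), color))
    return results


def detect_roots(image: Array, config: DetectorConfig | None = None,
                 image_id: int | str = 0) -> list[Detection]:
    """Detections only (see :func:`analyze_root_image`)."""
    return [det for det, _ in analyze_root_image(image, config, image_id)]


def split_train_validation(n_items: int, train_fraction: float,
                           seed: int) -> tuple[Array, Array]:
    """Seeded disjoint, exhaustive train/validation split of item ids.

    The training size is ``n_items * train_fraction`` rounded half up, so a
    135-item set at 70:30 yields 95 training and 40 validation items.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    if n_items < 2:
        raise ValueError("need at least two items to split")
    n_train = int(math.floor(n_items * train_fraction + 0.5))
    n_train = min(max(n_train, 1), n_items - 1)
    perm = np.random.default_rng(seed).permutation(n_items)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])
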