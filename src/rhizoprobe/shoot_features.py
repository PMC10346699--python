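"""Side-view shoot analysis.

White-reference calibration, excess-green plant segmentation, mean RGB/HSV
color, silhouette morphology (side-view leaf area and plant height in
pixels), and a ten-index RGB vegetation battery:

======  ==========================================
ExG     2G - R - B
ExGR    ExG - ExR, with ExR = 1.4R - G
NGRDI   (G - R) / (G + R)
NBRDI   (G - B) / (G + B)
RGRI    R / G
GBRI    B / G
CIVE    0.441R - 0.811G + 0.385B + 18.78745
VEG     G / (R^a * B^(1-a)), a = 0.667
RGBVI   (G^2 - B*R) / (G^2 + B*R)
MGRVI   (G^2 - R^2) / (G^2 + R^2)
======  ==========================================

Channels are on [0, 1] throughout; the CIVE intercept is kept as printed in
the source formula regardless of channel scale, a convention recorded here
so either choice is reproducible.  Indices with a vanishing denominator are
reported as NaN rather than +/-inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label

Array = np.ndarray

VEGETATION_INDEX_NAMES = (
    "ExG", "ExGR", "NGRDI", "NBRDI", "RGRI", "GBRI", "CIVE", "VEG", "RGBVI", "MGRVI",
)

#: exponent of the Vegetative Index; "a" in G / (R^a * B^(1-a))
VEG_EXPONENT = 0.667


@dataclass
class PlantMask:
    mask: Array           # H x W bool
    pixel_count: int
    top_row: int          # -1 when empty
    bottom_row: int


@dataclass
class ShootFeatureVector:
    R: float
    G: float
    B: float
    H: float              # degrees in [0, 360)
    S: float
    V: float
    leaf_area_px: int
    height_px: int


@dataclass
class VegetationIndexSet:
    ExG: float
    ExGR: float
    NGRDI: float
    NBRDI: float
    RGRI: float
    GBRI: float
    CIVE: float
    VEG: float
    RGBVI: float
    MGRVI: float
    a: float = VEG_EXPONENT

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self) if f.name != "a"}


def calibrate_with_white_reference(image: Array,
                                   board_region: tuple[int, int, int, int],
                                   board_target: float | tuple[float, float, float] = 205.0,
                                   ) -> Array:
    """Normalize ambient light using the white reference board.

    Each channel is multiplied by ``board_target / mean(channel over the
    board region)`` and clipped to [0, 255].  Returns a float image.
    """
    r0, r1, c0, c1 = board_region
    if r1 <= r0 or c1 <= c0:
        raise ValueError("board_region is empty")
    img = np.asarray(image, dtype=float)
    board = img[r0:r1, c0:c1].reshape(-1, 3)
    means = board.mean(axis=0)
    if np.any(means <= 0):
        raise ValueError("board channel mean is zero; cannot calibrate")
    target = np.broadcast_to(np.asarray(board_target, dtype=float), (3,))
    return np.clip(img * (target / means)[None, None, :], 0.0, 255.0)


def segment_plant(image: Array, exg_threshold: float | None = None,
                  min_exg: float = 0.15) -> PlantMask:
    """Segment the plant silhouette by excess-green thresholding.

    Per-pixel ExG = 2g - r - b (channels on [0, 1]) is thresholded (Otsu by
    default, overridable) and the largest connected component retained.  If
    no pixel reaches ``min_exg`` the image is treated as plant-free and an
    empty mask returned.
    """
    img = np.asarray(image, dtype=float) / 255.0
    exg = 2.0 * img[..., 1] - img[..., 0] - img[..., 2]
    if exg.max() < min_exg:
        return PlantMask(np.zeros(exg.shape, dtype=bool), 0, -1, -1)
    thr = threshold_otsu(exg) if exg_threshold is None else exg_threshold
    raw = exg > thr
    if not raw.any():
        return PlantMask(raw, 0, -1, -1)
    lab = label(raw)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    mask = lab == largest
    rows = np.flatnonzero(mask.any(axis=1))
    return PlantMask(mask, int(mask.sum()), int(rows[0]), int(rows[-1]))


def extract_mean_color(image: Array, mask: Array) -> tuple[float, float, float]:
    """Mean (R, G, B) over masked pixels, scaled to [0, 1]."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("mask is empty; no pixels to average")
    px = np.asarray(image, dtype=float)[m]
    r, g, b = px.mean(axis=0) / 255.0
    return float(r), float(g), float(b)


def rgb_to_hsv(R: float, G: float, B: float) -> tuple[float, float, float]:
    """Hexcone RGB -> HSV; H in degrees [0, 360), S and V in [0, 1].

    V = max(R, G, B); S = (max - min)/max (0 for black); H by the sector
    formula on the dominant channel.
    """
    mx = max(R, G, B)
    mn = min(R, G, B)
    V = mx
    if mx <= 0.0:
        return 0.0, 0.0, 0.0
    S = (mx - mn) / mx
    d = mx - mn
    if d == 0.0:
        H = 0.0
    elif mx == R:
        H = 60.0 * (((G - B) / d) % 6.0)
    elif mx == G:
        H = 60.0 * ((B - R) / d + 2.0)
    else:
        H = 60.0 * ((R - G) / d + 4.0)
    return H % 360.0, S, V


def measure_morphology(mask: PlantMask) -> tuple[int, int]:
    """(leaf_area_px, height_px): silhouette pixel count and vertical extent."""
    if mask.pixel_count == 0:
        return 0, 0
    return mask.pixel_count, mask.bottom_row - mask.top_row + 1


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0.0 else math.nan


def compute_vegetation_indices(R: float, G: float, B: float,
                               exr_red_coeff: float = 1.4) -> VegetationIndexSet:
    """All ten vegetation indices on channel values in [0, 1].

    ExR = ``exr_red_coeff``*R - G (the widely used excess-red definition).
    Undefined ratios (zero denominators) are NaN.
    """
    exg = 2.0 * G - R - B
    exr = exr_red_coeff * R - G
    a = VEG_EXPONENT
    den_veg = (R ** a) * (B ** (1.0 - a))
    return VegetationIndexSet(
        ExG=exg,
        ExGR=exg - exr,
        NGRDI=_safe_div(G - R, G + R),
        NBRDI=_safe_div(G - B, G + B),
        RGRI=_safe_div(R, G),
        GBRI=_safe_div(B, G),
        CIVE=0.441 * R - 0.811 * G + 0.385 * B + 18.78745,
        VEG=_safe_div(G, den_veg),
        RGBVI=_safe_div(G * G - B * R, G * G + B * R),
        MGRVI=_safe_div(G * G - R * R, G * G + R * R),
    )


def vegetation_index_features(image: Array, mask: Array,
                              mode: str = "per_pixel") -> dict[str, float]:
    """The index battery over a segmented plant.

    ``mode="per_pixel"`` (default) evaluates every index per pixel and
    averages over the mask, ignoring pixels where an index is undefined;
    ``mode="mean_rgb"`` evaluates each index once on the masked mean color.
    The two routes agree exactly for the linear indices (ExG, ExGR, CIVE).
    """
    if mode == "mean_rgb":
        r, g, b = extract_mean_color(image, mask)
        return compute_vegetation_indices(r, g, b).as_dict()
    if mode != "per_pixel":
        raise ValueError(f"unknown mode {mode!r}")
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("mask is empty")
    px = np.asarray(image, dtype=float)[m] / 255.0
    r, g, b = px[:, 0], px[:, 1], px[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        exg = 2.0 * g - r - b
        exr = 1.4 * r - g
        a = VEG_EXPONENT
        out = {
            "ExG": exg,
            "ExGR": exg - exr,
            "NGRDI": (g - r) / (g + r),
            "NBRDI": (g - b) / (g + b),
            "RGRI": r / g,
            "GBRI": b / g,
            "CIVE": 0.441 * r - 0.811 * g + 0.385 * b + 18.78745,
            "VEG": g / ((r ** a) * (b ** (1.0 - a))),
            "RGBVI": (g * g - b * r) / (g * g + b * r),
            "MGRVI": (g * g - r * r) / (g * g + r * r),
        }
    return {k: float(np.nanmean(np.where(np.isfinite(v), v, np.nan)))
            for k, v in out.items()}


def shoot_feature_vector(image: Array, board_region: tuple[int, int, int, int],
                         board_target: float | tuple[float, float, float] = 205.0,
                         index_mode: str = "per_pixel",
                         ) -> tuple[ShootFeatureVector, dict[str, float]]:
    """Calibrate, segment and featurize one side-view shoot image."""
    cal = calibrate_with_white_reference(image, board_region, board_target)
    pm = segment_plant(cal)
    area, height = measure_morphology(pm)
    if pm.pixel_count == 0:
        nan = float("nan")
        return (ShootFeatureVector(nan, nan, nan, nan, nan, nan, 0, 0),
                {k: nan for k in VEGETATION_INDEX_NAMES})
    r, g, b = extract_mean_color(cal, pm.mask)
    h, s, v = rgb_to_hsv(r, g, b)
    fv = ShootFeatureVector(r, g, b, h, s, v, area, height)
    return fv, vegetation_index_features(cal, pm.mask, mode=index_mode)
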