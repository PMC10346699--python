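"""Synthetic root scenes, probe sampling plans, and diagrammatic renders.

Everything downstream of this module (detection, density profiles, group
statistics) is tested against scenes generated here, so the generator records
full ground truth: segment identities and classes, per-image bounding boxes,
specular-highlight masks, plant silhouettes and the white-board region.

Coordinate convention: lengths in mm; ``x, y`` horizontal with the origin on
the stem axis at the soil surface; ``z`` is depth below the surface, positive
downward.  The probe samples a cylinder of radius ``cylinder_radius`` and
depth ``cylinder_depth`` centred on the stem.

The thin-root field is an inhomogeneous Poisson process in depth.  Roots do
not stop at the sampling boundary in real soil, so thin segments are
generated in a cylinder padded by ``sense_radius`` radially and at the
bottom; without the padding, sensing spheres truncated at the boundary would
depress apparent densities in the outermost bins.  The soil surface (z = 0)
is a real boundary and is not padded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

Array = np.ndarray

CONTROL = "control"
INOCULATED = "inoculated"
THIN = "thin"
THICK = "thick"

# Base colors (RGB, 0-255). Thin roots are whitish, thick crown roots carry
# the yellow/brown family that the width+color classification rule expects.
# Root colors are capped below sensor saturation (only specular highlights
# saturate), so brightness-based segmentation can always separate them from
# the specular mask.
THIN_BASE_COLOR = (210.0, 202.0, 188.0)
THICK_BASE_COLOR = (190.0, 150.0, 84.0)
ROOT_COLOR_MAX = 240.0
#: plant-level brightness offsets are truncated so baseline root color never
#: approaches soil darkness (roots stay separable from background by design)
PLANT_OFFSET_CLIP = 28.0


def exponential_rate_profile(surface_rate: float, decay_mm: float) -> Callable[[Array], Array]:
    """Thin-root intensity (segments per cm^3) decaying exponentially with depth."""
    if surface_rate < 0:
        raise ValueError("surface_rate must be non-negative")
    if decay_mm <= 0:
        raise ValueError("decay_mm must be positive")
    return lambda z: surface_rate * np.exp(-np.asarray(z, dtype=float) / decay_mm)


def constant_rate_profile(rate: float) -> Callable[[Array], Array]:
    if rate < 0:
        raise ValueError("rate must be non-negative")
    return lambda z: np.full_like(np.asarray(z, dtype=float), float(rate))


@dataclass
class SceneConfig:
    """Geometry, cohort and effect parameters of the simulated study.

    The sampling geometry defaults reproduce the study design: a cylinder of
    100 mm diameter and depth probed through 130 tunnels of 35 viewpoints
    each (4550 images per plant), over a cohort of 32 plants split half and
    half into control and inoculated groups.

    The inoculation effect has two dials: ``shallow_damage_fraction`` thins
    the thin-root Poisson intensity above ``damage_depth`` (larvae feed on
    the shallow crown region and inhibit fine-root development there), and
    ``root_darkening`` scales root colors down (damaged roots are darker).
    """

    cylinder_radius: float = 50.0
    cylinder_depth: float = 100.0
    n_tunnels: int = 130
    viewpoints_per_tunnel: int = 35
    n_plants: int = 32
    inoculated_fraction: float = 0.5
    thin_surface_rate_per_cm3: float = 0.5
    thin_depth_decay_mm: float = 80.0
    thin_rate_profile: Callable[[Array], Array] | None = None
    thick_root_count: int = 12
    shallow_damage_fraction: float = 0.4
    damage_depth: float = 40.0
    root_darkening: float = 0.1
    sense_radius: float = 6.0
    plant_color_sigma: float = 24.0
    segment_color_sigma: float = 6.0
    max_tunnel_tilt_deg: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cylinder_radius", "cylinder_depth", "sense_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("inoculated_fraction", "shallow_damage_fraction", "root_darkening"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.damage_depth < 0 or self.damage_depth > self.cylinder_depth:
            raise ValueError("damage_depth must lie in [0, cylinder_depth]")
        if self.n_tunnels < 1 or self.viewpoints_per_tunnel < 1:
            raise ValueError("tunnel and viewpoint counts must be >= 1")
        if self.thin_surface_rate_per_cm3 < 0:
            raise ValueError("thin_surface_rate_per_cm3 must be non-negative")

    @property
    def images_per_plant(self) -> int:
        return self.n_tunnels * self.viewpoints_per_tunnel

    def rate_profile(self) -> Callable[[Array], Array]:
        if self.thin_rate_profile is not None:
            return self.thin_rate_profile
        return exponential_rate_profile(self.thin_surface_rate_per_cm3, self.thin_depth_decay_mm)


@dataclass
class RootSegment:
    """A piecewise-linear root element with thickness, color and true class."""

    segment_id: int
    start: Array
    end: Array
    thickness: float
    color: tuple[float, float, float]
    true_class: str

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def midpoint(self) -> Array:
        return 0.5 * (self.start + self.end)


@dataclass
class RootSystem:
    plant_id: int
    group: str
    segments: list[RootSegment]
    stem_axis: tuple[float, float] = (0.0, 0.0)  # (x, y) of the vertical stem line

    def __len__(self) -> int:
        return len(self.segments)

    def endpoints(self) -> tuple[Array, Array]:
        """Stacked (n, 3) start and end arrays for vectorized geometry."""
        if not self.segments:
            empty = np.zeros((0, 3))
            return empty, empty
        a = np.stack([s.start for s in self.segments])
        b = np.stack([s.end for s in self.segments])
        return a, b


@dataclass
class SamplingPlan:
    """Probe tunnels and the viewpoints strung along them."""

    tunnels: list[tuple[Array, Array]]  # (entry point on surface, unit direction)
    viewpoint_id: Array                 # (n,) int
    tunnel_id: Array                    # (n,) int
    coords: Array                       # (n, 3) mm

    @property
    def n_viewpoints(self) -> int:
        return len(self.viewpoint_id)


@dataclass
class RenderedRootImage:
    pixels: Array                      # H x W x 3 uint8
    viewpoint_id: int
    ground_truth: list[tuple[tuple[int, int, int, int], str]]
    specular_mask: Array               # H x W bool, highlight pixels
    root_mask: Array                   # H x W bool, visible root pixels (any segment)


@dataclass
class RenderedShootImage:
    pixels: Array                      # H x W x 3 uint8
    board_region: tuple[int, int, int, int]  # (row0, row1, col0, col1), half-open
    ambient_gain: tuple[float, float, float]
    plant_mask: Array                  # H x W bool ground-truth silhouette
    board_true_color: tuple[float, float, float]


# ---------------------------------------------------------------------------
# Root-system generation
# ---------------------------------------------------------------------------

def _thin_intensity_per_mm(config: SceneConfig, group: str, z_mm: Array) -> Array:
    """Expected thin segments per mm of depth over the padded generation disk."""
    pad = config.sense_radius
    gen_radius_cm = (config.cylinder_radius + pad) / 10.0
    area_cm2 = math.pi * gen_radius_cm**2
    rate = np.asarray(config.rate_profile()(z_mm), dtype=float)
    if np.any(rate < 0):
        raise ValueError("thin_rate_profile returned a negative rate")
    lam = rate * area_cm2 / 10.0  # per mm of depth
    if group == INOCULATED and config.shallow_damage_fraction > 0:
        lam = np.where(z_mm < config.damage_depth,
                       lam * (1.0 - config.shallow_damage_fraction), lam)
    return lam


def generate_root_system(config: SceneConfig, group: str, plant_seed: int,
                         plant_id: int = 0) -> RootSystem:
    """Draw one plant's root system.

    Thin segments follow an inhomogeneous Poisson process in depth with
    intensity ``thin_rate_profile``; for inoculated plants the intensity above
    ``damage_depth`` is thinned by ``1 - shallow_damage_fraction`` (Poisson
    thinning, so the expected shallow count ratio is exactly the retained
    fraction).  Thick crown roots emanate from near the surface close to the
    stem and grow downward-outward.  Inoculated root colors are scaled by
    ``1 - root_darkening``.  Identical (config, group, plant_seed) gives a
    bitwise-identical system.
    """
    if group not in (CONTROL, INOCULATED):
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(plant_seed)
    pad = config.sense_radius
    gen_radius = config.cylinder_radius + pad
    gen_depth = config.cylinder_depth + pad

    # Plant-level color offset: plants differ in baseline root color mostly
    # along a shared brightness axis (channels co-vary), with a small
    # independent per-channel residual.
    plant_offset = (np.clip(rng.normal(0.0, config.plant_color_sigma),
                            -PLANT_OFFSET_CLIP, PLANT_OFFSET_CLIP) * np.ones(3)
                    + rng.normal(0.0, 4.0, size=3))

    segments: list[RootSegment] = []
    darken = (1.0 - config.root_darkening) if group == INOCULATED else 1.0

    # --- thin roots: inhomogeneous Poisson over depth, uniform over the disk
    z_grid = np.linspace(0.0, gen_depth, 600)
    lam = _thin_intensity_per_mm(config, group, z_grid)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (lam[1:] + lam[:-1]) * np.diff(z_grid))])
    total = cum[-1]
    n_thin = rng.poisson(total) if total > 0 else 0
    if n_thin > 0:
        depths = np.interp(rng.uniform(0.0, total, n_thin), cum, z_grid)
        radii = gen_radius * np.sqrt(rng.uniform(size=n_thin))
        azim = rng.uniform(0.0, 2 * math.pi, n_thin)
        centers = np.column_stack([radii * np.cos(azim), radii * np.sin(azim), depths])
        dirs = rng.normal(size=(n_thin, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        lengths = rng.uniform(8.0, 20.0, n_thin)
        thick = rng.uniform(0.4, 1.2, n_thin)
        colors = (np.asarray(THIN_BASE_COLOR) + plant_offset
                  + rng.normal(0.0, config.segment_color_sigma, size=(n_thin, 3)))
        colors = np.clip(colors * darken, 20.0, ROOT_COLOR_MAX)
        for i in range(n_thin):
            half = 0.5 * lengths[i] * dirs[i]
            segments.append(RootSegment(
                segment_id=len(segments),
                start=centers[i] - half,
                end=centers[i] + half,
                thickness=float(thick[i]),
                color=tuple(colors[i]),
                true_class=THIN,
            ))

    # --- thick crown roots: from near-surface crown, downward and outward
    for _ in range(config.thick_root_count):
        azim0 = rng.uniform(0.0, 2 * math.pi)
        r0 = rng.uniform(2.0, 8.0)
        start = np.array([r0 * math.cos(azim0), r0 * math.sin(azim0),
                          rng.uniform(2.0, 10.0)])
        tilt = math.radians(rng.uniform(20.0, 50.0))
        azim = azim0 + rng.normal(0.0, 0.3)
        d = np.array([math.sin(tilt) * math.cos(azim),
                      math.sin(tilt) * math.sin(azim),
                      math.cos(tilt)])
        length = rng.uniform(50.0, 90.0)
        length = min(length, 0.95 * _exit_length(start, d, gen_radius, gen_depth))
        color = (np.asarray(THICK_BASE_COLOR) + plant_offset
                 + rng.normal(0.0, 8.0, size=3))
        color = np.clip(color * darken, 20.0, ROOT_COLOR_MAX)
        segments.append(RootSegment(
            segment_id=len(segments),
            start=start,
            end=start + length * d,
            thickness=float(rng.uniform(2.8, 4.5)),
            color=tuple(color),
            true_class=THICK,
        ))

    return RootSystem(plant_id=plant_id, group=group, segments=segments)


def _exit_length(p: Array, d: Array, radius: float, depth: float) -> float:
    """Distance along direction d from p to the cylinder boundary."""
    t_z = (depth - p[2]) / d[2] if d[2] > 0 else math.inf
    a = d[0] ** 2 + d[1] ** 2
    if a < 1e-12:
        t_r = math.inf
    else:
        b = 2.0 * (p[0] * d[0] + p[1] * d[1])
        c = p[0] ** 2 + p[1] ** 2 - radius**2
        disc = b * b - 4 * a * c
        t_r = (-b + math.sqrt(max(disc, 0.0))) / (2 * a)
    return max(min(t_z, t_r), 0.0)


# ---------------------------------------------------------------------------
# Sampling plan
# ---------------------------------------------------------------------------

def generate_sampling_plan(config: SceneConfig, seed: int) -> SamplingPlan:
    """Place probe tunnels and viewpoints inside the sampling cylinder.

    Tunnels enter from the surface at uniform azimuth with entry radius
    sampled as R*sqrt(u) (uniform areal coverage of the surface disk) and an
    insertion direction tilted up to ``max_tunnel_tilt_deg`` from vertical.
    Viewpoints are evenly spaced along the in-cylinder portion of each
    tunnel, strictly inside the cylinder.
    """
    rng = np.random.default_rng(seed)
    R, D = config.cylinder_radius, config.cylinder_depth
    V = config.viewpoints_per_tunnel
    min_len = min(0.2 * D, D / (V + 1))

    tunnels: list[tuple[Array, Array]] = []
    coords = np.empty((config.n_tunnels * V, 3))
    tunnel_id = np.repeat(np.arange(config.n_tunnels), V)
    for k in range(config.n_tunnels):
        for attempt in range(200):
            azim = rng.uniform(0.0, 2 * math.pi)
            r0 = R * math.sqrt(rng.uniform())
            entry = np.array([r0 * math.cos(azim), r0 * math.sin(azim), 0.0])
            tilt = math.radians(rng.uniform(0.0, config.max_tunnel_tilt_deg))
            psi = rng.uniform(0.0, 2 * math.pi)
            d = np.array([math.sin(tilt) * math.cos(psi),
                          math.sin(tilt) * math.sin(psi),
                          math.cos(tilt)])
            t_exit = _exit_length(entry, d, R, D)
            if t_exit >= min_len:
                break
        else:
            raise RuntimeError(
                "could not place a tunnel with the requested viewpoints inside "
                "the cylinder; check the geometry configuration")
        t = t_exit * (np.arange(1, V + 1) / (V + 1))
        coords[k * V:(k + 1) * V] = entry[None, :] + t[:, None] * d[None, :]
        tunnels.append((entry, d))

    return SamplingPlan(
        tunnels=tunnels,
        viewpoint_id=np.arange(len(coords)),
        tunnel_id=tunnel_id,
        coords=coords,
    )


# ---------------------------------------------------------------------------
# Sensing
# ---------------------------------------------------------------------------

def point_segment_distances(points: Array, a: Array, b: Array) -> Array:
    """Distances from each of (n, 3) points to the 3D segment a-b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-18:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    closest = a[None, :] + t[:, None] * ab[None, :]
    return np.linalg.norm(points - closest, axis=1)


def sense_roots(plan: SamplingPlan, system: RootSystem,
                sense_radius: float) -> list[Array]:
    """Per-viewpoint indices of segments within ``sense_radius``.

    A segment is visible from a viewpoint iff the minimum point-to-segment
    distance does not exceed the sensing radius.  Returns one integer index
    array (into ``system.segments``) per viewpoint.
    """
    if sense_radius <= 0:
        raise ValueError("sense_radius must be positive")
    n_vp = plan.n_viewpoints
    if not system.segments:
        return [np.empty(0, dtype=int) for _ in range(n_vp)]
    a, b = system.endpoints()
    ab = b - a                                        # (S, 3)
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom < 1e-18, 1.0, denom)
    pa = plan.coords[:, None, :] - a[None, :, :]      # (N, S, 3)
    t = np.clip(np.einsum("nsj,sj->ns", pa, ab) / denom[None, :], 0.0, 1.0)
    diff = pa - t[:, :, None] * ab[None, :, :]
    visible = np.einsum("nsj,nsj->ns", diff, diff) <= sense_radius**2
    return [np.flatnonzero(visible[i]) for i in range(n_vp)]


# ---------------------------------------------------------------------------
# Root-image rendering
# ---------------------------------------------------------------------------

@dataclass
class RenderConfig:
    """Diagrammatic probe-image renderer settings.

    ``px_per_mm`` is the image scale at the reference distance
    ``ref_distance_mm``; the on-image width of a root scales with
    ``ref_distance / distance`` clipped to ``distance_factor_bounds``.
    Soil is a dark brown noisy background with small particle speckles; roots
    are drawn as capsules in their segment color with patchy additive
    specular highlights.
    """

    width: int = 260
    height: int = 190
    px_per_mm: float = 28.0
    ref_distance_mm: float = 6.0
    distance_factor_bounds: tuple[float, float] = (0.85, 1.3)
    soil_rgb: tuple[float, float, float] = (85.0, 66.0, 50.0)
    soil_noise_sigma: float = 8.0
    particles_mean: float = 25.0
    pixel_noise_sigma: float = 5.0
    truth_min_px: int = 250
    max_length_frac: float = 0.45    # drawn section length cap, of min(H, W)
    max_width_frac: float = 0.6      # drawn width cap, of min(H, W)
    placement_tries: int = 20        # seeded retries to keep sections apart
    separation_px: float = 8.0       # clearance kept between drawn sections
    max_sections_per_image: int = 4  # field-of-view cap: nearest sections only
    fov_area_frac: float = 0.5       # cap on total drawn root area per frame


def on_image_width_px(thickness_mm: float, distance_mm: float,
                      rc: RenderConfig) -> float:
    """Projected root width in pixels for a root at the given distance."""
    lo, hi = rc.distance_factor_bounds
    factor = float(np.clip(rc.ref_distance_mm / max(distance_mm, 1e-6), lo, hi))
    return thickness_mm * rc.px_per_mm * factor


# stratified anchor positions (fractions of width/height) cycling over the
# draw order, so several root sections stay visually separated in one frame
_ANCHORS = [(0.5, 0.5), (0.25, 0.25), (0.75, 0.75), (0.25, 0.75), (0.75, 0.25)]


def render_root_image(viewpoint: Array, visible_segments: Sequence[RootSegment],
                      render_config: RenderConfig | None = None,
                      seed: int = 0, viewpoint_id: int = 0) -> RenderedRootImage:
    """Render one probe image with ground-truth boxes.

    Segments are drawn far-to-near so closer roots occlude farther ones; a
    ground-truth box is recorded for every segment whose visible (topmost)
    pixel count reaches ``truth_min_px``.
    """
    rc = render_config or RenderConfig()
    rng = np.random.default_rng(seed)
    H, W = rc.height, rc.width

    img = np.asarray(rc.soil_rgb, dtype=float)[None, None, :] + rng.normal(
        0.0, rc.soil_noise_sigma, size=(H, W, 3))
    # soil particles: small blobs, some bright (stones), all below detector min_area
    yy, xx = np.mgrid[0:H, 0:W]
    for _ in range(rng.poisson(rc.particles_mean)):
        cy, cx = rng.uniform(0, H), rng.uniform(0, W)
        rad = rng.uniform(1.0, 3.0)
        blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2
        if rng.uniform() < 0.2:
            color = rng.uniform(170.0, 210.0) * np.ones(3)
        else:
            color = np.asarray(rc.soil_rgb) * rng.uniform(0.6, 1.6)
        img[blob] = color + rng.normal(0.0, 3.0, size=3)

    owner = np.full((H, W), -1, dtype=int)
    specular = np.zeros((H, W), dtype=bool)

    segs = list(visible_segments)
    dists = np.array([
        point_segment_distances(np.asarray(viewpoint, dtype=float)[None, :],
                                s.start, s.end)[0]
        for s in segs]) if segs else np.empty(0)
    # field-of-view cap: a close-up frame only shows a few distinct
    # sections, and a frame dominated by a wide root shows little else.
    # Keep the nearest sections while their projected area fits the budget.
    lo, hi = rc.distance_factor_bounds
    min_hw = min(H, W)
    budget = rc.fov_area_frac * H * W
    used = 0.0
    keep: set[int] = set()
    for idx in np.argsort(dists):
        if len(keep) >= rc.max_sections_per_image:
            break
        seg = segs[idx]
        factor = float(np.clip(rc.ref_distance_mm / max(dists[idx], 1e-6), lo, hi))
        w = min(seg.thickness * rc.px_per_mm * factor, rc.max_width_frac * min_hw)
        l = min(seg.length * rc.px_per_mm * factor, rc.max_length_frac * min_hw)
        area = l * w + math.pi * (0.5 * w) ** 2
        if keep and used + area > budget:
            continue
        keep.add(int(idx))
        used += area
    order = [idx for idx in np.argsort(-dists) if int(idx) in keep]  # far first

    for rank, idx in enumerate(order):
        seg = segs[idx]
        dist = dists[idx]
        w_px = min(on_image_width_px(seg.thickness, dist, rc),
                   rc.max_width_frac * min(H, W))
        lo, hi = rc.distance_factor_bounds
        factor = float(np.clip(rc.ref_distance_mm / max(dist, 1e-6), lo, hi))
        l_px = min(seg.length * rc.px_per_mm * factor,
                   rc.max_length_frac * min(H, W))
        # seeded retry placement: keep this section clear of already-drawn
        # roots where the frame allows, so sections stay distinguishable
        drawn = owner >= 0
        best = None
        best_overlap = math.inf
        for attempt in range(max(1, rc.placement_tries)):
            ax, ay = _ANCHORS[(rank + attempt) % len(_ANCHORS)]
            cx = W * ax + rng.normal(0.0, 0.05 * W)
            cy = H * ay + rng.normal(0.0, 0.05 * H)
            phi = rng.uniform(0.0, math.pi)
            ux, uy = math.cos(phi), math.sin(phi)
            p0 = np.array([cx - 0.5 * l_px * ux, cy - 0.5 * l_px * uy])
            p1 = np.array([cx + 0.5 * l_px * ux, cy + 0.5 * l_px * uy])
            dmap = _dist_to_segment_2d(xx, yy, p0, p1)
            capsule = dmap <= 0.5 * w_px
            area = int(capsule.sum())
            if area == 0:
                continue
            # clearance zone: capsule dilated by the separation margin must
            # avoid drawn roots, else closing in the detector merges sections
            zone = dmap <= 0.5 * w_px + rc.separation_px
            overlap = int((zone & drawn).sum()) / area
            if overlap < best_overlap:
                best = (capsule, cx, cy, ux, uy)
                best_overlap = overlap
            if overlap == 0.0:
                break
        if best is None:
            continue
        capsule, cx, cy, ux, uy = best
        img[capsule] = (np.asarray(seg.color)
                        + rng.normal(0.0, rc.pixel_noise_sigma,
                                     size=(int(capsule.sum()), 3)))
        owner[capsule] = idx
        specular[capsule] = False  # occluded highlights disappear
        # patchy specular highlights inside the capsule
        for _ in range(rng.integers(1, 4)):
            t = rng.uniform(-0.3, 0.3)
            off = rng.uniform(-0.25, 0.25) * w_px
            hx = cx + t * l_px * ux - off * uy
            hy = cy + t * l_px * uy + off * ux
            ha = max(2.0, 0.12 * min(l_px, 4 * w_px))
            hb = max(1.0, 0.12 * w_px)
            e = (((xx - hx) * ux + (yy - hy) * uy) / ha) ** 2 + \
                (((xx - hx) * -uy + (yy - hy) * ux) / hb) ** 2 <= 1.0
            hl = e & capsule
            img[hl] = rng.normal(252.0, 1.5, size=(int(hl.sum()), 3))
            specular |= hl

    ground_truth = []
    for idx, seg in enumerate(segs):
        vis = owner == idx
        if int(vis.sum()) < rc.truth_min_px:
            continue
        rows = np.flatnonzero(vis.any(axis=1))
        cols = np.flatnonzero(vis.any(axis=0))
        box = (int(cols[0]), int(rows[0]), int(cols[-1]) + 1, int(rows[-1]) + 1)
        ground_truth.append((box, seg.true_class))

    return RenderedRootImage(
        pixels=np.clip(img, 0, 255).astype(np.uint8),
        viewpoint_id=viewpoint_id,
        ground_truth=ground_truth,
        specular_mask=specular,
        root_mask=owner >= 0,
    )


def _dist_to_segment_2d(xx: Array, yy: Array, p0: Array, p1: Array) -> Array:
    d = p1 - p0
    denom = float(d @ d)
    px = xx - p0[0]
    py = yy - p0[1]
    if denom < 1e-12:
        return np.hypot(px, py)
    t = np.clip((px * d[0] + py * d[1]) / denom, 0.0, 1.0)
    return np.hypot(px - t * d[0], py - t * d[1])


# ---------------------------------------------------------------------------
# Shoot-image rendering
# ---------------------------------------------------------------------------

@dataclass
class ShootParams:
    """Parameters of one plant's side-view silhouette."""

    height_mm: float = 600.0
    green_rgb: tuple[float, float, float] = (62.0, 142.0, 58.0)
    n_leaves: int = 7
    leaf_len_mm: float = 150.0
    leaf_half_width_px: float = 4.0
    px_per_mm: float = 0.3


#: true reflectance color of the white reference board (kept below 255 so
#: channel gains above 1 do not clip it before calibration can undo them)
BOARD_TRUE_COLOR = (205.0, 205.0, 205.0)

_SHOOT_H, _SHOOT_W = 260, 200
_STEM_COL = 60
_BOARD = (15, 75, 130, 190)  # rows/cols, half-open


def sample_shoot_params(rng: np.random.Generator) -> ShootParams:
    """Draw shoot parameters from the cohort distribution.

    Both treatment groups draw from this same distribution by default: the
    study design posits no visible above-ground symptom at the sampled stage.
    Leaf color varies between plants mainly along a shared brightness factor
    and a greenness tilt (plus small independent channel noise), the way
    healthy plants of one genotype vary; vegetation indices computed from
    these colors are therefore strongly correlated across plants.
    """
    brightness = rng.normal(1.0, 0.08)
    greenness = rng.normal(0.0, 4.0)
    base = np.asarray((62.0, 142.0, 58.0))
    rgb = (base + np.array([0.0, greenness, 0.0]) + rng.normal(0.0, 0.3, 3)) * brightness
    return ShootParams(
        height_mm=float(np.clip(rng.normal(600.0, 50.0), 420.0, 780.0)),
        green_rgb=tuple(np.clip(rgb, 10.0, 250.0)),
        n_leaves=int(rng.integers(5, 9)),
        leaf_len_mm=float(np.clip(rng.normal(150.0, 20.0), 90.0, 200.0)),
        leaf_half_width_px=float(rng.uniform(3.0, 5.5)),
    )


def render_shoot_image(plant_params: ShootParams,
                       ambient_gain: tuple[float, float, float] = (1.0, 1.0, 1.0),
                       seed: int = 0) -> RenderedShootImage:
    """Render a side-view shoot image with a white reference board.

    The scene (gray background, board at its true color, green plant
    silhouette) is drawn and then multiplied per channel by ``ambient_gain``,
    emulating ambient-light variation that white-reference calibration must
    undo.  The plant mask height in pixels equals
    ``round(height_mm * px_per_mm)`` by construction.
    """
    gain = np.asarray(ambient_gain, dtype=float)
    if np.any(gain <= 0) or np.any(gain > 2.0):
        raise ValueError("ambient_gain channel multipliers must lie in (0, 2]")
    rng = np.random.default_rng(seed)
    H, W = _SHOOT_H, _SHOOT_W
    img = np.asarray((128.0, 126.0, 122.0))[None, None, :] + rng.normal(
        0.0, 3.0, size=(H, W, 3))

    r0, r1, c0, c1 = _BOARD
    img[r0:r1, c0:c1] = np.asarray(BOARD_TRUE_COLOR) + rng.normal(
        0.0, 2.0, size=(r1 - r0, c1 - c0, 3))

    p = plant_params
    height_px = int(round(p.height_mm * p.px_per_mm))
    bottom = H - 10
    top = bottom - height_px + 1
    mask = np.zeros((H, W), dtype=bool)
    mask[top:bottom + 1, _STEM_COL - 1:_STEM_COL + 2] = True

    leaf_len_px = p.leaf_len_mm * p.px_per_mm
    for i in range(p.n_leaves):
        frac = (i + 1) / (p.n_leaves + 1)
        ay = bottom - frac * (height_px - 1)
        side = 1 if i % 2 == 0 else -1
        ang = math.radians(rng.uniform(20.0, 45.0))
        ux, uy = side * math.cos(ang), -math.sin(ang)
        cxl = _STEM_COL + 0.5 * leaf_len_px * ux
        cyl = ay + 0.5 * leaf_len_px * uy
        # evaluate the ellipse only on its bounding window
        r = 0.5 * leaf_len_px + p.leaf_half_width_px
        y0, y1 = max(0, int(cyl - r)), min(H, int(cyl + r) + 1)
        x0, x1 = max(0, int(cxl - r)), min(W, int(cxl + r) + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        e = (((xx - cxl) * ux + (yy - cyl) * uy) / (0.5 * leaf_len_px)) ** 2 + \
            (((xx - cxl) * -uy + (yy - cyl) * ux) / p.leaf_half_width_px) ** 2 <= 1.0
        mask[y0:y1, x0:x1] |= e
    # keep the silhouette inside [top, bottom] so height is exact, and away
    # from the board columns so board and plant stay disjoint
    mask[:top, :] = False
    mask[bottom + 1:, :] = False
    mask[:, c0 - 10:] = False

    img[mask] = np.asarray(p.green_rgb) + rng.normal(0.0, 4.0, size=(int(mask.sum()), 3))
    img = np.clip(img * gain[None, None, :], 0, 255)

    return RenderedShootImage(
        pixels=img.astype(np.uint8),
        board_region=_BOARD,
        ambient_gain=tuple(gain),
        plant_mask=mask,
        board_true_color=BOARD_TRUE_COLOR,
    )
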