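# Methods

This note documents the models behind `rhizoprobe`: what the synthetic
scenes emulate, the measurement and statistics pipeline, the parameters that
matter, and the choices made where the design was genuinely open.

## Coordinate system and sampling geometry

All lengths are in mm. `x, y` are horizontal with the origin on the stem
axis at the soil surface; `z` is depth, positive downward. The probe samples
a cylinder of radius 50 and depth 100 centred on the stem.

A sampling plan consists of straight insertion tunnels entering from the
surface: entry azimuth uniform, entry radius `R·sqrt(u)` (uniform areal
coverage of the surface disk), insertion direction tilted up to 35° from
vertical toward a uniform azimuth. Viewpoints are evenly spaced along the
in-cylinder portion of each tunnel, strictly inside the cylinder; a tunnel
whose in-cylinder path is too short is resampled. The full design (130
tunnels × 35 viewpoints = 4550 viewpoints per plant) is the default
`SceneConfig`; the pipeline's default experiment scale is 20 × 10 per plant,
which preserves every statistical property of the design while keeping a
32-plant cohort in the order of a second of compute. `ExperimentConfig.full_viewpoints()`
restores the full design. The tunnel insertion angles and viewpoint spacing
are free parameters of the plan generator; nothing downstream depends on
their exact values because densities are normalized per sampled volume.

## Root-system model

Root systems are piecewise-linear segment sets, not an architectural growth
model — sufficient to carry the spatial and color statistics the pipeline
measures.

**Thin roots** follow an inhomogeneous Poisson process: intensity
`thin_rate_profile(z)` in segments/cm³, by default
`0.5 · exp(−z / 80 mm)`. Segments are short (8–20 mm), isotropically
oriented, 0.4–1.2 mm thick, whitish. The field is generated in a cylinder
padded by the sensing radius (radially and at the bottom): soil and roots
continue beyond the sampled region, and without padding the truncation of
sensing spheres at the boundary would depress apparent densities in the
outer bins. The surface (z = 0) is air and is not padded; the resulting
slight top-bin undercount is shared by both treatment groups and cancels in
comparisons.

**Thick crown roots** (12 per plant) start near the surface close to the
stem (radius 2–8 mm, depth 2–10 mm) and grow downward-outward (tilt 20–50°),
2.8–4.5 mm thick, yellow/brown.

**Inoculation effect.** Two dials, both defaulting to values chosen once to
reproduce the magnitude and ordering of the group contrasts the measurement
design is known to produce (see Calibration):

- `shallow_damage_fraction` (0.4): the thin-root intensity above
  `damage_depth` (40 mm) is multiplied by 1 − 0.4 for inoculated plants.
  Poisson thinning makes the expected shallow-count ratio exactly 0.6.
- `root_darkening` (0.1): inoculated root colors are scaled by 0.9.

**Color model.** Segment colors are a class base color (whitish
(210, 202, 188); brown (190, 150, 84)) plus a plant-level offset plus
per-segment noise. The plant offset is a *shared brightness shift* across
channels (σ = 24, truncated at ±28) plus a small independent per-channel
residual (σ = 4). The shared structure matters: real root color varies
between plants mainly in brightness, so the per-plant R, G, B, V features
are strongly correlated and behave like one test, not four. The truncation
keeps baseline roots separable from soil by brightness, which is the
contract the rule-based detector is defined against. Colors are capped at
240 so that only rendered specular highlights saturate.

## Sensing model

A segment is visible from a viewpoint iff its minimum point-to-segment
distance is ≤ `sense_radius` (default 6 mm). Each sighting yields one
observation at the viewpoint's coordinate (the image-level 3D tagging of the
real system; no within-image offset). A segment seen from several viewpoints
counts once per viewpoint — the raw "number of roots detected" convention;
segment identities are recorded so a deduplicated variant can be computed
from the synthetic truth.

The per-viewpoint sensed volume used for normalization is the sphere
`(4/3)π·sense_radius³` ≈ 0.905 cm³. Overlap between nearby viewpoints'
sensing regions is ignored, as is the dilation of the sensed region by
segment extent; both biases are multiplicative, identical across groups and
across bins of equal viewpoint density, so densities are comparable even
though their absolute scale is nominal. The defining property — uniform
roots give a flat radius profile while raw counts grow outward — is enforced
by test.

## Rendering

Rendering is diagrammatic, not photorealistic; the detector contract is
defined against this renderer. Probe images (260 × 190 px): dark-brown noisy
soil (base (85, 66, 50), σ = 8), Poisson-many small particle blobs (radius
1–3 px, some bright), roots as capsules whose on-image width is
`thickness · px_per_mm · clip(ref_distance/distance, 0.85, 1.3)` with
`px_per_mm = 28` at the 6 mm reference distance, drawn far-to-near so near
roots occlude far ones, with patchy near-saturated specular highlights.
Multiple visible sections are placed at stratified anchors with a seeded
retry that keeps an 8 px clearance between sections where the frame allows —
the renderer's way of keeping co-visible sections distinguishable. The
frame models a close-up camera's limited field of view: at most four
sections are drawn, nearest first, and only while their projected area fits
half the frame (a frame dominated by a wide crown root shows little else).
A ground-truth box is recorded for every drawn section with ≥ 250 visible
(topmost) pixels; slivers below that would not be labeled by a human
annotator either.

Shoot images (260 × 200 px): gray background, a white reference board
rendered at its true color (205, 205, 205) — kept below saturation so
channel gains above 1 remain invertible — and a green plant silhouette
(stem + elliptical leaves) whose mask height in pixels is exactly
`round(height_mm · 0.3 px/mm)`. The whole frame is multiplied per channel by
an ambient gain (sampled U(0.75, 1.2) per channel in the pipeline), which is
what white-reference calibration must undo. Both treatment groups draw shoot
parameters from the same distribution: the design posits no visible
above-ground symptom at the sampled stage. Leaf color varies between plants
along a brightness factor (σ = 8%) and a greenness tilt (σ = 4 on G), with
σ = 1 independent channel noise — so vegetation indices are strongly
correlated between plants, as they are in real canopy color data.

## Measurement pipeline

**Shoot branch.** Calibration multiplies each channel by
`board_target / mean(channel over board)` and clips to [0, 255].
Segmentation thresholds per-pixel excess green (2g − r − b on [0, 1]
channels; Otsu-selected threshold, overridable) and keeps the largest
connected component; an image whose ExG never reaches 0.15 is treated as
plant-free. Features: mean R, G, B over the mask (scaled to [0, 1]), HSV of
the mean color (hexcone conversion, H in degrees), leaf area = mask pixel
count, height = bottom row − top row + 1. The ten vegetation indices are
computed per pixel and averaged over the mask by default (a mean-RGB variant
is available); the two routes coincide for the linear indices. Indices with
a vanishing denominator are NaN, never ±inf. ExR, needed for ExGR, is not
defined by the index table itself; the standard `ExR = 1.4R − G` is used and
configurable. The CIVE intercept 18.78745 is kept as printed even though
channels are on [0, 1]; the convention is recorded so either scale choice is
reproducible.

**Root branch.** Root-pixel segmentation keeps pixels whose HSV value lies
in [0.48, 0.96] — soil sits far below, specular highlights above — then
applies a radius-2 morphological closing (re-excluding specular interiors)
and drops components under 150 px (soil particles, fragments). Width is the
inscribed-disk diameter: twice the maximum of the Euclidean distance
transform (image border counts as background). The class rule is a pure
conjunction: *thick* iff width > 60 px (strict, on root width rather than
box width, which would inflate for diagonal roots) and mean hue in [15°,
55°] and saturation ≥ 0.2; otherwise *thin*. Per-component color features
are means over the segmented pixels only; HSV is taken of the mean color.
Detection boxes are the tight component bounding boxes; the score is
component solidity.

**Density profiles.** Depth is divided into five 20 mm regions, radius into
five 10 mm annuli (half-open bins, last bin closed). Per bin: observation
count, viewpoint count, sampled volume = viewpoints × v_sense, density =
count / volume (NaN where a bin holds no viewpoints). Group summaries are
bin-wise means ± SD over plants.

**Statistics.** Welch's unequal-variance t-test with Welch–Satterthwaite
degrees of freedom is the default (the pooled test is behind a flag); when
both samples are constant and equal the result is reported as t = 0, p = 1.
NaN feature values (a plant with no thick detections, say) are dropped per
sample. PLS-DA codes the classes {0, 1}, draws seeded 70:30 splits
(training size rounded half-up, so 135 items give 95/40), standardizes on
the training set, fits a PLS regression with 2 components by default
(configurable; the number is not dictated by the design), classifies at
response ≥ 0.5 with ties to class 1, and averages accuracies over 1000
iterations by default. Single-class training draws are resampled and
logged. No multiple-testing correction is applied — the screens report raw
p-values, with −log₁₀ p against the −log₁₀ 0.05 reference in the comparison
report; a Benjamini–Hochberg option exists but is off by default. Zero
p-values are clipped to the smallest positive float.

**Pipeline.** `run_cohort` runs both branches for a 32-plant cohort. Its
`mode="full"` path renders and detects every probe image; `mode="direct"`
takes observations from the sensed ground-truth segments with
observation-level color jitter (σ = 4 RGB units), bypassing imaging. Direct
mode exists so that repeated-cohort experiments (type-I calibration over
hundreds of cohorts, effect-recovery screens) run in minutes; the imaging
path is validated separately by round-trip tests and rendered-batch
detector evaluation, and a full-vs-direct consistency test checks that the
two modes agree on thin-root counts within detector accuracy. The master
seed fans out to per-plant, per-stage seeds through a SHA-256 hash of
`seed/stage/plant` labels; reruns are byte-identical.

## Calibration of the study conditions

The measurement design's real-data outcome has a characteristic shape: the
thin-root count separates groups at p ~ 10⁻⁶, thin-root mean depth at
~10⁻⁴–10⁻³, thin-root R/G/B/V color at ~0.02 (H and S not at all — the
darkening is multiplicative, and hue and saturation are invariant to it),
nothing on the thick roots or the shoot. The generator's free parameters
were set once so the simulated cohorts land in that regime: thin surface
rate 0.5/cm³ (sets the per-plant count statistics), plant color sigma 24
with the shared-brightness structure (sets the color-test strength and the
channel correlation). Under those settings, across repeated cohorts the
smallest p-value belongs to a thin-root structure feature in ~95% of
cohorts, all ten vegetation indices stay non-significant in ~95%, and
PLS-DA test accuracy averages ~0.46–0.50.

Per-plant thin counts are pure Poisson given the plant's group — there is no
extra between-plant rate heterogeneity. Real plants would be overdispersed,
which would weaken the count t-statistic; the simulated effect sizes should
be read as of the design, not as field predictions.

## Validation experiment sizes

The validation suite (`rhizoprobe.validation`, driven by both the test
suite and `scripts/acceptance.py`) uses: 200 plants for the flat-density
check (3 Monte Carlo SE band); 500 null cohorts at 10 × 5 viewpoints for
type-I calibration (3.5σ binomial band per feature); 50 cohorts at the
default scale with MCCV at 200 iterations for effect recovery; 200 rendered
images for detector precision/recall (≥ 0.9 at IoU 0.5). These sizes are
the package's chosen balance of Monte Carlo error against run time on a
single CPU.

## Known limitations

- The renderer is diagrammatic; detector performance numbers characterize
  the renderer-detector pair, not transfer to real soil imagery.
- The rule-based detector cannot split directly overlapping root sections;
  the renderer's separation-aware placement keeps such frames rare rather
  than impossible.
- Sensed-volume normalization ignores overlap between viewpoints' sensing
  spheres; absolute densities are nominal, comparisons are unbiased.
- The root model has no topology, growth dynamics, or larval movement; the
  damage effect is a static intensity thinning plus darkening.
- One physical segment sighted from several viewpoints is counted per
  sighting; the dedup-by-identity variant is available on synthetic truth
  only.
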