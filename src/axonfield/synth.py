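"""Synthetic images and cohorts with exact ground truth.

No public DiI image set exists for the chiasm at this stage, so every
pipeline property is exercised on phantoms: bright curvilinear structures
with Gaussian cross-section (about the calibre of an embryonic axon bundle)
on a noisy background.  Three generators cover the needs of the test
pyramid:

* ``make_stripe`` — a straight ridge at a known angle;
* ``make_arc`` — a circular arc with analytic curvature 1/r;
* ``make_phantom_chiasm`` — a full specimen: eye landmarks plus a family of
  smooth trajectories that leave the injected (left) eye, converge on the
  midline and cross it at a controllable anteroposterior position.  An
  ``anterior_shift`` translates every trajectory toward the anterior, the
  signature perturbation used for effect-recovery experiments.

Default geometry is a scaled-down head: 320 x 320 px at 1.25 um/px with a
320 um inter-eye distance, which keeps whole-cohort simulations cheap while
preserving the ratio between filter scale (1.8 um), smoothing scale (30 um)
and region size.  Every generator is fully determined by its seed, and the
ground-truth record carries each trajectory's polyline, per-point travel
direction and analytic curvature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError
from .image import RasterImage
from .registration import EmbryoLandmarks

__all__ = [
    "PhantomSpec",
    "StripeTruth",
    "ArcTruth",
    "ChiasmTruth",
    "make_stripe",
    "make_arc",
    "make_phantom_chiasm",
    "make_cohort",
]


@dataclass
class StripeTruth:
    """Ground truth of a straight ridge: centreline points and orientation."""

    centreline_xy: np.ndarray  # (N, 2) pixel coordinates
    angle_rad: float
    profile_sigma_px: float


@dataclass
class ArcTruth:
    """Ground truth of a circular-arc ridge."""

    centreline_xy: np.ndarray
    direction_rad: np.ndarray  # travel direction per centreline point
    kappa_per_um: float  # signed; positive for counter-clockwise travel
    radius_um: float
    center_xy: tuple[float, float]
    injection_point: tuple[float, float]  # a point "behind" the arc start


@dataclass
class ChiasmTruth:
    """Ground truth of a phantom specimen.

    ``points_xy`` etc. concatenate all trajectories; ``trajectory_id`` maps
    each sample back to its curve.  Angles are image-frame radians; kappa is
    in rad/um, signed with the +pi/2-normal convention of the pipeline.
    """

    points_xy: np.ndarray
    direction_rad: np.ndarray
    kappa_per_um: np.ndarray
    trajectory_id: np.ndarray
    crossing_p: np.ndarray  # per-trajectory normalized crossing position
    saturated_mask: np.ndarray | None = None


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic specimen / cohort.

    Trajectories are parabolas in the normalized eye frame: posterior
    coordinate p dips from ``p_edge`` at the lateral edges to ``p_cross`` at
    the midline (m = 0.5), emulating axons that converge on the chiasm,
    cross, and fan out again.  ``anterior_shift`` (normalized p units)
    translates whole trajectories anteriorly, reproducing the mutant
    signature of an anteriorly displaced crossing.
    """

    size: tuple[int, int] = (448, 448)  # (rows, cols)
    pixel_size_um: float = 1.25
    left_eye: tuple[float, float] = (24.0, 56.0)
    right_eye: tuple[float, float] = (424.0, 56.0)
    injected_eye: str = "left"
    n_trajectories: int = 120
    p_front_cross: float = 0.125
    p_front_edge: float = 0.19
    band_tail_scale: float = 0.02
    band_depth_max: float = 0.08
    trajectory_jitter_sd: float = 0.002
    straggler_jitter_frac: float = 0.15
    band_jitter_sd: float = 0.002
    anterior_shift: float = 0.0
    profile_sigma_um: float = 1.8
    amplitude: float = 60.0
    background: float = 12.0
    noise_sigma: float = 4.0
    saturation_level: float | None = None
    landmark_jitter_px: float = 0.8
    seed: int = 0


def _add_noise(
    clean: np.ndarray, background: float, noise_sigma: float, rng: np.random.Generator
) -> np.ndarray:
    img = clean + background
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=clean.shape)
    return np.clip(img, 0.0, None)


def make_stripe(
    angle_rad: float,
    profile_sigma_um: float = 1.8,
    amplitude: float = 60.0,
    background: float = 8.0,
    noise_sigma: float = 0.0,
    size: tuple[int, int] = (128, 128),
    pixel_size_um: float = 1.0,
    seed: int = 0,
) -> tuple[RasterImage, StripeTruth]:
    """Straight ridge with Gaussian cross-section through the image centre."""
    rng = np.random.default_rng(seed)
    h, w = size
    sigma_px = profile_sigma_um / pixel_size_um
    yy, xx = np.indices((h, w), dtype=float)
    # integer centre: a half-integer centreline straddles two pixel rows
    # whose responses tie exactly, which strict NMS would suppress
    cy, cx = float(h // 2), float(w // 2)
    # signed distance from the centre line at angle_rad
    d = -(xx - cx) * math.sin(angle_rad) + (yy - cy) * math.cos(angle_rad)
    clean = amplitude * np.exp(-(d**2) / (2.0 * sigma_px**2))
    img = _add_noise(clean, background, noise_sigma, rng)
    # centreline samples inside the frame
    half_diag = math.hypot(h, w) / 2.0
    t = np.arange(-half_diag, half_diag, 0.5)
    pts = np.column_stack(
        [cx + t * math.cos(angle_rad), cy + t * math.sin(angle_rad)]
    )
    keep = (
        (pts[:, 0] >= 0) & (pts[:, 0] <= w - 1) & (pts[:, 1] >= 0) & (pts[:, 1] <= h - 1)
    )
    truth = StripeTruth(pts[keep], float(np.mod(angle_rad, np.pi)), sigma_px)
    return RasterImage(img, pixel_size_um), truth


def make_arc(
    radius_um: float,
    span_deg: float = 100.0,
    profile_sigma_um: float = 1.8,
    amplitude: float = 60.0,
    background: float = 8.0,
    noise_sigma: float = 0.0,
    pixel_size_um: float = 1.0,
    margin_px: int = 24,
    counter_clockwise: bool = True,
    seed: int = 0,
) -> tuple[RasterImage, ArcTruth]:
    """Circular-arc ridge with analytic curvature 1/radius.

    The arc is centred in a canvas just large enough to hold it.  The
    suggested ``injection_point`` lies behind the arc start along the
    initial tangent, so direction disambiguation recovers the travel sense.
    """
    if not (radius_um > 0):
        raise InvalidParameterError(f"radius_um must be > 0, got {radius_um}")
    r_px = radius_um / pixel_size_um
    sigma_px = profile_sigma_um / pixel_size_um
    rng = np.random.default_rng(seed)
    half_span = math.radians(span_deg) / 2.0
    # arc occupies polar angles around -pi/2 (apex at top of the circle);
    # canvas is sized from the arc's bounding box
    probe = -math.pi / 2.0 + np.linspace(-half_span, half_span, 721)
    ext_x = float(np.max(np.abs(r_px * np.cos(probe))))
    y_lo = float(np.min(r_px * np.sin(probe)))
    y_hi = float(np.max(r_px * np.sin(probe)))
    w = int(math.ceil(2 * ext_x)) + 2 * margin_px
    h = int(math.ceil(y_hi - y_lo)) + 2 * margin_px
    cx = float(w // 2)
    cy = float(round(margin_px - y_lo))  # integer centre avoids NMS ties
    yy, xx = np.indices((h, w), dtype=float)
    rho = np.hypot(xx - cx, yy - cy)
    phi = np.arctan2(yy - cy, xx - cx)
    delta = np.mod(phi - (-math.pi / 2.0) + math.pi, 2.0 * math.pi) - math.pi
    on_arc = np.abs(delta) <= half_span
    clean = amplitude * np.exp(-((rho - r_px) ** 2) / (2.0 * sigma_px**2)) * on_arc
    img = _add_noise(clean, background, noise_sigma, rng)

    step = 0.5 / r_px
    sense = 1.0 if counter_clockwise else -1.0
    angles = -math.pi / 2.0 + sense * np.arange(-half_span, half_span, step)
    pts = np.column_stack(
        [cx + r_px * np.cos(angles), cy + r_px * np.sin(angles)]
    )
    direction = np.mod(angles + sense * math.pi / 2.0, 2.0 * math.pi)
    # curl sign convention: direction angle increases along travel for
    # clockwise-in-screen (counter_clockwise=True here means increasing phi)
    kappa = sense / radius_um
    start = pts[0]
    tangent = direction[0]
    inj = (
        start[0] - 0.75 * r_px * math.cos(tangent),
        start[1] - 0.75 * r_px * math.sin(tangent),
    )
    truth = ArcTruth(
        centreline_xy=pts,
        direction_rad=direction,
        kappa_per_um=kappa,
        radius_um=radius_um,
        center_xy=(cx, cy),
        injection_point=inj,
    )
    return RasterImage(img, pixel_size_um), truth


def _render_polylines(
    polylines: list[np.ndarray],
    shape: tuple[int, int],
    sigma_px: float,
    amplitude: float,
    step_px: float = 0.3,
) -> np.ndarray:
    """Rasterize polylines as ridges of Gaussian cross-section.

    Unit line mass is splatted bilinearly along each polyline and blurred;
    the blur of a unit-density line has peak 1/(sqrt(2 pi) sigma), so the
    result is rescaled to make an isolated ridge peak at ``amplitude``.
    """
    h, w = shape
    canvas = np.zeros((h, w))
    for pts in polylines:
        seg = np.diff(pts, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        arclen = np.concatenate([[0.0], np.cumsum(seglen)])
        total = arclen[-1]
        if total <= 0:
            continue
        s = np.arange(0.0, total, step_px)
        x = np.interp(s, arclen, pts[:, 0])
        y = np.interp(s, arclen, pts[:, 1])
        inside = (x >= 0) & (x <= w - 1.001) & (y >= 0) & (y <= h - 1.001)
        x, y = x[inside], y[inside]
        x0 = np.floor(x).astype(int)
        y0 = np.floor(y).astype(int)
        fx = x - x0
        fy = y - y0
        np.add.at(canvas, (y0, x0), step_px * (1 - fx) * (1 - fy))
        np.add.at(canvas, (y0, x0 + 1), step_px * fx * (1 - fy))
        np.add.at(canvas, (y0 + 1, x0), step_px * (1 - fx) * fy)
        np.add.at(canvas, (y0 + 1, x0 + 1), step_px * fx * fy)
    blurred = ndimage.gaussian_filter(canvas, sigma_px)
    return blurred * amplitude * math.sqrt(2.0 * math.pi) * sigma_px


def make_phantom_chiasm(
    spec: PhantomSpec,
) -> tuple[RasterImage, EmbryoLandmarks, ChiasmTruth]:
    """Render one synthetic specimen from its spec.

    Trajectory i is the parabola p(m) through (0.08, p_edge_i),
    (0.5, p_cross_i), (0.92, p_edge2_i) in the normalized eye frame,
    mapped to pixels via the specimen's own eye positions, so registration
    of the rendered image recovers a common geometry.  The recorded
    landmarks carry a small annotation jitter, as a human operator's would.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    lx, ly = spec.left_eye
    rx, ry = spec.right_eye
    origin = complex(lx, ly)
    baseline = complex(rx, ry) - origin
    eye_dist_px = abs(baseline)
    eye_dist_um = eye_dist_px * spec.pixel_size_um

    m0, m1 = 0.08, 0.92
    m = np.linspace(m0, m1, 400)
    polylines: list[np.ndarray] = []
    all_pts, all_dir, all_kappa, all_tid = [], [], [], []
    crossing = np.empty(spec.n_trajectories)
    # Topographically ordered bundle: trajectories keep their neighbour
    # order (as retinotopic axons do) at stereotyped quantile positions of
    # an exponential depth profile -- the tract packs densely against its
    # sharp anterior boundary and tapers off posteriorly, the way axons
    # crowd the edge of the repellent territory.  Small per-axon and
    # per-specimen jitters add individual variability.
    u = (np.arange(spec.n_trajectories) + 0.5) / spec.n_trajectories
    tau, dmax = spec.band_tail_scale, spec.band_depth_max
    depth = -tau * np.log1p(-u * (1.0 - math.exp(-dmax / tau)))
    band_offset = rng.normal(0.0, spec.band_jitter_sd)
    for i in range(spec.n_trajectories):
        # deep (posterior) axons straggle more than the tightly packed front
        jit = spec.trajectory_jitter_sd + spec.straggler_jitter_frac * depth[i]
        common = depth[i] + band_offset - spec.anterior_shift
        p_a = spec.p_front_edge + rng.normal(0, jit) + common
        p_b = spec.p_front_edge + rng.normal(0, jit) + common
        p_c = spec.p_front_cross + rng.normal(0, jit) + common
        crossing[i] = p_c
        # quadratic through (m0, p_a), (0.5, p_c), (m1, p_b)
        coeffs = np.polyfit([m0, 0.5, m1], [p_a, p_c, p_b], 2)
        p = np.polyval(coeffs, m)
        dp = np.polyval(np.polyder(coeffs), m)
        ddp = float(np.polyder(coeffs, 2)[0])
        z = origin + (m + 1j * p) * baseline
        pts = np.column_stack([z.real, z.imag])
        polylines.append(pts)
        # tangent (away from the injected left eye = increasing m)
        tangent = np.angle((1.0 + 1j * dp) * baseline)
        # signed curvature of (m, p(m)) in normalized units -> per um
        kappa_norm = ddp / (1.0 + dp**2) ** 1.5
        kappa_um = kappa_norm / eye_dist_um
        all_pts.append(pts)
        all_dir.append(np.mod(tangent, 2.0 * np.pi))
        all_kappa.append(kappa_um)
        all_tid.append(np.full(m.size, i))

    clean = _render_polylines(
        polylines,
        (h, w),
        spec.profile_sigma_um / spec.pixel_size_um,
        spec.amplitude,
    )
    img = _add_noise(clean, spec.background, spec.noise_sigma, rng)
    sat_mask = None
    if spec.saturation_level is not None:
        sat_mask = img >= spec.saturation_level
        img = np.minimum(img, spec.saturation_level)

    jit = spec.landmark_jitter_px
    landmarks = EmbryoLandmarks(
        left_eye=(lx + rng.normal(0, jit), ly + rng.normal(0, jit)),
        right_eye=(rx + rng.normal(0, jit), ry + rng.normal(0, jit)),
        injected_eye=spec.injected_eye,
    )
    truth = ChiasmTruth(
        points_xy=np.concatenate(all_pts),
        direction_rad=np.concatenate(all_dir),
        kappa_per_um=np.concatenate(all_kappa),
        trajectory_id=np.concatenate(all_tid),
        crossing_p=crossing,
        saturated_mask=sat_mask,
    )
    return RasterImage(img, spec.pixel_size_um, spec.saturation_level), landmarks, truth


@dataclass
class Specimen:
    image: RasterImage
    landmarks: EmbryoLandmarks
    truth: ChiasmTruth


def make_cohort(
    n_specimens: int,
    spec: PhantomSpec,
    effects: dict | None = None,
    seed: int = 0,
    genotype: str = "",
) -> list[Specimen]:
    """A cohort of specimens sharing one parameter set.

    Per-specimen seeds are spawned from the master seed, and each specimen
    gets realistic inter-individual variation: its own head placement
    (rotation within +-8 degrees, +-4% eye-distance scale, translation) and
    a +-10% labelling amplitude factor.  ``effects`` overrides PhantomSpec
    fields for the whole cohort (e.g. ``{"anterior_shift": 0.06}``).
    """
    if n_specimens < 1:
        raise InvalidParameterError("n_specimens must be >= 1")
    if effects:
        spec = replace(spec, **effects)
    master = np.random.SeedSequence(seed)
    children = master.spawn(n_specimens)
    out = []
    for i, child in enumerate(children):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(child_seed)
        h, w = spec.size
        lx, ly = spec.left_eye
        rx, ry = spec.right_eye
        centre = complex((lx + rx) / 2.0, (ly + ry) / 2.0)
        half = complex(rx, ry) - centre
        rot = math.radians(rng.normal(0.0, 4.0))
        scale = 1.0 + rng.normal(0.0, 0.02)
        shift = complex(rng.normal(0.0, 3.0), rng.normal(0.0, 3.0))
        half2 = half * scale * complex(math.cos(rot), math.sin(rot))
        left = centre - half2 + shift
        right = centre + half2 + shift
        sp = replace(
            spec,
            left_eye=(left.real, left.imag),
            right_eye=(right.real, right.imag),
            amplitude=spec.amplitude * (1.0 + rng.normal(0.0, 0.08)),
            seed=int(rng.integers(2**31)),
        )
        image, landmarks, truth = make_phantom_chiasm(sp)
        landmarks.specimen_id = f"{genotype or 'spec'}-{i:02d}"
        landmarks.genotype = genotype
        out.append(Specimen(image, landmarks, truth))
    return out
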