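"""Self-validation experiments on phantoms with known ground truth.

Because no public image set exists for this preparation, the package
validates itself against its own synthetic generators: every function here
sets up a phantom study, runs the regular pipeline on it, and returns the
measured accuracy or calibration figures.  The test suite asserts on these
figures; the acceptance script reports them.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from . import filters
from .config import PipelineConfig
from .field import (
    curvature_from_curl,
    resolve_directions,
    smooth_direction_field,
)
from .image import RasterImage
from .pipeline import analyze_specimen
from .registration import (
    EmbryoLandmarks,
    GridSpec,
    bin_sample,
    cohort_heatmap,
    normalize_vectors,
)
from .ridge import median_threshold, nonmax_suppress
from .stats import MEASURES, bh_fdr, compare_genotypes, two_sample_t, watson_williams
from .synth import PhantomSpec, make_arc, make_cohort, make_stripe


def _sub_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# filter-stage checks


def steering_identity_errors(seed: int = 0, n_angles: int = 50) -> dict:
    """Steered responses vs the closed trigonometric form and vs direct
    convolution with the explicitly rotated kernel."""
    rng = np.random.default_rng(seed)
    img = RasterImage(rng.random((64, 64)) * 10.0, 1.0)
    bank = filters.build_filter_bank(1.8, 1.0)
    basis = filters.basis_responses(img, bank)
    a = 0.5 * (basis.r_a + basis.r_c)
    b = 0.5 * (basis.r_a - basis.r_c)
    c = -basis.r_b
    rel = 0.0
    for theta in rng.uniform(0.0, np.pi, n_angles):
        steered = filters.steered_response(basis, theta)
        closed = a + b * np.cos(2 * theta) + c * np.sin(2 * theta)
        rel = max(rel, float(np.max(np.abs(steered - closed)) / np.max(np.abs(steered))))
    # rotated-kernel cross-check at pi/4
    from scipy import ndimage

    theta = np.pi / 4.0
    kern = filters.oriented_kernel(bank, theta)
    direct = ndimage.correlate(img.pixels, kern, mode="reflect")
    steered = filters.steered_response(basis, theta)
    rms = float(np.sqrt(np.mean((steered - direct) ** 2) / np.mean(direct**2)))
    return {"closed_form_rel_err": rel, "rotated_kernel_rel_rms": rms}


def _stripe_orientation_field(angle_rad, noise_sigma=0.0, seed=0):
    img, truth = make_stripe(angle_rad, noise_sigma=noise_sigma, seed=seed)
    bank = filters.build_filter_bank(1.8, img.pixel_size_um)
    fld = filters.dominant_orientation(filters.basis_responses(img, bank))
    fld = median_threshold(img, nonmax_suppress(fld), 2.0)
    return img, truth, fld


def stripe_orientation_errors(
    angles_deg: np.ndarray | None = None, seed: int = 0
) -> np.ndarray:
    """Absolute error (deg) of the mean recovered centreline orientation
    for straight ridges across the axial range."""
    from .stats import circular_mean

    if angles_deg is None:
        angles_deg = np.arange(0, 180, 5)
    errors = []
    for deg in angles_deg:
        _, truth, fld = _stripe_orientation_field(np.radians(deg), seed=seed)
        est = circular_mean(fld.theta[fld.mask], axial=True)
        diff = abs(est - np.radians(deg % 180)) % np.pi
        errors.append(np.degrees(min(diff, np.pi - diff)))
    return np.asarray(errors)


def stripe_thinning_metrics(
    angle_deg: float = 30.0, seed: int = 0, noise_sigma: float = 1.0
) -> dict:
    """Centreline quality after NMS + threshold on one stripe.

    Walks the stripe axis in 1 px steps over its central 90% and reports the
    fraction of steps covered by a <= 2 px-wide retained cross-section.
    """
    img, truth, fld = _stripe_orientation_field(
        np.radians(angle_deg), noise_sigma=noise_sigma, seed=seed
    )
    ys, xs = np.nonzero(fld.mask)
    h, w = img.shape
    cy, cx = float(h // 2), float(w // 2)  # the generator's centreline origin
    u = np.array([np.cos(np.radians(angle_deg)), np.sin(np.radians(angle_deg))])
    n = np.array([-u[1], u[0]])
    t = (xs - cx) * u[0] + (ys - cy) * u[1]
    d = (xs - cx) * n[0] + (ys - cy) * n[1]
    # ignore pixels far from the true centreline (stray noise detections)
    on_line = np.abs(d) <= 3.0
    t, d = t[on_line], d[on_line]
    # walk only where the mask can exist: the border band one kernel support
    # wide is flagged off by design
    margin = 9.0
    cl = truth.centreline_xy
    interior = (
        (cl[:, 0] >= margin)
        & (cl[:, 0] <= w - 1 - margin)
        & (cl[:, 1] >= margin)
        & (cl[:, 1] <= h - 1 - margin)
    )
    t_truth = (cl[interior, 0] - cx) * u[0] + (cl[interior, 1] - cy) * u[1]
    lo, hi = np.percentile(t_truth, [5, 95])
    steps = np.arange(lo, hi, 1.0)
    covered = 0
    for s in steps:
        # +-0.75 px window: axial projections of a connected digital line
        # can be up to sqrt(2)/2 px apart, so a 1 px window can fall between
        # two pixels of an unbroken centreline
        sel = np.abs(t - s) <= 0.75
        if sel.sum() >= 1 and np.ptp(d[sel]) <= 1.5 and np.all(np.abs(d[sel]) <= 1.5):
            covered += 1
    return {
        "coverage": covered / len(steps),
        "n_retained": int(fld.mask.sum()),
        "n_off_line": int((~on_line).sum()),
    }


def threshold_survivor_mismatch(seed: int = 0) -> int:
    """Pixels where the pipeline's median threshold disagrees with an
    explicit per-pixel re-application of the two 2x-median rules."""
    img, _ = make_stripe(np.radians(40), noise_sigma=3.0, amplitude=50, seed=seed)
    bank = filters.build_filter_bank(1.8, img.pixel_size_um)
    fld = filters.dominant_orientation(filters.basis_responses(img, bank))
    fld = nonmax_suppress(fld)
    out = median_threshold(img, fld, 2.0)
    med_i = float(np.median(np.sort(img.pixels.ravel())))
    med_r = float(np.median(np.sort(fld.response.ravel())))
    mismatch = 0
    h, w = img.shape
    for y in range(h):
        for x in range(w):
            keep = fld.mask[y, x]
            if img.pixels[y, x] < 2.0 * med_i or fld.response[y, x] < 2.0 * med_r:
                keep = False
            if keep != out.mask[y, x]:
                mismatch += 1
    return mismatch


# ---------------------------------------------------------------------------
# curvature


def ring_curvature(
    radii_um=(20.0, 50.0, 100.0), seed: int = 0, smoothing_sigma_um: float = 30.0
) -> dict:
    """Median |curl|-curvature on closed-ring phantoms vs 1/r.

    Rings (closed arcs) are used because an open arc shorter than the
    smoothing scale has no symmetric smoothing window anywhere; the travel
    sense, which is ill-posed for a loop under the eye rule, is resolved
    against the generator's recorded tangent (|kappa| does not depend on
    it).
    """
    out = {}
    for r in radii_um:
        img, truth = make_arc(r, span_deg=360.0, noise_sigma=2.0, seed=_sub_seed(seed, int(r)))
        bank = filters.build_filter_bank(1.8, img.pixel_size_um)
        fld = filters.dominant_orientation(filters.basis_responses(img, bank))
        fld = median_threshold(img, nonmax_suppress(fld), 2.0)
        tree = cKDTree(truth.centreline_xy)
        yy, xx = np.indices(img.shape)
        _, idx = tree.query(np.column_stack([xx.ravel(), yy.ravel()]))
        ref = truth.direction_rad[idx].reshape(img.shape)
        smoothed = smooth_direction_field(
            resolve_directions(fld, ref), smoothing_sigma_um, img.pixel_size_um
        )
        curv = curvature_from_curl(smoothed, img.pixel_size_um)
        med = float(np.nanmedian(np.abs(curv.kappa[curv.mask])))
        out[float(r)] = {
            "median_kappa": med,
            "true_kappa": 1.0 / r,
            "rel_err": abs(med - 1.0 / r) * r,
        }
    return out


# ---------------------------------------------------------------------------
# registration


def _random_vector_table(rng: np.random.Generator, landmarks: EmbryoLandmarks, n: int = 400):
    import pandas as pd

    tr_m = rng.uniform(0.35, 0.65, n)
    tr_p = rng.uniform(0.02, 0.28, n)
    (lx, ly), (rx, ry) = landmarks.left_eye, landmarks.right_eye
    base = complex(rx, ry) - complex(lx, ly)
    z = complex(lx, ly) + (tr_m + 1j * tr_p) * base
    rot = np.angle(base)
    direction = rng.uniform(0, 2 * np.pi, n)
    return pd.DataFrame(
        {
            "x_px": z.real,
            "y_px": z.imag,
            "orientation_rad": np.mod(direction + rot, np.pi),
            "direction_rad": np.mod(direction + rot, 2 * np.pi),
            "curv_direction_rad": np.mod(direction + rot + np.pi / 2, 2 * np.pi),
            "kappa_per_um": rng.normal(0.0, 0.01, n),
            "response": rng.uniform(1, 10, n),
        }
    )


def registration_invariance(seed: int = 0, n_draws: int = 5) -> dict:
    """Bin a specimen, then re-bin after random similarity perturbations of
    all raw coordinates; counts must match exactly, angles to 1e-6."""
    rng = np.random.default_rng(seed)
    base_lm = EmbryoLandmarks((40.0, 60.0), (360.0, 70.0))
    table = _random_vector_table(rng, base_lm)
    pixel_size = 1.25
    grid = GridSpec()
    ref = bin_sample(normalize_vectors(table, base_lm, pixel_size), grid)
    max_count = 0
    max_angle = 0.0
    for _ in range(n_draws):
        ang = rng.uniform(0, 2 * np.pi)
        scale = rng.uniform(0.6, 1.6)
        shift = complex(*rng.uniform(-50, 50, 2))
        q = scale * np.exp(1j * ang)

        def warp(x, y):
            z = (np.asarray(x) + 1j * np.asarray(y)) * q + shift
            return z.real, z.imag

        t2 = table.copy()
        t2["x_px"], t2["y_px"] = warp(table["x_px"], table["y_px"])
        for col, period in (
            ("orientation_rad", np.pi),
            ("direction_rad", 2 * np.pi),
            ("curv_direction_rad", 2 * np.pi),
        ):
            t2[col] = np.mod(table[col] + ang, period)
        t2["kappa_per_um"] = table["kappa_per_um"] / scale
        lx, ly = warp(*base_lm.left_eye)
        rx, ry = warp(*base_lm.right_eye)
        lm2 = EmbryoLandmarks((float(lx), float(ly)), (float(rx), float(ry)))
        other = bin_sample(normalize_vectors(t2, lm2, pixel_size), grid)
        max_count = max(max_count, int(np.max(np.abs(other.count - ref.count))))
        for attr, period in (
            ("mean_orientation", np.pi),
            ("mean_curv_direction", 2 * np.pi),
        ):
            va, vb = getattr(ref, attr), getattr(other, attr)
            both = np.isfinite(va) & np.isfinite(vb)
            diff = np.abs(np.mod(va[both] - vb[both] + period / 2, period) - period / 2)
            max_angle = max(max_angle, float(diff.max()))
        both = np.isfinite(ref.mean_curv_magnitude) & np.isfinite(other.mean_curv_magnitude)
        max_angle = max(
            max_angle,
            float(
                np.max(
                    np.abs(
                        ref.mean_curv_magnitude[both] - other.mean_curv_magnitude[both]
                    )
                )
            ),
        )
    return {"max_count_diff": max_count, "max_angle_diff": max_angle}


# ---------------------------------------------------------------------------
# statistical calibration


def type1_rates(seed: int = 0, n_reps: int = 2000, alpha: float = 0.05) -> dict:
    """Empirical type-I error of the two per-bin tests under their nulls."""
    rng = np.random.default_rng(seed)
    ww_rej = 0
    for _ in range(n_reps):
        res = watson_williams(rng.vonmises(0.0, 5.0, 20), rng.vonmises(0.0, 5.0, 20))
        if res.testable and res.pvalue < alpha:
            ww_rej += 1
    t_rej = 0
    for _ in range(n_reps):
        res = two_sample_t(rng.normal(0, 1, 10), rng.normal(0, 1, 10))
        if res.testable and res.pvalue < alpha:
            t_rej += 1
    return {"watson_williams": ww_rej / n_reps, "t_test": t_rej / n_reps}


def fdr_null_proportion(
    seed: int = 0, n_maps: int = 500, n_bins: int = 1024, alpha: float = 0.05
) -> dict:
    """Mean false-discovery proportion of BH on all-null p-value maps."""
    rng = np.random.default_rng(seed)
    fdp = np.empty(n_maps)
    for i in range(n_maps):
        rej = bh_fdr(rng.uniform(size=n_bins), alpha)
        fdp[i] = 1.0 if rej.any() else 0.0  # complete null: all rejections false
    se = float(fdp.std(ddof=1) / np.sqrt(n_maps))
    return {"mean_fdp": float(fdp.mean()), "se": se, "bound": alpha + 2 * se}


# ---------------------------------------------------------------------------
# end-to-end cohort experiments


def _run_experiment(
    spec: PhantomSpec,
    shift: float,
    seed: int,
    n_per_cohort: int = 5,
    config: PipelineConfig | None = None,
):
    config = config or PipelineConfig()
    cohort_a = make_cohort(n_per_cohort, spec, seed=_sub_seed(seed, 1), genotype="a")
    cohort_b = make_cohort(
        n_per_cohort,
        spec,
        effects={"anterior_shift": shift},
        seed=_sub_seed(seed, 2),
        genotype="b",
    )
    binned_a = [analyze_specimen(s.image, s.landmarks, config)[1] for s in cohort_a]
    binned_b = [analyze_specimen(s.image, s.landmarks, config)[1] for s in cohort_b]
    comparison = compare_genotypes(binned_a, binned_b, alpha=config.alpha)
    return comparison, binned_a, binned_b


def null_experiment_fractions(
    n_experiments: int = 100, seed: int = 0, n_per_cohort: int = 5
) -> dict:
    """Mean fraction of FDR-significant bins per measure when both cohorts
    come from the same phantom distribution."""
    spec = PhantomSpec()
    nbins = GridSpec().n_rows * GridSpec().n_cols
    fractions = {m: [] for m in MEASURES}
    for i in range(n_experiments):
        comparison, _, _ = _run_experiment(
            spec, 0.0, _sub_seed(seed, 1000 + i), n_per_cohort
        )
        for m in MEASURES:
            fractions[m].append(comparison.significant[m].sum() / nbins)
    return {m: float(np.mean(v)) for m, v in fractions.items()}


def effect_recovery(
    shift: float = 0.05,
    n_experiments: int = 5,
    seed: int = 0,
    n_per_cohort: int = 5,
) -> dict:
    """Anterior-shift recovery: where count rejections fall, and how far the
    count heat-map centre of mass moves, vs the imposed offset."""
    spec = PhantomSpec()
    grid = GridSpec()
    p_centers = 0.5 * (grid.p_edges[:-1] + grid.p_edges[1:])
    p_mid = 0.5 * (grid.p_range[0] + grid.p_range[1])
    anterior = 0
    total = 0
    com_shifts = []
    for i in range(n_experiments):
        comparison, binned_a, binned_b = _run_experiment(
            spec, shift, _sub_seed(seed, 2000 + i), n_per_cohort
        )
        rows = np.nonzero(comparison.significant["count"])[0]
        total += len(rows)
        anterior += int(np.sum(p_centers[rows] < p_mid))

        def com_p(heat):
            weights = heat.sum(axis=1)
            return float(np.sum(p_centers * weights) / weights.sum())

        com_shifts.append(
            com_p(cohort_heatmap(binned_a)) - com_p(cohort_heatmap(binned_b))
        )
    return {
        "n_rejections": total,
        "anterior_fraction": anterior / total if total else float("nan"),
        "com_shift": float(np.mean(com_shifts)),
        "imposed_shift": shift,
        "bin_height": grid.p_width,
    }


# ---------------------------------------------------------------------------
# expression


def expression_ramp_check() -> dict:
    """Gradient of a synthetic linear ramp: constant, high-to-low, with
    magnitude equal to the slope."""
    from .expression import expression_gradient

    grid = GridSpec()
    slope = 50.0  # intensity per normalized p unit
    p_centers = 0.5 * (grid.p_edges[:-1] + grid.p_edges[1:])
    ramp = np.tile(slope * p_centers[:, None], (1, grid.n_cols))
    gm, gp = expression_gradient(ramp, grid)
    return {
        "max_gm": float(np.max(np.abs(gm))),
        "gp_deviation": float(np.max(np.abs(gp + slope))),
        "points_high_to_low": bool(np.all(gp < 0)),
    }
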