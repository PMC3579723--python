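"""Per-bin two-group statistics with FDR control.

The unit of replication is the specimen: each embryo contributes one value
per grid square per measure (a count, a circular mean orientation, a
circular mean curvature direction, a mean curvature magnitude).  Counts and
curvature magnitudes are compared with the classic pooled-variance two-sample
t-test; orientations (axial, compared on doubled angles) and curvature
directions use the Watson-Williams test for equality of mean directions.
Each measure's 1024-bin p-value map is corrected separately with the
Benjamini-Hochberg step-up procedure at alpha = 0.05.

A bin is *untestable* for a measure when a group has fewer than two
specimens with data there, when a pooled variance vanishes with unequal
means, or when the Watson-Williams concentration requirement fails; such
bins carry NaN p-values and are excluded from the FDR ranking (reported,
never silently dropped).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InvalidParameterError

#: minimum weighted mean resultant length for the Watson-Williams test
WW_MIN_RESULTANT = 0.45

MEASURES = ("count", "orientation", "curv_direction", "curv_magnitude")


class TestResult(NamedTuple):
    statistic: float
    pvalue: float
    testable: bool
    note: str = ""


def circular_mean(angles: Sequence[float], axial: bool = False) -> float:
    """Mean direction of a sample of angles (radians).

    With ``axial=True`` the angles are orientations defined modulo pi:
    they are doubled, averaged, and the result is halved back into
    [0, pi).  Returns NaN when the resultant length is numerically zero
    (the mean is undefined, e.g. two orthogonal orientations).
    """
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise InvalidParameterError("circular_mean of an empty sample")
    mult = 2.0 if axial else 1.0
    z = np.exp(1j * mult * a).mean()
    if abs(z) < 1e-9:
        return float("nan")
    mean = np.angle(z) / mult
    period = np.pi if axial else 2.0 * np.pi
    return float(np.mod(mean, period))


def resultant_length(angles: Sequence[float], axial: bool = False) -> float:
    """Mean resultant length R-bar in [0, 1]."""
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise InvalidParameterError("resultant_length of an empty sample")
    mult = 2.0 if axial else 1.0
    return float(abs(np.exp(1j * mult * a).mean()))


def _kappa_from_rbar(rbar: float) -> float:
    """Fisher's approximation to the inverse of A1 (von Mises MLE)."""
    if rbar < 0.53:
        return 2.0 * rbar + rbar**3 + 5.0 * rbar**5 / 6.0
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1.0 - rbar)
    return 1.0 / (rbar**3 - 4.0 * rbar**2 + 3.0 * rbar)


def watson_williams(
    group_a: Sequence[float],
    group_b: Sequence[float],
    axial: bool = False,
) -> TestResult:
    """Two-sample Watson-Williams test for equal mean directions.

    The F statistic compares the summed per-group resultant lengths with the
    pooled resultant, with the standard 1 + 3/(8 kappa) concentration
    correction, and is referred to F(1, N - 2).  The test assumes reasonably
    concentrated von Mises samples: when the weighted mean resultant length
    falls below ``WW_MIN_RESULTANT`` the bin is flagged untestable rather
    than trusted.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        return TestResult(float("nan"), float("nan"), False, "n < 2")
    if axial:
        a = 2.0 * a
        b = 2.0 * b
    n1, n2 = a.size, b.size
    n = n1 + n2
    r1 = n1 * abs(np.exp(1j * a).mean())
    r2 = n2 * abs(np.exp(1j * b).mean())
    r_all = abs(np.exp(1j * np.concatenate([a, b])).sum())
    rw = (r1 + r2) / n
    if rw < WW_MIN_RESULTANT:
        return TestResult(
            float("nan"), float("nan"), False, f"resultant {rw:.3f} < {WW_MIN_RESULTANT}"
        )
    kappa = _kappa_from_rbar(rw)
    correction = 1.0 + 3.0 / (8.0 * kappa)
    denom = n - (r1 + r2)
    numer = (r1 + r2) - r_all
    if denom <= 1e-12:
        # perfectly concentrated groups: any mean difference is decisive
        if numer <= 1e-12:
            return TestResult(0.0, 1.0, True)
        return TestResult(float("inf"), 0.0, True)
    f_stat = correction * (n - 2) * numer / denom
    f_stat = max(f_stat, 0.0)
    p = float(sps.f.sf(f_stat, 1, n - 2))
    return TestResult(float(f_stat), p, True)


def two_sample_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Classic pooled-variance two-sample t-test, two-sided.

    Degenerate samples (zero pooled variance) give p = 1 when the means are
    equal and an untestable flag otherwise — a deterministic difference has
    no valid t-scale.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        return TestResult(float("nan"), float("nan"), False, "n < 2")
    nx, ny = x.size, y.size
    sx = x.var(ddof=1)
    sy = y.var(ddof=1)
    pooled = ((nx - 1) * sx + (ny - 1) * sy) / (nx + ny - 2)
    diff = x.mean() - y.mean()
    if pooled <= 0:
        if abs(diff) <= 1e-12:
            return TestResult(0.0, 1.0, True)
        return TestResult(float("nan"), float("nan"), False, "zero pooled variance")
    t = diff / np.sqrt(pooled * (1.0 / nx + 1.0 / ny))
    p = 2.0 * float(sps.t.sf(abs(t), nx + ny - 2))
    return TestResult(float(t), p, True)


def bh_fdr(pvalues: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at level ``alpha``.

    NaN entries (untestable bins) are excluded before ranking and are never
    rejected.  Returns a boolean array of the same shape.
    """
    p = np.asarray(pvalues, dtype=float)
    reject = np.zeros(p.shape, dtype=bool)
    testable = np.isfinite(p)
    if testable.any():
        ok, _, _, _ = multipletests(p[testable], alpha=alpha, method="fdr_bh")[:4]
        reject[testable] = ok
    return reject


@dataclass
class GroupComparison:
    """Per-bin p-values and FDR significance masks for the four measures."""

    pvalues: dict[str, np.ndarray]
    statistics: dict[str, np.ndarray]
    significant: dict[str, np.ndarray]
    n_a: dict[str, np.ndarray]
    n_b: dict[str, np.ndarray]
    alpha: float
    label_a: str = "A"
    label_b: str = "B"


def _vectorized_t(values_a: np.ndarray, values_b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pooled t-test per column, NaN-aware.  Returns (t, p, n_a, n_b)."""
    import warnings

    na = np.sum(np.isfinite(values_a), axis=0)
    nb = np.sum(np.isfinite(values_b), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # empty/degenerate slices are resolved to NaN below
        warnings.simplefilter("ignore", RuntimeWarning)
        ma = np.nanmean(np.where(np.isfinite(values_a), values_a, np.nan), axis=0)
        mb = np.nanmean(np.where(np.isfinite(values_b), values_b, np.nan), axis=0)
        va = np.nanvar(values_a, axis=0, ddof=1)
        vb = np.nanvar(values_b, axis=0, ddof=1)
        pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t = (ma - mb) / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
        p = 2.0 * sps.t.sf(np.abs(t), na + nb - 2)
    diff = ma - mb
    degenerate = pooled <= 0
    equal = degenerate & (np.abs(diff) <= 1e-12)
    t = np.where(equal, 0.0, t)
    p = np.where(equal, 1.0, p)
    bad = (na < 2) | (nb < 2) | (degenerate & ~equal)
    t = np.where(bad, np.nan, t)
    p = np.where(bad, np.nan, p)
    return t, p, na, nb


def compare_genotypes(
    cohort_a: Sequence,
    cohort_b: Sequence,
    alpha: float = 0.05,
    label_a: str = "A",
    label_b: str = "B",
) -> GroupComparison:
    """Compare two cohorts of :class:`~axonfield.registration.BinnedSample`.

    Counts and curvature magnitudes go through the t-test, orientations and
    curvature directions through Watson-Williams on each specimen's per-bin
    circular mean; each measure's map is FDR-corrected separately.
    """
    if len(cohort_a) < 2 or len(cohort_b) < 2:
        raise InvalidParameterError("each cohort needs at least two specimens")
    shape = cohort_a[0].count.shape
    nbins = int(np.prod(shape))

    def stack(cohort, attr):
        return np.stack([getattr(s, attr).reshape(nbins) for s in cohort]).astype(float)

    pvals: dict[str, np.ndarray] = {}
    stats_out: dict[str, np.ndarray] = {}
    n_a: dict[str, np.ndarray] = {}
    n_b: dict[str, np.ndarray] = {}

    for measure, attr in (("count", "count"), ("curv_magnitude", "mean_curv_magnitude")):
        t, p, na, nb = _vectorized_t(stack(cohort_a, attr), stack(cohort_b, attr))
        stats_out[measure] = t.reshape(shape)
        pvals[measure] = p.reshape(shape)
        n_a[measure] = na.reshape(shape)
        n_b[measure] = nb.reshape(shape)

    for measure, attr, axial in (
        ("orientation", "mean_orientation", True),
        ("curv_direction", "mean_curv_direction", False),
    ):
        va = stack(cohort_a, attr)
        vb = stack(cohort_b, attr)
        f = np.full(nbins, np.nan)
        p = np.full(nbins, np.nan)
        na = np.sum(np.isfinite(va), axis=0)
        nb = np.sum(np.isfinite(vb), axis=0)
        for j in np.nonzero((na >= 2) & (nb >= 2))[0]:
            res = watson_williams(
                va[np.isfinite(va[:, j]), j], vb[np.isfinite(vb[:, j]), j], axial=axial
            )
            if res.testable:
                f[j] = res.statistic
                p[j] = res.pvalue
        stats_out[measure] = f.reshape(shape)
        pvals[measure] = p.reshape(shape)
        n_a[measure] = na.reshape(shape)
        n_b[measure] = nb.reshape(shape)

    significant = {m: bh_fdr(pvals[m], alpha) for m in MEASURES}
    return GroupComparison(
        pvalues=pvals,
        statistics=stats_out,
        significant=significant,
        n_a=n_a,
        n_b=n_b,
        alpha=alpha,
        label_a=label_a,
        label_b=label_b,
    )
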