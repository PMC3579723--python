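# Methods

This note records the model behind each pipeline stage, the defaults and why
they were chosen, what the synthetic phantoms do and do not emulate, and the
numerical decisions a maintainer would otherwise have to reverse-engineer.

## Steerable ridge filtering

Axon bundles in fluorescence images are bright curvilinear ridges whose
cross-section is approximately Gaussian with σ ≈ 1.8 μm. The matched
detector at orientation θ is the *negated* second directional derivative of
a Gaussian taken along the ridge normal; it is maximal and positive when the
filter runs along a bright ridge. This family is exactly steerable with the
three-member G₂ basis. The basis stored here is

    k_a = −σ²G_yy,  k_b = −σ²G_xy,  k_c = −σ²G_xx,

so the interpolation functions are cos²θ, −2 cosθ sinθ, sin²θ and the
steered response is the second-harmonic polynomial A + B cos 2θ + C sin 2θ
with A = (r_a + r_c)/2, B = (r_a − r_c)/2, C = −r_b. The argmax is the
closed form θ\* = ½ atan2(C, B); no angular search is ever performed, and a
dense angular sweep is used in the tests only as an oracle. The σ² factor
makes responses dimensionless in scale.

Parameters and conventions:

* `sigma_um` (default **1.8 μm**): the Gaussian σ of the basis. "Width" of a
  filter is ambiguous (σ vs FWHM); σ is the default reading because it is
  the basis' only scale parameter and matches embryonic axon-bundle calibre;
  `sigma_is_fwhm=True` switches to the FWHM reading (σ = width / 2.355).
* All physical scales are given in μm and divided by `pixel_size_um`.
  A filter σ below 0.5 px is refused as undersampled.
* Kernels are truncated at 4σ; the truncation residual of the even kernels
  is removed by mean subtraction so every kernel has exactly zero DC
  response. `k_c` is stored as the literal 90° array rotation of `k_a`,
  which makes that symmetry exact on the sampled grid.
* Convolution uses reflect padding (edge sample repeated). The border band
  one kernel support wide is flagged off in the orientation-field mask:
  responses there mix real and mirrored image content.
* Isotropic pixels (B = C = 0) take θ\* = 0 by the atan2 convention. They
  carry no orientation information and are removed by non-maximum
  suppression, which cannot certify a directional maximum there.

## Ridge reduction

* **Non-maximum suppression** keeps a pixel only when its response
  *strictly* exceeds the responses at the two positions one pixel away
  along the ridge normal (θ\* + π/2). Flank responses are bilinearly
  interpolated by default; `nms_flank_mode="snapped"` rounds the offsets to
  the nearest integer neighbour for letter-exact reproduction of a
  pixel-neighbour rule. Strictness means plateaus — including perfectly
  flat images — retain nothing.
* **Global threshold**: a pixel survives only if its intensity is at least
  `threshold_factor` (default **2**) times the median intensity of the whole
  image *and* its response at least that factor times the median response of
  the whole image. Both medians run over all pixels, not just retained
  ones. Note this rule presumes a real noise floor: in a noise-free image
  with constant background the median response is zero and the response
  rule accepts everything, including the zero-crossing ring of the filter
  around each ridge. Phantom studies therefore include at least mild
  additive noise, which is also the realistic condition.
* **Saturation**: pixels at or above `saturation_level` are grouped into
  8-connected components; inside each component the orientation is filled by
  solving the Laplace equation for cos 2θ and sin 2θ (orientations are
  axial, so interpolation must happen in doubled-angle space) with Dirichlet
  values from the one-pixel rim, and the response is set to the rim mean.
  Components with no valid rim (e.g. running off the image) stay masked out.

## Direction and curvature

* Each orientation θ is disambiguated to the candidate in {θ, θ + π} with
  positive dot product onto the ray from the injected eye — axons grow away
  from their eye of origin. Exact ties fall back to the +x candidate, then
  +y. `resolve_directions` offers the same disambiguation against an
  arbitrary reference field for geometries where the radial rule is
  ill-posed (closed validation loops, flow priors).
* Smoothing (default **30 μm**) is a normalized convolution: the unit-vector
  components, zeroed off the mask, are Gaussian-blurred together with the
  mask indicator and renormalized. Off-axon zeros therefore never bias the
  angle, and a uniform field is a fixed point. The smoothing could
  alternatively have been applied to raw responses or to doubled angles;
  component smoothing of the disambiguated field was chosen because the
  curl step needs a true (not axial) vector field. After smoothing, the
  direction value is defined on the whole blurred support, which is what
  makes the finite differences of the next step well posed at the thin
  retained mask.
* Curvature is the 2-D scalar curl ∂v_y/∂x − ∂v_x/∂y of the smoothed unit
  field, by central differences in μm (one-sided at support edges; pixels
  with no usable neighbour are dropped). For a unit direction field the
  curl equals the derivative of the angle along the flow, i.e. the
  trajectory curvature; this identity is what the ring tests check. The
  curvature "vector" is |κ| along the turn-side normal (direction + π/2 for
  κ > 0).
* The second suppression pass re-runs the NMS rule using the *smoothed*
  orientation to define the normal and the original filter response as the
  height; a config switch (`second_nms_target="curvature"`) suppresses on
  curvature magnitude instead, since the quantity this pass was meant to
  thin is not pinned down by precedent.

A caution established during validation: smoothing at scale σ flattens any
direction structure on curves shorter than a few σ, because no point of a
short open arc has a symmetric smoothing window. Curvature validation
therefore uses closed rings (every point symmetric; direction exactly
preserved under normalized convolution), on which the pipeline recovers
1/r within a few percent at r = 20–100 μm. On open-ended real trajectories
the curvature near free ends is biased low on the last ~σ of arc.

## Registration, binning, statistics

* The eye landmarks define the unique rotation + uniform scale +
  translation sending the left eye to (0, 0) and the right eye to (1, 0).
  Coordinates are named (m, p): m along the baseline (midline at 0.5), p
  perpendicular, positive on the chiasm side (`chiasm_side=-1` flips it).
  Angles change by the rotation only. Curvature magnitudes are rescaled to
  rad per eye-distance unit so they are comparable across specimens of
  slightly different size; the eye-distance QC (flag above 8% relative
  difference between cohort means) guards the comparability assumption.
  The published grid notation is ambiguous about tuple ordering (the right
  eye is written "(0, 1)" yet the region "(0.4 : 0.6, 0.05 : 0.25)" only
  contains the chiasm if the first coordinate is mediolateral); the
  implemented convention is recorded in every output header and
  `axis_order` switches the printed ordering.
* Right-eye-injected specimens are mirrored (m → 1 − m, angles → π − angle
  in the matching period) so cohorts read uniformly as left-injected.
* The 32 × 32 grid covers m ∈ [0.4, 0.6], p ∈ [0.05, 0.25] with half-open
  bins (exact tiling, no double counting). Per bin and specimen: vector
  count, axial circular-mean orientation, circular-mean curvature
  direction, arithmetic-mean curvature magnitude. Empty bins carry count 0
  and NaN angular means — a circular mean of nothing is undefined.
* The unit of replication is the specimen: angular tests run on one summary
  angle per specimen per bin; pooling pixels would pseudo-replicate.
  Counts and curvature magnitudes use the pooled-variance two-sample
  t-test (magnitude is a linear quantity); orientations (doubled angles)
  and curvature directions use the Watson–Williams F-test with the
  1 + 3/(8κ̂) correction, κ̂ from Fisher's A1-inverse approximation. Bins
  where a group has fewer than two usable specimens, where a pooled
  variance vanishes with unequal means, or where the weighted mean
  resultant length falls below 0.45 (the test's standard applicability
  bound) are flagged untestable, reported, and excluded from ranking.
* Each measure's 1024-bin map is Benjamini–Hochberg-corrected separately at
  α = 0.05 (four independent maps, matching how the four measures are
  presented); a joint-family option would be a one-line change in
  `compare_genotypes`.

## Synthetic phantoms

`synth` provides straight stripes (orientation ground truth), circular
arcs/rings (analytic curvature 1/r), and full chiasm phantoms. A phantom
specimen is a scaled-down head: 448 × 448 px at 1.25 μm/px with a 320 μm
inter-eye distance — the true anatomy is several times larger, but this
size keeps whole-cohort simulations affordable while preserving the ratios
between filter scale (1.8 μm), smoothing scale (30 μm) and grid-square
size. The axon tract is a family of parabolic trajectories in the
normalized frame that leave the injected eye, converge on the midline and
cross it. Its depth structure models two features of real tracts: the
bundle is **topographically ordered** (trajectories keep their neighbour
order, placed at quantiles rather than resampled independently — real
retinotopic tracts are stereotyped between individuals, and independent
resampling would overstate inter-embryo variability at this scaled-down
count density), and it packs against a **sharp anterior boundary with an
exponentially tapering posterior tail** (truncated-exponential depth
profile, scale 0.02, cut at 0.08 normalized units), the way axons crowd the
edge of a repellent territory. Individual variability enters as a
per-specimen band offset (σ = 0.002), per-axon jitter that grows with
depth (stragglers wander; σ = 0.002 + 0.15 × depth), head placement
(rotation σ = 4°, scale σ = 2%, translation σ = 3 px), labelling-strength
variation (σ = 8%) and operator landmark annotation noise (σ = 0.8 px).
Images add Gaussian noise (σ = 4 on a background of 12 with ridge amplitude
60); Gaussian was preferred over Poisson for analytic tractability.
`anterior_shift` translates entire trajectories anteriorly — the mutant
signature — so the binned centre of mass moves by exactly the imposed
offset in expectation.

What the phantoms do *not* emulate: out-of-focus light and 3-D projection
artefacts of thick sections, fasciculation-defasciculation dynamics,
uneven DiI fill, real inter-embryo anatomical variation beyond similarity
transforms, and axons that turn back or leave the plane. Passing phantom
studies therefore demonstrates the correctness and calibration of the
measurement and statistics chain, not robustness to every property of real
microscopy data.

## Validation studies and problem sizes

`validation.py` (used by both the test suite and `scripts/acceptance.py`)
fixes the study sizes: 50 random angles for the steering identity; stripes
every 5° across the axial range; rings at r = 20/50/100 μm; 2000 null
replicates for each test's type-I error (von Mises κ = 5, n = 20 per group
for Watson–Williams; normal, n = 10 per group for the t-test); 500
simulated 1024-bin null maps for the FDR proportion; 100 simulated null
experiments and 5 effect experiments at the cohort sizes of the motivating
study (5 specimens per cohort). These sizes give Monte-Carlo standard
errors comfortably inside the asserted bands while keeping a full
validation run in the minutes range.

## Known limitations

* Single-scale analysis: bundles much thicker or thinner than the filter σ
  respond sub-optimally; no multi-scale selection is attempted.
* At crossings the orientation estimate reports the locally dominant
  bundle, and the smoothed direction field blends the two populations —
  per-bin summaries are averages over whatever crosses the bin.
* Curvature is biased low within ~one smoothing length of trajectory ends.
* The saturation-inpainting response fill is constant within a component,
  so a later strict NMS pass can remove inpainted plateau pixels; in
  practice saturated areas are small.
* Counts are proportional to centreline pixel density, not to the number of
  axons; they support distribution comparisons, never absolute axon counts.
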