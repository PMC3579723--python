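# axonfield

Steerable-filter quantification of labelled axon populations in 2-D
fluorescence images.

Dense axon tracts — the developing optic chiasm labelled by a DiI injection
into one eye is the motivating preparation — cannot be analysed by tracing
individual fibres. `axonfield` instead measures the *population*: at every
pixel that lies on an axon it records the local orientation, the direction
of travel away from the injected eye, and the trajectory curvature. Multiple
specimens are registered into a common anatomical frame through their eye
landmarks, summarised on a 32 × 32 grid, and cohorts (e.g. genotypes) are
compared square by square with circular statistics under false-discovery-rate
control. The package is aimed at developmental neurobiologists quantifying
guidance phenotypes in complex tracts, and ships a synthetic-phantom module
so every stage is testable without microscopy data.

## Method

**Orientation.** Bright axon bundles are ridges of roughly Gaussian
cross-section (σ ≈ 1.8 μm). The matched detector is the negated second
directional derivative of a Gaussian, which is steerable with three basis
kernels G₂ = {−σ²G_yy, −σ²G_xy, −σ²G_xx}. The response at orientation θ is
exactly

    R(θ) = cos²θ·r_a − 2 cosθ sinθ·r_b + sin²θ·r_c
         = A + B cos 2θ + C sin 2θ,

with A = (r_a + r_c)/2, B = (r_a − r_c)/2, C = −r_b, so the best orientation
is θ\* = ½ atan2(C, B) in closed form, with peak response A + √(B² + C²).

**Ridge reduction.** Non-maximum suppression keeps a pixel only if its
response strictly exceeds the two flanking samples one pixel away along the
ridge normal; a global threshold then removes pixels dimmer than twice the
median intensity or weaker than twice the median response. Orientations
inside small saturated patches are restored by harmonic interpolation of the
doubled-angle components from the patch rim.

**Direction and curvature.** Each axial orientation is disambiguated into
the direction pointing away from the injected eye, the unit field is
smoothed with a 30 μm Gaussian by normalized convolution over the retained
mask, and the scalar curl ∂v_y/∂x − ∂v_x/∂y of the unit field — which equals
the trajectory curvature κ in rad/μm — is taken by masked central
differences. A second suppression pass with the smoothed normals prunes
pixels displaced off-ridge.

**Registration and statistics.** The similarity transform that sends the
left eye to (0, 0) and the right eye to (1, 0) maps every specimen into
normalized (m, p) coordinates (m along the eye baseline, p toward the
chiasm); right-eye-injected specimens are mirrored. Vectors inside
m ∈ [0.4, 0.6], p ∈ [0.05, 0.25] are binned 32 × 32; per bin and specimen
the count, circular-mean orientation, circular-mean curvature direction and
mean curvature magnitude are kept. Between cohorts, counts and curvature
magnitudes are compared with Student's t-test and the angular measures with
the Watson–Williams test on per-specimen means; each measure's 1024 p-values
are corrected by Benjamini–Hochberg at α = 0.05.

## Worked example

Compare two synthetic cohorts of five specimens whose only difference is a
0.05-unit (8 grid rows) anterior shift of the crossing tract:

```python
import numpy as np
from axonfield import compare_cohorts, eye_distance_qc
from axonfield.config import PipelineConfig
from axonfield.synth import PhantomSpec, make_cohort

spec = PhantomSpec()
wild_type = make_cohort(5, spec, seed=11, genotype="wild-type")
mutant = make_cohort(5, spec, effects={"anterior_shift": 0.05}, seed=12,
                     genotype="mutant")

qc = eye_distance_qc(
    {"wild-type": [s.landmarks for s in wild_type],
     "mutant": [s.landmarks for s in mutant]},
    pixel_size_um=spec.pixel_size_um)
print(f"eye-distance QC: {qc.max_relative_difference:.1%} between cohort "
      f"means (limit {qc.limit:.0%}, flagged={qc.flagged})")

config = PipelineConfig(pixel_size_um=spec.pixel_size_um)
comparison, binned_wt, binned_mut = compare_cohorts(
    [(s.image, s.landmarks) for s in wild_type],
    [(s.image, s.landmarks) for s in mutant],
    config, label_a="wild-type", label_b="mutant")
for measure, sig in comparison.significant.items():
    rows = np.nonzero(sig)[0]
    line = f"{measure:15s} significant bins: {sig.sum():3d}"
    if len(rows):
        line += f"  (fraction in anterior half: {(rows < 16).mean():.2f})"
    print(line)
```

prints

```
eye-distance QC: 0.9% between cohort means (limit 8%, flagged=False)
count           significant bins:  12  (fraction in anterior half: 1.00)
orientation     significant bins:   4  (fraction in anterior half: 1.00)
curv_direction  significant bins:   2  (fraction in anterior half: 0.50)
curv_magnitude  significant bins:   0
```

The anteriorized tract shows up as significant count and orientation bins
concentrated in the anterior half of the grid, while curvature magnitude —
unchanged by a rigid shift — shows nothing; the eye-distance QC confirms the
cohorts are geometrically comparable.

The same pipeline is available from the shell: `axonfield synth` writes
phantom cohorts as TIFFs with landmark tables, `axonfield analyze` produces
a per-pixel vector table for one specimen, `axonfield compare` runs the full
two-cohort comparison, `axonfield expression` builds staining-intensity and
gradient maps, and `axonfield qc` checks inter-eye distances.

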