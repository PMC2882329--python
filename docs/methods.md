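# Methods notes

## Measurement model

The package treats a quantification run as a deterministic function of
(images, masks, landmarks, thresholds). One animal contributes one serial
section stack per dLGN, ordered rostral → caudal at 50 µm spacing with
1.00 µm²/pixel; the dLGN boundary, the dorsomedial and ventrolateral tips,
the outer (optic-tract-adjacent) boundary arc, the ventrolateral monocular
segment and the 40,000-px background region are *inputs*, not outputs — the
package does not segment the nucleus.

The analysis section is the one 100 µm rostral of the largest-area section;
with 50 µm sections that is exactly two indices toward the rostral end
(index 0). Area-argmax ties are broken toward the more rostral section so the
selection is deterministic; a stack whose argmax sits at index < 2 cannot be
analyzed and is excluded with explicit accounting.

Background is the arithmetic mean of exactly 40,000 pixels ventromedial to
the dLGN. Only the pixel count is fixed by the protocol; the default
placement — a 200 × 200 px square whose top-right corner sits 10 px down-left
of the dLGN bounding box — is this package's convention and is configurable
per section. Subtraction clamps at zero because all later thresholds compare
against non-negative signal.

### Thresholds

The ipsilateral threshold is `Ti = α·Mi` with `Mi` the maximum
background-subtracted signal inside the dLGN masks of five consecutive
sections centred on the largest-area section. The contralateral threshold is
`Tc = β·Mc` with `Mc` the mean of the first 10,000 monocular-segment pixels
in raster order (a deterministic subsample; reproducibility beats random
sampling here). The proportional forms are the package's reading of the
protocol; the coefficients are free parameters with defaults α = 0.3 and
β = 0.5, calibrated on phantoms: across noisy phantoms the
recovery-error-minimizing α sits at 0.30 ± 0.05 (the optimum is a broad
plateau because the Gaussian tails of both false-positive and false-negative
pixel counts fall steeply), and β = 0.5 splits the bimodal
plateau-vs-background intensity distribution at its midpoint. `Mi` is taken
inside the dLGN masks only, since extreme optic-tract pixels outside the
nucleus would corrupt a whole-image maximum. Both threshold comparisons are
strict (`> Ti`, `< Tc`), as is the patch filter (`> 150 px`).

### Digital topology

Foreground (supra-threshold label) uses 8-connectivity, background
(sub-threshold) 4-connectivity — the standard complementary pairing that
avoids paradoxes at diagonal contacts. Both labelings are validated against
a brute-force BFS oracle in the test suite.

The gap is the set of sub-threshold dLGN pixels left after removing
4-connected components that touch the mask contour (the flood-fill
exclusion). A section whose gap itself reaches the contour must be
discarded; since the measurement cannot see intent, the package flags a
section invalid when any contour-connected sub-threshold component
penetrates deeper than `rim_depth` (default 5 px) from the contour — a thin
rim artifact never does, a central hole that has leaked to the boundary
always does on realistic geometries. The depth cutoff is configurable.

### Axis extents

The DM-VL construction sweeps lines parallel to the tip-to-tip chord at
1-px offsets; on each line the patch extent is the distance between the
outermost patch intersections (two endpoints, not a sum of runs), and the
selected line maximizes that extent, with ties broken toward the larger
dLGN chord and then the smaller offset. The O-I construction drops a
perpendicular from the outer boundary through the unweighted centre of mass
of the patch union; the local tangent comes from a least-squares fit over an
11-point arc window (configurable — wide enough to smooth pixelated
boundaries, short enough to stay local). Spans are pixel-quantized
(outermost − innermost + 1), so a k-pixel-wide axis-aligned patch measures
exactly k µm. Whether the centre of mass should be intensity-weighted and
whether disjoint patches should be unioned were open design points; the
package uses binary pixels and the union, consistent with the binarized
processing chain, and exposes the patch set so callers can do otherwise.

### Profiles

The profile strip runs from the dorsomedial tip through the ventrolateral
tip to the last dLGN pixel in that direction, 40 px wide, sampled at 1-px
bins with bilinear interpolation. CTB profiles are normalized by the mean of
the final 200 bins (the monocular segment of the strip); marker
(VGLUT1-style) profiles subtract the no-primary-antibody control mean
(clamped at zero) and divide by the whole-strip mean. Normalization makes
both profiles invariant to global intensity scaling.

### Statistics

Two groups: two-sided F-test on the variances (larger variance on top,
p = min(1, 2·upper tail)); Student's t if p ≥ 0.05, Welch's t (Satterthwaite
df) otherwise. Two zero-variance groups count as equal variances. Three or
more groups: Tukey–Kramer from the studentized range with pooled
within-group variance and unequal-n standard errors; the implementation is
cross-checked against an independent library routine in the tests. All
tests are two-sided. The summary-statistic and raw-value routes agree
exactly by construction (the raw route summarizes and delegates).

## The phantom

The synthetic nucleus is an annular sector: outer radius 240 px, inner
radius 80 px, angular span 1.8 rad, chosen so that (a) the nucleus holds
≈ 46,000 px at the central section — a desk-scale stand-in for the real
organ, a few times smaller in area, with every protocol constant (40,000-px
background region, 10,000-px monocular segment, 200-bin normalization,
150-px patch filter) still satisfiable — and (b) the dorsomedial →
ventrolateral strip, 40 px wide, stays inside the tissue and crosses the
gap. Sections scale linearly by 1 − 0.12·|i − mid|/mid so the area peaks
uniquely at the middle section.

The ipsilateral patch is a centred angular sub-sector over a radial band;
with the band centred at mid-radius the patch area fraction reduces to
ψ·f/φ (ψ patch half-angle, f radial fraction, φ nucleus half-angle), so area
is controlled exactly. Alternatively both axis extents can be targeted
directly: the O-I target fixes the radial band and the DM-VL target is
solved by root finding on the closed-form chord ratio — the widest patch
chord parallel to the tip line passes through the patch's outer corners.
The gap is a circle at mid-radius sized from the target area fraction, with
a feasibility check that it stays strictly interior (≥ 1.5 px clearance);
`valid_gap=False` instead centres it on the outer arc to exercise the
discard rule.

A single fluorescence image cannot be simultaneously a dark nucleus with an
ipsilateral patch and a fully labeled nucleus with a gap, so a spec renders
one `kind` at a time ("ipsi" or "contra") while carrying both parameter
sets.

Intensity is background (default 100) plus a plateau (default 1000) on
foreground, an optional low-order multiplicative bias (default off), and
optional additive Gaussian noise, rounded to integers so that written 16-bit
TIFFs round-trip losslessly. Noise defaults are calibration choices — the
protocol publishes no image-level noise statistics; the recovery suite uses
SD = plateau/10, at which threshold misclassification is a sub-pixel
effect (the thresholds sit ≥ 4 noise SDs from both modes).

Truth records: area fractions are exact mask pixel counts; axis lengths are
the chord constructions evaluated on the noiseless true masks (the
quantities are *defined* by those constructions, so pixel-quantized truth is
the honest reference), with the closed-form geometric targets recorded
alongside and held to within ~1.5 points of the mask truth in tests.

Cohort simulation has two labeled modes. *Endpoint mode* draws per-animal
measured values from Normal(mean, SD) truncated at zero, using the
reference (mean ± SD, n) summaries of the ME/MD/TTX experiments that ship
as presets. *Image-parameter mode* draws each animal's true patch fraction
from its group distribution and renders a full stack per animal, so the
pipeline can be validated end to end; quantification runs blind and group
labels are joined only at the statistics stage.

### What the phantom does and does not emulate

It exercises section selection, background subtraction, both thresholds,
flood-fill gap extraction, the chord geometry and the statistics under
known truth, noise and illumination bias. It does not emulate axon-arbor
texture, partial-volume edges, section-to-section registration error or
non-circular gap shapes, so passing recovery tests demonstrates the
correctness and noise robustness of the measurement chain, not performance
on real histology.

## Numerical choices and degenerate inputs

* Line sampling uses 1-px steps with nearest-pixel lookup (half-to-even
  rounding); the brute-force sweep oracle in the tests uses the same
  convention, so equivalence is exact.
* Rigid-rotation invariance of the axis extents is pixelation-limited;
  tests hold 30° and 90° re-renders to within 1.5 percentage points.
* Degenerate inputs raise distinct exceptions: empty masks, missing
  landmark keys, a zero five-section maximum (no threshold can be formed),
  a monocular segment under 10,000 px, a strip shorter than 200 bins, an
  empty patch set for the axis constructions, and a boundary tangent
  collinear with the radius.
* A chord that misses the patch reports a zero span rather than an error.
* All randomness flows through `numpy.random.default_rng` seeded from
  explicit spec/run seeds; identical seeds give bit-identical images and
  tables.

## Problem sizes

The recovery suite uses 20 phantoms of five 720 × 740 sections each
(fractions drawn U(5, 30)% and U(5, 25)%, noise SD = plateau/10) and the
null simulations use 10,000 replicates; both sizes give stable third-digit
estimates while keeping a full validation run around ten seconds on one
core.

## Known limitations

* The threshold coefficients α and β are conventions calibrated on
  phantoms, not protocol constants; real-data use should sweep them.
* The invalid-gap rule (`rim_depth`) is an operational surrogate for a
  human "gap touches the contour" judgment.
* The DM-VL sweep granularity of 1 px bounds the offset optimum to ±1 px;
  sub-pixel sweeps were not needed at the tested tolerances.
* Boundary delineation, registration and intensity calibration across
  imaging sessions are out of scope; annotations are trusted as given.
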