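# dlgnquant

Quantification of retinogeniculate projection territories in serial coronal
sections of the mouse dorsal lateral geniculate nucleus (dLGN), together with
a synthetic phantom generator that makes the whole pipeline testable against
known ground truth.

After monocular enucleation (ME), monocular deprivation (MD) or intraocular
TTX, the remaining eye's retinal ganglion cell axons — labeled with a
fluorescent tracer such as CTB — can re-expand into dLGN territory they had
vacated during eye-specific segregation. The package implements the standard
section-based readouts of that rearrangement for users analyzing epifluorescence
section stacks (1.00 µm²/px, 50 µm spacing, dLGN boundaries and landmarks
supplied as annotations):

* **Analysis-section selection** — the section 100 µm rostral (two sections)
  of the section with the largest dLGN area.
* **Background subtraction** — the mean of 40,000 pixels ventromedial to the
  dLGN, subtracted and clamped at zero.
* **Ipsilateral territory** — threshold `Ti = α·Mi`, where `Mi` is the maximum
  signal over five consecutive sections centred on the largest-area section
  (α configurable, default 0.3); the supra-threshold area inside the dLGN and
  its percentage of the dLGN area; ipsilateral *patches* = 8-connected
  components larger than 150 px.
* **Contralateral gap** — threshold `Tc = β·Mc`, where `Mc` is the mean of
  10,000 pixels in the ventrolateral monocular segment (β default 0.5);
  sub-threshold regions connected to the dLGN contour are removed by 4-connected
  flood fill, the remainder is the gap; sections whose gap touches the contour
  are flagged invalid.
* **Axis extents** — patch length along the dorsomedial–ventrolateral axis
  (offset sweep of lines parallel to the tip-to-tip chord, maximizing the
  outermost-intersection span) and along the outer–inner axis (chord through
  the patch centre of mass, perpendicular to the outer boundary), each
  normalized by the corresponding dLGN chord: `100·Q₁Q₂/D′V′` and
  `100·P₁P₂/LM` in the field's notation.
* **Intensity profiles** — a 40-px-wide strip from the dorsomedial tip to the
  ventrolateral end, binned at 1 px and normalized by the final 200 bins
  (CTB) or by the whole-strip mean after no-primary-antibody subtraction
  (VGLUT1-style markers).
* **Group statistics** — a two-sided F-test on the group variances gates the
  choice between unpaired Student's and Welch's t-tests; three or more groups
  go through Tukey–Kramer. Summary-statistic variants accept published
  (mean ± SD, n) triplets directly.

Because no imaging data are deposited for this kind of study, the `phantom`
module renders crescent-shaped (annular-sector) nucleus sections with
controllable patch fraction, axis extents, gap fraction, noise and
illumination bias, and attaches exact truth records to every section.

## Worked example

```python
from dlgnquant import GroupSummary, summary_ttest

me = GroupSummary("ME-P10", 22.1, 3.6, 5)       # mean %, SD, n animals
ctl = GroupSummary("control", 10.8, 1.2, 3)
res = summary_ttest(me, ctl)                     # the F-gate picks the test
print(res.test, round(res.statistic, 2), res.df, round(res.pvalue, 4))
```

prints `student 5.12 6 0.0022`: the variances pass the F-test gate, so the
pooled-variance Student's t-test applies, and the ipsilateral CTB-positive
fraction after ME at P10 (22.1 ± 3.6 %, n = 5) is significantly larger than
in controls (10.8 ± 1.2 %, n = 3) at p < 0.01 — a more than two-fold
difference in means.

Recovering phantom ground truth through the full image pipeline:

```python
from dlgnquant import run_phantom_validation

report, summary = run_phantom_validation(seed=0, n_phantoms=5, noise_relative=0.1)
print(summary.to_string(index=False))
```

```
             metric    bias     rmse  max_abs
   gap_fraction_pct 0.00000 0.000000 0.000000
normalized_dmvl_pct 0.00000 0.000000 0.000000
  normalized_oi_pct 0.00000 0.000000 0.000000
 patch_fraction_pct 0.00056 0.001253 0.002802
```

Each phantom draws a true patch fraction from U(5, 30)% and a true gap
fraction from U(5, 25)%, renders a five-section stack with Gaussian noise of
SD = plateau/10, and runs the complete measurement chain; the errors are in
percentage points relative to the exact mask-count truth.

The same operations are available from a shell:

```
dlgnquant render --out stack/ --seed 1 --kind ipsi --patch-fraction 0.2
dlgnquant cohort --preset me_p10_vs_control_fraction --seed 1
dlgnquant phantom-validate --seed 1 --n-phantoms 20 --out validation/
dlgnquant stats --table results.csv --group-col group --value-col value
```

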