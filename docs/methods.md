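# Methods

`neurophen` quantifies cerebellar neurodegeneration and gait impairment
in mouse ataxia models from two kinds of raw data: calbindin/hematoxylin
(H-DAB) stained cerebellum sections, and inked paw-print sequences from
a runway ("inkblot") test.  This note records the models, the parameter
choices, and the design decisions that were genuinely open.

## Stain separation

Brightfield chromogens attenuate light multiplicatively, so per-channel
optical density `OD_c = -log10(I_c / I_max)` is linear in stain
concentration (Beer-Lambert).  A slide stained with hematoxylin (blue,
nuclei) and DAB (brown, calbindin-positive Purkinje somata) is unmixed
per pixel by solving the 3x3 system `OD = c M`, where the rows of `M`
are unit-norm per-channel OD vectors of the pure stains.  The default
`M` is the published Ruifrok-Johansson H-DAB basis — hematoxylin
(0.650, 0.704, 0.286), DAB (0.269, 0.568, 0.778), residual = their
normalized cross product — the de-facto standard used by QuPath and
ImageJ.  Whether a particular study used these defaults or
slide-estimated vectors is generally unknowable from a methods section,
so the matrix is a nine-number configuration entry.  Negative solved
concentrations are clipped to zero and the clipped fraction is reported
per channel; intensities are floored at `I_max * 1e-6` so black pixels
stay finite.  Automatic stain estimation (Macenko/NMF) and cross-slide
color normalization are out of scope.

## Granular-layer segmentation

The granular layer is the nuclei-dense cortical band; the Purkinje
somata line its outer edge.  The layer is isolated from the hematoxylin
channel by the chain

1. white top-hat, disk radius 5 px — keeps the sub-element nuclei
   speckle, cancels flat background and broad shading;
2. Gaussian blur, sigma 90 px, reflective boundaries — pools speckle
   into a smooth band-shaped ridge;
3. Otsu threshold over a 256-bin histogram, foreground strictly above;
4. binary erosion, disk radius 10 px — compensates the size increase
   introduced by the blur;
5. connected components below `min_component_area_px` (default 5000)
   are dropped — the unattended stand-in for interactive review; a QC
   overlay renderer is provided for human inspection.

All sizes are in pixels, deliberately not rescaled by pixel size, and
are recorded verbatim in each mask's provenance.  The erosion radius
quantifies an otherwise qualitative "slight" erosion and is exposed as
configuration.  Otsu's threshold is computed in-package (histogram
cumulants, between-class variance, ties resolved to the mean of tied
bin centers) and is tested against exhaustive search and against
scikit-image; note that for integer images scikit-image bins at exact
integer centers while this implementation histograms over
`(min, max)`, so thresholds can differ by up to one bin width.

## Perimeter and linear density

The measurement track is the layer's *outer* (Purkinje-facing)
boundary.  Boundaries are traced sub-pixel with marching squares at
level 0.5.  Tracing the raw binary mask overestimates smooth-boundary
length by a staircase bias of about +6% on a circle, so the mask is
first smoothed with a small Gaussian (sigma 2 px, configurable, 0 =
exact raw trace); the smoothed trace is accurate to ~0.05% on a
radius-100 px disk.

The outer boundary is selected with a reference point placed on the
Purkinje side (configuration, annotation, or synthetic truth).  Open
contours — the through-going sides of a band clipped by the image
border — are preferred over closed ones, and candidates are ranked by
*minimum* vertex distance to the reference.  Minimum distance agrees
with a mean-distance ranking for parallel band sides but, unlike the
mean, also separates concentric arcs (outer vs. inner edge of a curved
layer), which is the case that actually occurs in cerebellar sections.
Candidates within a 2 px score tolerance raise an ambiguity error
rather than guessing.

The length statistic is `measured = polyline - chord`: the polyline
length of the selected boundary minus the straight-line distance
between its endpoints, in mm.  Endpoints are where the boundary meets
the image border; for fully interior closed boundaries the maximal-
Euclidean-separation (diameter) pair is used, overridable by explicit
annotation.  Multi-lobule sections contribute per-component measures
that are summed; components smaller than the smoothing scale contribute
zero.  Linear Purkinje density is then `manual cell count / measured
length` (cells/mm).  A `full` boundary mode (total region perimeter
before chord subtraction) is available behind a switch because the
choice between the two readings cannot be settled from a typical
methods description; the Purkinje-facing edge is the default.

## Gait geometry

From labeled prints (paw in {LF, RF, LH, RH}, step index, center in
mm, print-axis angle), averaged over up to four steps:

* **midline** — total-least-squares line through left/right pair
  midpoints (paired by nearest step index), directed toward increasing
  step index.  Midpoints of a left/right pair lie on the true midline
  identically, so the estimate is exact for noise-free input even when
  front and hind stance widths differ; a TLS fit through *all* print
  centers is provably tilted in that case (the half-stride stagger
  couples with the width difference), which is why midpoints are used.
* **stride length** — mean distance between consecutive same-paw
  centers.
* **stance width** — mean left/right separation per girdle, measured
  perpendicular to the midline (raw Euclidean pairing available behind
  a flag); perpendicular projection keeps the width honest for
  staggered alternating gaits.
* **paw angle** — signed rotation of the print axis relative to the
  midline; positive means rotated away from the midline (out-toeing)
  on either body side.  The sign convention is this package's
  declaration, not an attribution.
* **stride angle** — unsigned angle between the midline and the
  segment from each hind print to the opposite-side front print of the
  same cycle (LH-RF, RH-LF).

All four metrics are invariant under rigid motions of the print set
and exact on noise-free synthetic input.  Fewer than four available
steps are accepted with `n_steps_used` recorded.

## Group statistics

Two-tailed Student's t with pooled variance (`df = n1 + n2 - 2`) or
Welch's t (Welch-Satterthwaite df) — the variant is an explicit flag,
never an automatic F-test gate, because reported analyses of this kind
state the assumption rather than a selection rule.  One-way ANOVA
(`F = MS_between / MS_within`); for two groups `F = t^2` exactly, which
is used as a cross-check.  Bonferroni: `p_adj = min(1, m p)`, reject at
raw `p <= alpha / m`.  Degenerate inputs (zero variance everywhere with
equal means; all-identical ANOVA values) return statistic 0 and p = 1
with an explanatory note instead of NaN.  Nerve-fiber counts are
summarized section -> sample mean -> group mean +/- sample SD, with a
normal-quantile diagnostic table (not a test) for judging normality.
Heterozygous animals are carried through summaries but excluded from
two-group WT-vs-KO comparisons unless requested.  For the cohort ANOVA
both a one-way genotype analysis per age and a genotype x age layout
can be assembled from the same records; neither is presented as
canonical.

## Synthetic ground truth

The generator exists so every stage can be validated analytically.

**Cerebellum scenes.**  A granular band is rendered as a dense speckle
of small nuclei (disk radius 2 px, ~30% areal coverage, hematoxylin OD
0.8) restricted to the band, with DAB somata (radius 14 px, OD 1.0,
spacing 0.04 mm) tangent to the band's outer edge.  Pixel
transmittance is composed exactly as `10^(-c M)` on a white background,
so deconvolution with the generating matrix recovers the concentration
fields to numerical precision; optional Gaussian noise is added in OD
space and transmittance clipped to [0, 1].  Truth arc length is
computed by dense-polyline quadrature of the offset curve (tested
against closed forms to 1e-6).  One integer seed governs all draws;
identical parameters and seed give bit-identical scenes.

The default scene is a *semicircular* band: a half-annulus (centerline
radius 600 px, varied 480-640 px across cohorts; halfwidth 180 px;
pixel size 0.0007 mm/px, a ~20x-scan scale) whose circle center lies
exactly on the bottom image border row.  Two properties motivate this
geometry.  First, the halfwidth is ~2x the blur sigma, which places the
blurred cross-profile's half-maximum at the true band edge, so
threshold plus erosion give a small, predictable offset.  Second, the
band meets the border perpendicularly and its mirror image across the
border completes the annulus, so the reflective blur padding sees a
continuous band: the border contact is artifact-free and the outer
boundary's endpoints are well defined on the border.  (A near-complete
annulus with a shallow border clip was evaluated and rejected: there
the band grazes the border, reflect-padding smears stain mass along
it, and the measured length biases by tens of percent.)  With this
geometry the full pipeline recovers linear density with a median
absolute error well under 2% and every scene within 10% at zero noise.

What the scenes do *not* emulate: folial branching, tissue texture,
stain variability across slides, tears and artifacts, or chord/length
ratios of real sections.  Passing the synthetic recovery criteria
demonstrates the computational chain is correct and stable, not that
the printed filter sizes are optimal for any particular scanner
resolution.

**Footprints.**  Step cycles place LH at `(iL, +w_h/2)`, RH staggered
half a stride, and front paws offset longitudinally by
`(w_f + w_h) / (2 tan(stride angle))`, so the requested stride angle is
realized exactly and all four metrics are exactly recoverable at zero
noise.  Placement noise is i.i.d. Gaussian on print centers.  Defaults
(stride 65 mm, front/hind stance 20/28 mm, paw angle 8 deg, stride
angle 35 deg, four steps) approximate a healthy adult laboratory mouse
on a runway.

**Cohorts.**  Gaussian linear densities per group, reproducible by
seed; `sd = 0` returns the group means exactly.

## Numerical choices and edge cases

* Scene coordinates are row-major with origin top-left and y down; all
  truth geometry is stored in mm and converted through the pixel size.
* Erosion treats out-of-image pixels as foreground, so masks recede
  only from interior boundaries, not from the image border.
* A constant image has no Otsu threshold (degenerate histogram) and is
  rejected; an empty post-filter mask raises "no layer found".
* `measured = polyline - chord` is non-negative by the triangle
  inequality; the implementation clamps at exactly 0 against rounding.
* Rounded-kb interval lengths use half-away-from-zero rounding.
* Problem sizes used by the validation suite — 50 scenes for density
  recovery, 200 images for the Otsu oracle, 500 seeds for the stride
  Monte-Carlo, 2000 replicates for t-test calibration, 1000 for the
  Bonferroni family-wise error — were chosen to give comfortable
  Monte-Carlo margins for the stated tolerances on a single CPU.

## Known limitations

* The pixel-unit filter sizes (5/90/10) are faithful to common
  practice but only meaningful at a matching scan resolution; no
  physical-unit rescaling is attempted.
* The chord-subtracted length of a nearly straight layer approaches
  zero, making density ill-conditioned there; the statistic is suited
  to curved layers (as in cerebellar sections).
* Boundary-side selection needs a usable reference point; symmetric
  degenerate cases raise an ambiguity error by design.
* Group statistics assume independent sections/animals; repeated
  measures and mixed effects are out of scope.
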