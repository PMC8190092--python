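# Methods

## Scope and design

The package quantifies thylakoid membrane biogenesis in rod-shaped
cyanobacteria from three kinds of evidence: the spatial arrangement of
membrane layers in thin sections, the distribution of labelled
photosynthetic complexes along the cell periphery in fluorescence images,
and bulk measurements (protein abundances, band intensities, pigment
photometry, 77 K spectra).  Because the original micrographs are not
redistributable, the pipeline is driven by a synthetic-scene generator that
emulates the statistical structure those analyses assume, with complete
ground truth; every analysis consumes only the rendered images, never the
ground truth, which is used solely to score recovery.

## Cell model and arc convention

A cell is a 2-D spherocylinder (capsule): a rectangle of length L − W and
width W capped by two semicircles of radius W/2, with L ≥ W > 0 and
orientation normalized to [0, 180)°.  Defaults: L = 3.0 µm ± 10% and
W = 1.0 µm ± 5% uniform jitter per cell, uniform random orientation.

All modules share one arc coordinate: normalized arc length t ∈ [0, 1)
measured counterclockwise (positive shoelace in (x, y) pixel coordinates)
from the midpoint of longitudinal side L1.  Side L1 is fixed geometrically —
after rotating the major axis horizontal, it is the side with smaller y.
The traversal from the anchor meets: second half of L1, pole P1, side L2,
pole P2, first half of L1.  For L = 3, W = 1 µm the perimeter is
2(L − W) + πW = 7.1416 µm, each pole occupies a fraction 0.2199 and each
side 0.2800 of it.  Which physical side becomes L1 is arbitrary (the imaged
cells carry no intrinsic label), so the side-asymmetry statistic is defined
order-free (brighter/dimmer); the convention only pins reproducibility.

## Thylakoid shells and condition presets

Thylakoid membranes are concentric parallel outlines offset inward from the
plasma membrane; a shell at offset d is itself a spherocylinder with
L − 2d, W − 2d.  Shells are listed per longitudinal side; an entry spans
`arc_extent` of that side's half-outline centred on the side midpoint, so
two full entries at the same offset compose a continuous ring and
`arc_extent` < 1 is a membrane fragment.

Presets encode the light conditions studied:

| preset | side 1 | side 2 | inter-layer spacing |
|---|---|---|---|
| GL | 3 full layers | 3 full layers | 78.4 nm |
| HL | fragment (extent 0.35) + 1 full layer | 1 full layer | 109.2 nm |
| LL1 | 2 layers (outer extent 0.8) | 1 layer | 110.6 nm |
| LL2 | 2 full + 1 half layer | 2 full layers | 95 nm |
| LL3–LL5 | 3 full layers | 3 full layers | 85 / 80 / 78.4 nm |

The GL/HL/LL1 spacings are the measured group means for those conditions;
the LL2–LL5 values are invented interpolations toward the growth-light
phenotype (only qualitative descriptions exist past the first low-light
day).  The distance from the plasma membrane to the first thylakoid layer
is not reported anywhere; the default of 40 nm reflects fragments described
as "close to the plasma membrane" and thin-section appearance.  Layer
*spacings*, the quantity the pipeline measures, are independent of this
choice.

## Protein point distribution

Each of `n_points` complexes gets an arc position drawn from a mixture:
with probability κ/(1 + κ) from one of `n_clusters` wrapped-Gaussian
clusters (σ = 0.03 of the perimeter, centres uniform per scene), otherwise
uniform; κ = 0 is exactly uniform.  Region weighting is applied by
rejection: side 1 density × a (`side_asymmetry`), side 2 × 1, caps ×
`polar_enrichment`.  Points are then attached to a shell on their half of
the outline whose drawn arc covers them (plasma membrane as fallback), and
rendered at the shell's own outline position.

Defaults: n_points = 2000 (a realistic order of magnitude for tagged
photosystem complexes per cell — actual copy numbers are in the thousands
to tens of thousands), amplitude 120 counts/point.  The clustering and
asymmetry magnitudes are placeholders: the source observations are
qualitative ("more clustered", "higher degree of asymmetrical
distribution"), so κ ∈ {0, 2, 8} and a ∈ {1, 2} are sweep levels, not
calibrated biology.

## Rendering and noise

Fluorescence (30 nm/px, PSF σ = 80 nm by default, an SRRF-like resolution):
GFP = point amplitudes bilinearly splatted; Chl = shell arcs at uniform
line density (800 counts per pixel of arc).  Both are Gaussian-blurred with
constant (zero) padding — blur redistributes intensity and light leaving
the grid is lost, never reflected — then background (5), Poisson shot noise
(gain 1), and Gaussian read noise (σ = 2) are applied in that fixed order.
The order is a modelling choice; with all gains at 0 the render is exact
and total GFP intensity equals the summed point amplitudes to < 1% (the
grid always includes a 3σ PSF margin, enforced).

TEM-like (5 nm/px): exterior 210, cytoplasm 160, membranes (plasma
membrane always, plus shells) as dark lines of density 500 counts/px,
blurred by the combined membrane-width/PSF σ = √(8² + 3²) nm, then Poisson
and Gaussian (σ = 4) noise.  Membranes are intensity *minima* (stained
dark); a polarity flag in the detector supports inverted contrast.

Determinism: one seeded generator per scene for sampling; renderers derive
independent child streams from the scene seed, so identical (parameters,
seed) give bitwise-identical scenes and images.

## Segmentation and outline

Cells are connected components above the Otsu threshold of the Chl channel
(or below it, for inverted TEM-like contrast), morphologically closed
(disk radius 2), hole-filled and area-filtered; border-touching components
are flagged and excluded by default.  Whether the original tracing used
the GFP or Chl channel is unstated; Chl (the membrane marker) is the
default and the channel is configurable.

The rod fit takes orientation from second-order moments, length from the
pixel extent along the major axis (+1 px for pixel width), and width from
the area-preserving root of A = (L − W)W + π(W/2)²; on exact rasterized
capsules it recovers orientation within 1–2° and L, W within one pixel.

The outline is marching squares at the 0.5 level of the σ = 1 px smoothed
mask, checked simple (shapely), forced counterclockwise, and rolled so
vertex 0 is nearest the L1 midpoint of the fitted rod.  Cumulative vertex
arc length equals the polygon segment sum exactly.

## Periphery profiles and statistics

The profile samples N = 360 equally spaced arc positions (positions k/N
from the anchor); each value is the mean of bilinearly interpolated
intensities over a ±1 px band along the local normal (band 0 = pure line
tracing; N and band are configurable).  N is fixed across cells because
patchiness = SD/Σ scales as 1/N — profiles are only comparable at equal
sampling density.  The "total" in the denominator is the sum of the N
samples, per the literal description of the source method; dividing by the
mean instead is available as an option.  Side asymmetry takes the maxima
over the region-labelled profile samples (not raw pixels), brighter over
dimmer.  Colocalization is plain Pearson correlation over in-mask pixels,
without Costes thresholding; Manders split coefficients (thresholds 0) are
offered as extras.  Group comparison uses the pooled two-sample t-test —
the classical default reading of "two-sample t-Test" — with a Welch flag.

Recovered values are biased estimators: the max of a noisy profile
over-estimates, proportionally more on the dimmer side, so the mean
recovered ratio for a true side ratio of 2 sits near 1.7–1.8 at 2000
points/cell and noise defaults (it approaches 2 as point counts rise).
The acceptance band [1.7, 2.3] reflects this known finite-sampling bias.

## Transects, peaks, spacings

The mid-cell transect samples the line through the fitted centroid
perpendicular to the major axis (span = width + 60 nm margin each side,
averaged over 5 parallel lines 1 px apart).  Membranes are minima with
prominence ≥ 20% of the transect dynamic range and separation ≥ 20 nm
(both configurable, invented defaults), refined by three-point parabolic
interpolation (clamped to ±0.5 px).  The outermost minimum on each side
within 25 nm of W/2 is the plasma membrane and is removed before counting;
a side without one is flagged but still counted.  Spacings are distances
between adjacent detected membranes on the same side — the measurement
line is not defined in the source, and the mid-cell perpendicular transect
is chosen for determinism, where concentric layers run parallel to the
straight sides so offsets are read directly.  Whether the reported n = 50
distances were one per cell or pooled is unstated; the pipeline reports
pooled distances and keeps per-cell records.

## Trajectories, ratios, photometry

Abundances are divided per protein by the reference-condition (GL)
replicate mean; zero-reference proteins are dropped with a report.  Fits
are ordinary least squares quartics over the condition coding 0..6, on
condition means by default ("values are represented as means"; a flag fits
replicates) — one stated reason printed adjusted-R² lists may not reproduce
exactly.  Adjusted R² counts p = degree parameters excluding the intercept.
The published per-protein adjusted-R² values require the original
supplementary abundance table and its (unstated) fit conventions; the
recipe is implemented and exercised on a synthetic stand-in, but those
printed values are documented targets, not tested ones.

Photometry implements the printed formulas directly: 12.7 × OD₆₆₅ for the
methanol extract (units carried symbolically as "extract units per OD");
A_Chl678 = 1.0162 A₆₇₈ − 0.0630 A₆₂₅ and c = A_Chl678/(68 · path) for whole
cells, with negative corrected absorbance flagged rather than raised and
an optional (off by default) 750 nm turbidity pre-subtraction — the
published formula is taken to expect raw readings, with turbidity
normalization treated as presentation.  77 K spectra are background-
subtracted (constant, or the in-range minimum) and divided by the maximum
within ±10 nm of the mode's anchor (720 nm for 435 nm excitation, 655 nm
for 600 nm); the window half-width is invented around the approximate
("~") peak positions.

## Problem sizes and limitations

The simulated studies use 50 cells per condition for thin-section spacing
and 30 cells per cohort for fluorescence statistics — the same cohort sizes
as the emulated experiments — at 5 nm/px (TEM-like) and 30 nm/px
(fluorescence); a full acceptance run covers ~250 rendered cells.

What passing tests show is that the *quantification* recovers known ground
truth under the stated forward model.  The generator does not emulate:
3-D sectioning or optical sectioning (scenes are 2-D projections), membrane
convergence zones, perforations, or tubular structures near the plasma
membrane; dividing cells or cell crowding; depth-dependent PSF or detector
artefacts beyond Poisson + Gaussian noise; spectral bleed-through.  The
absolute spacings and layer counts are properties of the emulated
conditions, not new measurements of real micrographs.
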