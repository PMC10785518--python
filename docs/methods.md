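# Methods

This note records the models, numerical conventions and design choices
behind the package, in the spirit of a statistical-software methods
appendix. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Coordinate and grid conventions

All volumes live on regular, axis-aligned voxel grids in patient LPS
coordinates: +x patient-left, +y posterior, +z superior, distances in
mm. Indices are 0-based, voxel positions refer to voxel centers, and
axial slice *k* means all voxels with third index *k*. Two geometries
are equal when shape matches and spacing/origin agree within 1e-6 mm.
Masks and dose grids must share a geometry before any metric or DVH
computation; resampling (`dosimetry.resample_dose`, trilinear, 0 Gy
outside the source extent with a warning) is always an explicit step,
because silent resampling hides interpolation error. Oblique or rotated
grids are rejected at the I/O layer.

## Geometric agreement metrics

The surface of a mask is the set of centers of its voxels with at least
one face-adjacent (6-connectivity) neighbour that is background or
outside the grid. All surface distances are Euclidean point-to-point
distances between voxel centers with anisotropic spacing respected; no
sub-voxel mesh is constructed. This is the simplest convention that an
independent all-pairs computation can verify bit-for-bit, which the
test suite does on ≤24³ grids to 1e-9 mm.

* **DSC** is computed by voxel counting.
* **ASD** pools the two directed nearest-neighbour distance sums and
  divides by the total surface-point count (surface-count-weighted
  symmetrization), the common "average symmetric surface distance".
* **HD95** is the maximum of the two directed 95th percentiles, with
  the percentile linearly interpolated over the sorted directed
  distances — the most widespread convention.
* **Centroid deviation** is the Euclidean distance between the two
  unweighted means of true-voxel centers. Slice-area weighting was
  considered and rejected: the unweighted mean is the literal centroid
  of the voxel set and is exactly recovered under rigid translation.

Empty inputs raise errors rather than returning 0 or NaN, because
sentinel values silently corrupt mean ± SD summaries downstream.

## Anatomical subdivision

The nodal CTV is cut into four z-bands by the femoral-head, piriformis
and iliac-bifurcation planes, numbered inferior→superior (N1 caudal).
N1 splits left/right at the midline; N2 and N3 split into quadrants
(left/right × up/down); N4 stays whole — 11 parts. Three genuinely open
conventions were fixed as follows:

* the N2/N3 "up/down" cut is a transverse (axial) plane; an
  anterior/posterior variant is available via `quadrant_axis="y"`;
* the cut sits at the midpoint of that band's *occupied* z-extent (not
  the midpoint between landmark planes), so the split adapts to where
  the structure actually lies;
* ties are half-open and deterministic: a voxel center exactly on a
  boundary plane joins the superior band, exactly on the midline joins
  the patient-right side.

The longitudinal halving of the vaginal/cervical targets uses the same
occupied-extent midpoint and the same at-or-above-goes-up rule, which
gives a 10/11 split for 21 occupied slices. Both operations return
verified exact partitions (disjoint, union equals source), enforced at
construction of every `SubregionSet`.

Margin expansion (CTV→PTV, 5 mm default, 10 mm for the uterus) marks
every voxel whose center lies within the margin of a source voxel
center, via an exact Euclidean distance transform with the grid
spacing; erosion is its complement-dilate-complement dual.

## Edit-magnitude rubric

The four-level grading (no / minor / moderate / major) follows the
slice-fraction rule: *no* if nothing changed; *minor* if no slice needs
a big change and at most 10 % need small changes; *moderate* if more
than 10 % need small changes (no big ones) or at most 10 % need big
changes; *major* otherwise. The clinical "small vs big" slice judgment
is a physician call; the package substitutes a transparent surrogate —
a changed slice is small when its 2D Dice ≥ 0.90 **and** its 2D
Hausdorff ≤ 3 mm, both configurable — and a slice present in only one
mask is always big. The denominator is the count of slices occupied in
either mask. The residual ("major") class absorbs every case beyond the
moderate bounds, including deletions and recontours. The grading is
provably monotone: worsening any single slice never lowers the label.

## Dose-volume metrics

A pure voxel-count model: VxGy counts in-mask voxels with dose ≥ x
(voxels exactly at threshold are covered), in percent of mask volume or
absolute cm³; Dq sorts in-mask doses descending and reads the value at
rank ⌈q·N⌉ (q as a voxel count from percent or cm³), so D100 % is the
minimum in-mask dose and small-q limits approach the maximum. No
partial-volume weighting is applied; differences from a treatment
planning system's interpolated DVHs are expected at the one-voxel
quantization level and are documented rather than hidden. V100 % uses
the plan's prescription as threshold. Mean doses are reported in
absolute Gy; any normalization (e.g. per-fraction scaling) is left to
the reporting layer.

## Paired statistics

Plan contrasts use a two-sided paired t-test on per-fraction
differences, treating each fraction as an independent observation (the
analysis convention this mirrors; within-patient correlation across
25–28 fractions is a known limitation, and case IDs are retained so a
clustered analysis could be added). Summaries are mean ± sample-SD
(n−1). If all paired differences are exactly zero the test is flagged
undefined, never reported as p = 0 or 1. p-values below 0.05 render as
"< 0.05", otherwise "= value" at two decimals. No multiple-testing
correction is applied. Type-I calibration at nominal α = 0.05 is
verified by simulation in the test suite (1000 seeded null replicates,
n = 20, binomial 99 % acceptance band).

## Synthetic phantom and cohort model

The phantom places bilateral nodal tubes spanning all four landmark
bands, midline uterus/cervix (or vagina) targets, influencer organs and
secondary OARs as fractions of the grid extent, so one recipe scales
across grid sizes. The default production grid is 128×128×80 at
2×2×3 mm; tests and the acceptance script use 64×64×48 at 3 mm
isotropic, chosen so cohort-scale runs complete in seconds while all 11
nodal subregions stay populated. All structures are pairwise disjoint
and interior to the grid by construction, validated at build time.

Auto-vs-manual contour differences are emulated by deforming the
phantom with a known spec: grid-snapped rigid translation, uniform
margin change, then smooth per-slice boundary jitter (seeded Gaussian
noise filtered across slices, applied as per-slice 2D dilation/erosion
in mm). Defaults encode the qualitative anatomy of the problem: the
uterus moves most (translation σ = 6 mm per axis — its fundus can shift
by centimetres between fractions), vaginal/cervical targets deform
moderately with amplitude ramping toward their superior end (ramp ×3,
reflecting the mobile vaginal cuff), nodal chains are nearly stable
(σ = 0.8 mm), and influencer organs change both position (σ = 3 mm) and
filling (margin σ = 1.5 mm). These are generator conditions, not fitted
values; the tests assert orderings and recovery of *injected* truth,
never published patient statistics.

The synthetic dose is 1.05 × prescription × logistic(depth/falloff + 3),
with depth the signed Euclidean distance to the target surface. The
5 % interior plateau above prescription plus the +3 offset put the
target surface at roughly the prescription, so small falloffs give
≥95 % V100 on the generating target; a capped logistic could never
reach the prescription under the ≥-threshold convention. Per fraction,
the S-Adapted field conforms to the day's (manual) PTV while the
scheduled and automatic plan surrogates conform to the reference PTV,
which coincides with the automatic contours in this phantom; each plan
receives an independent ~1 % output-factor perturbation so no two plans
are numerically identical and paired tests stay defined. This
reproduces the expected qualitative ordering (adapted ≥ scheduled
coverage on the day's anatomy) but deliberately does not model
optimizer trade-offs, beam geometry or heterogeneity corrections.

What passing tests on this phantom do **not** show: performance on real
iCBCT anatomy. The generator produces idealized smooth shapes, rigid
OARs beyond the influencers, no image noise, no true deformable motion,
and dose fields without optimizer structure. It validates the
*measurement machinery* — metrics, subdivision, DVH, statistics — and
the pipeline's ability to recover known deformations, not clinical
contouring accuracy.

## Determinism and numerical details

Every stochastic component draws from `numpy.random.Generator` seeded
through `SeedSequence` spawning, so cohorts, jitter and plan noise are
bit-reproducible for a fixed seed. Distance-transform thresholds carry
a 1e-9 mm guard against floating-point ties; geometry comparisons use
1e-6 mm. Degenerate inputs (empty masks, both-empty metric pairs,
zero-variance paired tests, q = 0 volumes) raise typed errors or are
flagged, never coerced to numbers.
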