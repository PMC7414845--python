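# Methods

This note records the models implemented by `paleocanid`, the choices
made where the design was genuinely open, and what the synthetic data do
and do not establish about behaviour on real material.

## Biometry

Each measurement `x` (mm, von den Driesch measurement codes) is compared
with the homologous measurement of a designated standard skeleton via
`d = log10(x / x_std)` (base-10 by the log-ratio-diagram convention of
the zooarchaeological literature). `d` is scale-equivariant: multiplying
all values and the standard by the same constant leaves it unchanged,
and a population generated by scaling the standard by a factor `f` with
no noise recovers `mean d = log10 f` exactly. Rows flagged `reworked`,
`burnt` or `unmeasurable` are removed before analysis with a per-row
report; missing measurements are omitted, never imputed. Both
specimen-level profiles and per-(population, code) summaries are
provided, since log-ratio diagrams are drawn both ways.

## MicroCT tissue analyses

**Coordinates.** Volumes are `(z, y, x)` index grids with isotropic
voxels; physical positions are `index × voxel_mm`. A `Plane` is
`n·x = offset` with unit normal and the occlusal/proximal side positive.

**Segmentation** is multi-level Otsu thresholding with the thresholds
reported and overridable — the "semi-automatic" contract: the default is
reproducible, manual assistance is expressed as explicit threshold
overrides. A volume whose histogram has fewer distinct intensities than
classes (or zero range) is rejected by name of the offending statistic.

**Cervix plane.** The cervix ring is extracted as enamel surface voxels
within two voxels (26-connectivity) of dentine surface voxels — the line
where enamel, dentine and background meet — and the plane is a
total-least-squares fit (smallest singular vector), oriented toward the
occlusal side.

**Crown slice.** Cross-section 2 is operationalised as the lowest
cervix-parallel level at which the occlusal enamel splits into exactly
two sizable 26-connected components (the two cusps separating); this
turns a geometric description into a testable rule. Cross-section 1 is
found on a cervix-parallel top-height map as the minimum along the
segment joining the two cusp apices — the bottom of the occlusal valley.
Components smaller than `min_component` voxels (default 20) are ignored
as specks. The percent of crown dentine is
`100 · V_dentine / (V_dentine + V_enamel)` inside the slice; pulp or
void space inside the slice is deliberately excluded from `Vc`, which
names dentine + enamel only. On phantoms the extracted levels land
within ~1 voxel of the generating geometry, and the computation is
exactly invariant to axis relabelling (90° rotations) and voxel-size
rescaling.

**Wear screen.** Above cross-section 2, a tooth is flagged worn when a
contiguous patch (≥ `min_region` surface columns) exposes dentine at the
occlusal surface, or when a contiguous patch of occlusal enamel is
thinner than `thin_frac` (default 0.5) of the median occlusal thickness.
Thickness statistics are taken on interior columns well above the
separation level, because the cap's own edge is legitimately thin.
Severity is 1 minus the thinnest-to-median thickness ratio.

**Broken-cervix reconstruction.** The preserved cervix ring of the
target is aligned to each intact reference ring by an ICP similarity
transform (nearest-neighbour correspondences, closed-form
rotation+scale+translation per iteration). The reference's fitted
cervix plane is pulled back through the inverse transform, giving the
target an orientation borrowed from the reference, from which the slice
and dentine percent are computed — one estimate per reference. An
alignment whose residual exceeds 10 voxels is rejected as disjoint.

**BV/TV.** BV is the bone voxels proximal to the separation plane; TV is
the volume inside the outer bone envelope on that side. The envelope is
the bone labels with all enclosed cavities filled (so marrow voids count
toward TV). A morphological closing before filling is available
(`closing_frac`, ball radius as a fraction of bone extent) for specimens
whose voids open through the cortex, but it is off by default: discrete
ball closing inflates a convex envelope by a sub-voxel crust (~3–4% of
TV on the phantoms), whereas hole filling alone is exact whenever the
cortex encloses the voids. The maturity call compares BV/TV with a
configurable threshold whose default (0.65) is the midpoint of the
default young (0.5 porosity → BV/TV 0.5) and adult (0.2 → 0.8) phantom
conditions; no published numeric cut-off exists for this comparison.

**Group comparison** uses the two-sided Mann–Whitney U test: exact
distribution for combined n ≤ 25 without ties, tie-corrected normal
approximation otherwise.

## Outline geometric morphometrics

Outlines are closed 2D point sequences with two homologous anchor
landmarks. Orientation is normalised to counter-clockwise traversal
starting at anchor 1; an outline whose traversal is clockwise is treated
as a mirrored (right-side) specimen and reflected across the x axis,
which maps left and right teeth onto one convention. Curve 1 (anchor 1 →
anchor 2) receives 80 semilandmarks and curve 2 the remaining 60, each
equally spaced by arc length exclusive of the anchors — 142 points in
total.

**Sliding** moves semilandmarks along their local tangents (anchors
fixed) to minimise, per specimen, either the thin-plate-spline bending
energy of the deformation from the Procrustes consensus (default — the
cited semilandmark tradition) or the plain Procrustes distance. Each
iteration re-runs GPA, re-estimates the consensus, and solves the
linearised tangent problem in closed form. The recorded total objective
is non-increasing by construction: an iteration that would increase it
(possible because the tangent step is a linearisation) is reverted and
the procedure stops.

**GPA** centres each configuration, scales it to unit centroid size
(full Procrustes; size is carried separately as centroid size), and
iterates optimal rotations against a re-normalised mean until the mean
changes by less than 1e-10 RMS. Rotations come from the SVD of the
cross-covariance with a determinant correction so reflections are never
introduced.

**bgPCA** is the PCA of the group mean shapes with groups weighted
equally, giving at most g−1 between-group axes; all individuals,
training and a-posteriori unknowns alike, are projected onto those axes
and unknowns never influence the means. Principal axes of the pooled
within-group residuals (orthogonal to the between-group axes) can be
appended and are flagged as residual axes, since a two-group design
yields only one between-group axis and any second ordination axis must
come from somewhere else; the package exposes the flag rather than
guessing a convention.

**Allometry** regresses each axis score on log centroid size (per-axis
OLS with the standard F test). A caveat found during validation: when a
strong group contrast uncorrelated with size is present, the pooled
regression residuals are a two-group mixture and the F test becomes
mildly liberal (empirically ~0.07 at α = 0.05 under the default
contrast). Under the contrast-free isometric null the measured type-I
rate is 0.054 over 3,000 replicates. Group-mean-centred regression would
remove the mixture but changes the question; the pooled regression is
kept and the caveat documented.

**Assignment** is descriptive, not a classifier: nearest group mean in
between-group score space, a typicality per group (fraction of that
group's training specimens at least as far from their own mean), and an
overlap flag when the query lies inside more than one group's 95%
distance hull.

## Ancient-DNA summaries

Reads are stored as sequenced (reverse-strand reads are the reverse
complement of the reference segment), so terminal damage positions refer
to the molecule's own 5'/3' ends. The damage profile counts, at position
i from the 5' end, reads with reference C and read T over reads with
reference C (and mirrored G→A from the 3' end); positions without
opportunities are NaN, and 5-position terminal window means are also
reported because published figures sometimes quote windows rather than
position 1. Fragment-length statistics use the n−1 convention (SD of a
single read is NaN). Mean coverage is averaged over *all* reference
positions including zero-depth ones — a documented choice where usage in
the literature is ambiguous. Mapping, quality filtering and consensus
calling are out of scope; the module summarises a given alignment.

## Radiocarbon

Replicates are combined by the inverse-variance weighted mean with
combined error `(Σ wᵢ)^(−1/2)` and a chi-square consistency test
(df = n−1); failing the test warns but does not block the combination.
Calibration interpolates the curve linearly in μ and s to 1-yr steps
(IntCal grids are 5–20 yr and HPD endpoints need finer support),
evaluates `exp(−(y−μ(t))²/2(σ²+s(t)²))`, and normalises. HPD ranges are
density-ranked (smallest set reaching the requested mass, default
0.954), merged into contiguous runs, reported older-bound first, with no
endpoint rounding — rounding conventions differ between software and are
left to the caller. On an identity curve with s = 0 the 95.4% range
reproduces the normal ±1.996σ interval to one grid step, and on
synthetic wiggly curves the 95.4% HPD covers the true calendar age at
0.95 ± 0.02 over 1,000 simulated dates.

## Synthetic data: what it emulates, and what it does not

* **Outlines** are truncated Fourier perturbations of a polar base
  profile with two Gaussian cusp bulges; positive radius guarantees a
  simple closed curve. The group contrast is a fixed unit pattern on
  harmonics 2–4; a scalar `group_offset` is the *norm* of the contrast,
  and the default 0.12 equals three times the expected within-individual
  deviation norm (`within_sd · sqrt(2·n_fourier)` = 0.04) — the
  "contrast three times the noise" condition is stated in shape space,
  where it is testable, not per coefficient. Within- and between-group
  variance magnitudes are otherwise unreported for the real material;
  the defaults reproduce the qualitative overlap pattern of the
  ordination (distinct but adjacent clouds), nothing finer.
* **Allometry** enters as a size-proportional shift along the same
  harmonic pattern. The slope constant targeting R² ≈ 0.27 on bgPC1 at
  n = 44 (`ALLOMETRY_SLOPE_R2_027` = 0.233) was derived from the
  variance budget and calibrated once by simulation, because the
  coefficient-to-shape-space projection shrinks the residual variance
  below its coefficient-space value.
* **Tooth phantoms** are height-field solids over an elliptical
  footprint: two Gaussian cusps joined by a buccal crest, so the fossa
  floor (on the inter-apex segment) lies genuinely below the
  cusp-separation level (the crest's pass), as in a real carnassial
  where the shearing crest connects the cusps buccally. Enamel is the
  shell of tooth voxels within the nominal thickness of the outer
  surface above the cervix plane (Euclidean distance transform), wear is
  a planar truncation, and the cervix break removes the lowest-x
  fraction of the ring with the surrounding wall. Ground-truth slice
  levels are computed from the analytic height field (the separation
  level by bisection on connectivity). No imaging physics — noise is
  i.i.d. Gaussian per tissue; beam hardening and ring artifacts are
  absent, so segmentation accuracy on phantoms (>99.9%) is an upper
  bound, not a field estimate.
* **Epiphysis phantoms** are ellipsoids with a solid cortical shell over
  a trabecular interior made porous by thresholding smoothed Gaussian
  noise at the quantile that sets the void fraction of the whole
  envelope to `porosity` — hence BV/TV = 1 − porosity exactly, with the
  separation plane tangent to the distal edge of the epiphysis.
  Real trabecular architecture (connected struts, anisotropy) is not
  modelled.
* **Reads** have lognormal lengths (moment-matched to mean 57.6 bp,
  SD 15 bp; right-skewed like real ancient-DNA length distributions),
  with fragments under 30 bp discarded and redrawn. Deamination applies
  C→T at the 5' end and G→A at the 3' end with probability
  `rate · exp(−λ·position)` (λ = 0.3/position) — the canonical
  damage-profile shape the estimator must recover. Sequencing error,
  quality scores and mapping artifacts are absent.
* **Calibration curves** are affine trends plus two sinusoidal wiggle
  harmonics, with the amplitude capped analytically so the cal→14C
  mapping stays strictly monotone. Real curves have plateaus and
  reversals that synthetic monotone curves do not reproduce; the
  coverage property holds on both.

Passing tests on these generators demonstrates that the estimators
recover known structure under the stated statistical assumptions; they
do not certify performance under real imaging artifacts, digitisation
error, or non-model damage chemistry.

## Problem sizes and numerics

The test-suite and acceptance runs use the study sample sizes where they
are the point (21 + 23 outlines and teeth, 50,000 reads, 1,000 simulated
calibrations, 500 isometric replicates) and reduced sizes where they are
not: the type-I simulation resamples outlines at (20, 15) semilandmarks
— the test statistic's null distribution does not depend on the point
count — and demo-preset pipeline runs use small cohorts. Tooth phantoms
default to 72×48×64 voxels at 0.1 mm, chosen so that a cohort of 44
teeth segments and slices in seconds while keeping ~7 voxels across the
enamel thickness. Tolerances: GPA convergence 1e-10 RMS; sliding stops
on objective change < 1e-8 or reversal; TPS systems carry a 1e-8 kernel
ridge and the tangent solve a 1e-10 ridge; posterior mass is normalised
to 1e-9. Ties in multi-Otsu, ICP sign ambiguities and degenerate inputs
(coincident points, collinear rings, single-cusp teeth, empty slices)
raise errors naming the failed precondition.

## Known limitations

* The IntCal13 curve is published data and not redistributed; the one
  real-data calibration check requires a local copy under `data/` and
  fails with instructions otherwise. All other validation is
  curve-independent.
* Volume I/O is TIFF stack + JSON sidecar only.
* The wear screen is a screen, not an enamel-thickness cartography; its
  thresholds are configuration, tuned on phantoms.
* `assign_group` intentionally provides no probabilistic classification
  (no LDA/CVA); positions relative to group clouds are reported instead.
* The BV/TV maturity threshold is a configurable default, not an
  empirically established cut-off.
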