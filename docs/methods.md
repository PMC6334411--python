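# Methods

`smlmkit` analyzes 2D single-molecule localization microscopy (SMLM) data:
tables of fitted emitter positions (x, y, in nm) with per-localization
precision σ (the standard deviation of the position estimate, typically
5–30 nm for dSTORM). This note records the models, conventions, defaults
and numerical choices behind each stage, and what the synthetic benchmarks
do and do not demonstrate.

## Localization tables and ROIs

A table carries the required fields x, y, precision plus optional channel
(≥ 1), frame and photon count. Invariants (finite coordinates, σ > 0) are
enforced at construction; on file import, rows violating them are dropped
and counted rather than aborting the read, because real localization
exports routinely contain NaN rows. The ThunderSTORM dialect maps headers
by alias ("x [nm]" → x, "uncertainty [nm]"/"uncertainty_xy [nm]" →
precision); "sigma [nm]" is the fitted PSF width and is deliberately
ignored. Other vendor formats are handled through an explicit column map
plus a unit scale (nm per input unit).

Rectangular ROI membership is half-open, `[min, max)`, so abutting ROIs
partition the plane with no double counting; ROI splitting re-expresses
coordinates relative to the ROI origin. Overlapping ROIs duplicate shared
localizations by design (each ROI is analyzed independently).

## Rendering

Two quantitative reconstructions share one kernel engine that evaluates
truncated Gaussians at pixel centers and multiplies by pixel area
(midpoint rule):

* **Gaussian render** — each localization contributes an isotropic 2D
  Gaussian with σ equal to its own precision, mass 1 (or its photon
  count). Intensity therefore mixes density and precision; it is the
  classic SMLM visualization, not a density estimate.
* **KDE render** — all points smoothed with one global bandwidth h, pixel
  values converted to localizations/µm². The image integrates to the
  number of contributing localizations, so pixel values are physical local
  densities and segmentation thresholds are densities.

Numerical choices: kernels truncated at 4σ (mass loss < 1e-3, e.g.
`1 − (1 − e⁻⁸) ≈ 3.4e-4`, which bounds the mass-conservation error
asserted in the tests); default pixel size 5 nm (≥ 2× oversampling of
10–20 nm structures); bandwidth `"auto"` = mean precision of the rendered
table, tying smoothing to measurement uncertainty. No renormalization is
applied for mass lost off the field edge — the conservation property is
only claimed for tables ≥ 5h inside the field. The midpoint rule (rather
than per-pixel integration) commits an error that is negligible at 5 nm
pixels relative to typical σ ≥ 8 nm.

## Clustering

Three segmentation routes, all returning per-localization labels
(0 = noise, 1..K contiguous):

* **Binary-KDE** — threshold the KDE image at a density (localizations/µm²),
  take 8-connected components of the mask, let each localization inherit
  its pixel's component, drop components with fewer than `min_size`
  members, renumber by descending membership. The threshold has no
  universal default; it is a physical density the user places between
  background and cluster peaks.
* **DBSCAN** — classic density-based clustering: a core point has ≥
  `min_pts` neighbors within `eps` nm (counting itself); clusters are grown
  from core points in ascending row order and border points join the first
  cluster that claims them, making the labeling fully deterministic.
  Neighborhoods come from a k-d tree; the expansion is implemented here
  rather than delegated so that border-point assignment follows this fixed
  convention. Defaults eps = 50 nm, min_pts = 5: the radius sits at about
  twice the typical localization precision, the scale at which repeated
  observations of one binding site merge.
* **Voronoi tile-area thresholding** — a localization is "clustered" iff
  its Voronoi tile area is below `threshold_factor` (default 2) times the
  median bounded tile area (small tile ⇔ high local density); unbounded
  border tiles are excluded from the median and never selected. Selected
  points are grouped wherever they are Delaunay neighbors; groups smaller
  than `min_size` revert to noise. Degenerate inputs (< 3 points, all
  collinear) raise a geometry error; when every tile is unbounded (e.g. 3
  points) everything is noise.

Per-cluster features use the population covariance (divisor n) of member
coordinates: sd_major/sd_minor are the principal-axis standard deviations,
orientation the major-axis angle in (−π/2, π/2], elongation their ratio,
and the scalar FWHM is `2√(2 ln 2)·√(sd_major·sd_minor)` — the full width
at half maximum of the isotropic Gaussian with the cluster's geometric-mean
spread, derived from localization scatter rather than from an image fit to
stay independent of pixelation. Hull area comes from the convex hull
(0 for < 3 distinct or collinear points); singleton clusters report zero
spread and missing elongation instead of raising. Mask ("pixel") area is
reported only for KDE-derived clusters.

### Scoring against ground truth

Four performance parameters compare a labeling with per-localization
truth: true clusters detected, false clusters, % of noise clustered, % of
signal clustered. The matching rule — not fixed by the metric definitions —
is a 50% majority: a true cluster counts as detected iff at least half its
members share one non-noise label; true clusters whose majority labels
coincide are *fused* and count once; a detected cluster is false iff fewer
than half its members are signal. Majority matching is the simplest rule
that reproduces the fused-cluster convention symmetrically.

## Particle averaging

Template-free alignment uses features of a reference channel only, applied
to all channels (preserving inter-channel geometry): translate the
centroid to the origin, rotate the major covariance eigenvector onto the
x-axis, and mirror about the y-axis if the heavier half-plane (by
localization count, or photon sum when photon counts exist) is on the
right — so the high-intensity side always ends at x < 0. The covariance
principal axis is computed from the localizations, not a rendered image,
avoiding pixel-size dependence. The eigenvector's sign ambiguity is fixed
by requiring a positive x-component, so an already-canonical particle maps
to the identity transform.

Two residual points:

* **Tie-break.** With unit weights and an even count, the two half-planes
  can carry exactly equal mass; the decision then falls back to the sign of
  the weighted third moment about the axis, which is odd under mirroring
  and therefore picks the same pose for any two rigid-motion copies of the
  same point set.
* **Up/down ambiguity.** The left/right rule leaves a free reflection
  about the x-axis. It is not resolved by default (the mirror pose is
  equally valid); `resolve_top=True` additionally folds the heavier half
  below the axis, which pins a unique pose — used by the recovery tests.

Particles with elongation < 1.1 have a noise-dominated major axis; they
are flagged `orientation_reliable=False` but still processed. Averaging
offers both a render of the merged localizations and the pixel-wise mean
of per-particle renders; the two differ only in normalization choices, and
both are provided because either reading of "averaging" is defensible.
Iterative all-to-all registration is deliberately out of scope — the point
of the feature-based approach is to stay cheap and assumption-light for
structurally variable particles.

## Synthetic data

The cluster benchmark emits 6 isolated isotropic Gaussian clusters of 50
localizations, one 100-localization component made of two sub-clusters
whose centers sit 60 nm apart (genuinely overlapping at 25 nm spread), and
300 uniform noise points — 700 rows with exact, non-stochastic component
counts. Spatial scales not dictated by the composition are fixed once at
dSTORM-typical values: 3000 nm field, 25 nm cluster σ, 400 nm minimum
center separation (rejection-sampled placement), precisions lognormal with
10 nm median and 0.3 log-σ. "Circular" clusters are read as isotropic
Gaussians; a uniform-disc mode exists as an option.

Elongated test particles are anisotropic Gaussians (length σ 100 nm, width
σ 30 nm) whose x-profile is a two-sided half-normal with side scales
chosen so the mean is zero while exactly 70% of points lie at x < 0 — the
zero mean matters because alignment centers on the centroid, and a profile
with nonzero mean would not preserve its left fraction after centering.
Each particle is perturbed by a recorded mirror/rotation/translation so
recovery can be checked against ground truth.

The generators emulate spatial structure only: no blinking kinetics, drift,
repeated-frame emitters or camera noise. Passing the benchmark therefore
shows that the algorithms segment and score idealized spatial mixtures
correctly at realistic scales; it does not certify performance on data with
blinking-induced over-counting or drift artefacts, which upstream
processing must handle.

## Problem sizes and determinism

Default test and acceptance runs use the benchmark at its native size
(700 localizations), 100 random DBSCAN instances of ≤ 200 points against a
brute-force oracle, 20 KDE mass checks, 20 Voronoi oracle instances and 50
particles × 300 localizations for averaging recovery — sizes at which every
oracle is exact and the whole suite completes in seconds. All randomness
flows through seeded `numpy.random.Generator` instances; identical seeds
give bit-identical tables, labels and CSV outputs.
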