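# smlmkit

Quantitative analysis of 2D single-molecule localization microscopy (SMLM)
data — dSTORM, PALM and related modalities — where an "image" is really a
table of emitter coordinates (x, y, in nm) with per-localization precision
σ. `smlmkit` covers the downstream workflow once localizations have been
fitted: import and filter localization tables, split them into regions of
interest (ROIs), reconstruct super-resolution images, identify and
quantify clusters of localizations, benchmark clustering against synthetic
ground truth, and perform feature-based, template-free particle averaging
across many copies of the same nanoscale structure (e.g. DNA-repair foci).

## What it computes

**Rendering.** Per-localization Gaussian rendering (each point drawn with
σ equal to its precision) and a count-normalized 2D kernel density
estimate whose pixel values are physical densities in localizations/µm²
(the image integrates to the number of localizations), so segmentation
thresholds are densities, not arbitrary intensities.

**Clustering.** Three algorithms returning per-localization labels
(0 = noise): binary-KDE segmentation (threshold the density image at
*d* localizations/µm², 8-connected components), DBSCAN (core point iff ≥
`min_pts` neighbors within `eps`; deterministic border assignment), and
Voronoi tile-area thresholding (a point is clustered iff its tile area <
2× the median tile area, grouped by Delaunay adjacency). Per-cluster
features: count, centroid, mean precision, principal-axis spreads
σ_major/σ_minor, orientation, elongation = σ_major/σ_minor, convex-hull
area, and FWHM = 2√(2 ln 2)·√(σ_major·σ_minor).

**Benchmark scoring.** Against ground truth, four performance parameters:
true clusters detected (clusters fused under one label count once), false
clusters, % of noise localizations clustered, % of signal localizations
clustered.

**Particle averaging.** Each particle is centered on its reference
channel's center of mass, rotated so the major covariance axis lies along
x, and mirrored so the high-intensity side is on the left; the transform
is applied to all channels and the aligned particles are merged or
averaged as images.

**Synthetic data.** A ground-truthed cluster benchmark (6 isolated
clusters of 50 localizations, one overlapping pair of 100, 300 uniform
noise points in a 3 µm field) and elongated asymmetric particles under
recorded rigid motions, for end-to-end validation.

## Worked example

```python
import numpy as np
from smlmkit import (S2Config, make_s2_testset, cluster_dbscan,
                     cluster_features, features_to_frame, score_clustering)

table, truth = make_s2_testset(S2Config(seed=1))
print(table)                       # LocalizationTable(n=700, channels=[1])

labeling = cluster_dbscan(table, eps=50.0, min_pts=5)
report = score_clustering(labeling, truth)
print(labeling.n_clusters)         # 7
print(report.n_positive_detected,  # 7   true clusters found (pair fused -> 1)
      report.n_false_clusters)     # 0
print(round(report.pct_noise_clustered, 2),   # 2.33  % of noise swept up
      round(report.pct_signal_clustered, 2))  # 99.75 % of signal recovered

feats = features_to_frame(cluster_features(table, labeling))
print(feats[["cluster_id", "n_localizations", "fwhm", "elongation"]])
#    cluster_id  n_localizations       fwhm  elongation
# 0           1               50  51.532192    1.183382
# 1           2               51  55.218811    1.365178
# 2           3               51  57.879578    1.156080
# 3           4               52  61.445053    1.009496
# 4           5               50  66.903665    1.080097
# 5           6               51  59.465237    1.188096
# 6           7              101  69.924168    1.661021
```

Clusters 1–6 are the isolated 50-point clusters (a stray noise point or
two gets swept in); their ≈ 59 nm FWHM matches the generator's 25 nm
spread (2.355·25 ≈ 59). Cluster 7 is the overlapping pair — twice the
membership, larger FWHM and visibly elongated, which is exactly how fused
clusters betray themselves. The same data can be segmented with
`cluster_kde(table, geometry, density_threshold=1000.0)` or
`cluster_voronoi(table)` and scored identically.

The same workflow is available from the shell:

```sh
smlmkit simulate s2 --seed 1 --out run/
smlmkit cluster dbscan run/locs.csv --eps 50 --min-pts 5 --out run/clus/
smlmkit score run/clus/labels.csv run/truth.csv --out run/report.csv
# {"n_positive_detected": 7, "n_false_clusters": 0, ...}
```

Every command writes a `runlog.json` with the effective parameters and
seed; identical seeds give byte-identical outputs.

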