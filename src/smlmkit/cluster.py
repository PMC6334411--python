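"""Cluster identification, per-cluster features and benchmark scoring.

Three complementary segmentation strategies for 2D localization data:

``cluster_kde``
    Threshold the count-normalized KDE image at a physical density
    (localizations/µm²) and take 8-connected components of the binary mask;
    localizations inherit the label of their pixel.  This is the image-space
    route: robust to heterogeneous density, resolution set by the bandwidth.
``cluster_dbscan``
    Classic DBSCAN on the raw coordinates: a point is a core point iff it
    has at least ``min_pts`` neighbors within ``eps`` nm (counting itself);
    clusters are maximal density-connected sets, everything else is noise.
``cluster_voronoi``
    Voronoi tessellation of all points; a localization is "clustered" iff
    its tile area falls below ``threshold_factor`` times the median bounded
    tile area (small tile = high local density), and selected points are
    grouped through Delaunay neighbor connectivity.

All three return a :class:`ClusterLabeling` aligned row-for-row with the
input table (0 = noise, 1..K = clusters).  :func:`cluster_features` computes
the per-cluster descriptors (count, centroid, precision, principal-axis
spread, elongation, FWHM, convex-hull area), and :func:`score_clustering`
evaluates a labeling against synthetic ground truth with four performance
parameters: truth clusters detected (fusions counted once), false clusters,
percent of noise clustered and percent of signal clustered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay, Voronoi, cKDTree
from scipy.spatial import QhullError
from shapely.geometry import Polygon
from skimage import measure

from smlmkit.io import LocalizationTable, LocalizationError
from smlmkit.render import ImageGeometry, RenderedImage, render_kde

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM of a Gaussian = 2.355 sigma


class GeometryError(ValueError):
    """Raised when a tessellation or hull cannot be constructed."""


@dataclass
class ClusterLabeling:
    """Per-localization cluster assignment.

    ``labels[k]`` is 0 for noise/background or the 1-based id of the cluster
    containing row k; ids are contiguous 1..K and every id has at least one
    member.  ``params`` records the algorithm parameters for provenance.
    """

    labels: np.ndarray
    algorithm: str
    params: dict = field(default_factory=dict)
    label_image: RenderedImage | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max(initial=0))

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)


@dataclass
class ClusterFeatureRecord:
    """Quantitative descriptors of one cluster of localizations.

    ``sd_major``/``sd_minor`` are the principal-axis standard deviations of
    the member coordinates (population covariance, divisor n);
    ``orientation`` is the major-axis angle to the x-axis in (−π/2, π/2];
    ``elongation = sd_major / sd_minor`` (NaN when the minor axis is
    degenerate); ``fwhm = 2√(2 ln 2)·√(sd_major·sd_minor)`` — the full width
    at half maximum of the equivalent isotropic Gaussian;  ``hull_area`` is
    the convex-hull area (0 for fewer than 3 distinct points);
    ``pixel_area`` is the mask area for KDE-derived clusters, NaN otherwise.
    """

    cluster_id: int
    n_localizations: int
    centroid_x: float
    centroid_y: float
    mean_precision: float
    sd_major: float
    sd_minor: float
    orientation: float
    elongation: float
    fwhm: float
    hull_area: float
    pixel_area: float = float("nan")


@dataclass
class PerformanceReport:
    """Clustering performance against ground truth.

    Four parameters: the number of true clusters detected (clusters fused
    under one label count once), the number of detected clusters that match
    no true cluster, and the percentages of noise and signal localizations
    that were assigned to any cluster.
    """

    n_positive_detected: int
    n_false_clusters: int
    pct_noise_clustered: float
    pct_signal_clustered: float


# ---------------------------------------------------------------------------
# DBSCAN


def cluster_dbscan(
    table: LocalizationTable, eps: float = 50.0, min_pts: int = 5
) -> ClusterLabeling:
    """Density-based clustering (DBSCAN) on Euclidean 2D distance.

    A core point has >= ``min_pts`` neighbors within ``eps`` nm, counting
    itself.  Clusters are grown from core points in ascending row order;
    border points (in range of a core point but not core themselves) join
    the first cluster that claims them, which makes the labeling
    deterministic.  Unreachable points get label 0.

    Defaults (eps 50 nm, min_pts 5) place the neighborhood radius at about
    twice the typical localization precision of dSTORM data.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    n = len(table)
    labels = np.zeros(n, dtype=np.int64)
    if n == 0:
        return ClusterLabeling(labels, "dbscan", {"eps": eps, "min_pts": min_pts})

    tree = cKDTree(table.xy)
    neighborhoods = [sorted(nb) for nb in tree.query_ball_point(table.xy, r=eps)]
    core = np.array([len(nb) >= min_pts for nb in neighborhoods])

    cluster_id = 0
    for seed in range(n):
        if labels[seed] != 0 or not core[seed]:
            continue
        cluster_id += 1
        labels[seed] = cluster_id
        queue = [seed]
        while queue:
            p = queue.pop(0)
            for q in neighborhoods[p]:
                if labels[q] == 0:
                    labels[q] = cluster_id
                    if core[q]:
                        queue.append(q)
    return ClusterLabeling(labels, "dbscan", {"eps": eps, "min_pts": min_pts})


# ---------------------------------------------------------------------------
# binary-KDE segmentation


def cluster_kde(
    table: LocalizationTable,
    geometry: ImageGeometry,
    bandwidth: float | str = "auto",
    density_threshold: float = 1.0,
    min_size: int = 5,
) -> ClusterLabeling:
    """Segment clusters from the thresholded KDE image.

    The KDE image (localizations/µm²) is binarized at ``density_threshold``;
    8-connected components of the mask become candidate clusters and each
    localization inherits the label of the pixel containing it (0 when the
    pixel is below threshold or outside the field).  Components with fewer
    than ``min_size`` member localizations are relabelled noise; surviving
    ids are renumbered 1..K by descending member count.

    Returns a labeling whose ``label_image`` holds the relabelled component
    image for mask-area measurements.
    """
    if density_threshold <= 0:
        raise ValueError("density_threshold must be > 0")
    if len(table) == 0:
        raise LocalizationError("cluster_kde requires a non-empty table")
    kde = render_kde(table, geometry, bandwidth=bandwidth)
    mask = kde.pixels >= density_threshold
    components = measure.label(mask, connectivity=2)

    i, j = geometry.pixel_of(table.x, table.y)
    inside = (i >= 0) & (i < geometry.width) & (j >= 0) & (j < geometry.height)
    raw = np.zeros(len(table), dtype=np.int64)
    raw[inside] = components[j[inside], i[inside]]

    # drop small clusters, renumber survivors by descending membership
    ids, counts = np.unique(raw[raw > 0], return_counts=True)
    keep = ids[counts >= min_size]
    keep_counts = counts[counts >= min_size]
    order = np.lexsort((keep, -keep_counts))  # big first, ties by original id
    remap = {int(old): rank + 1 for rank, old in enumerate(keep[order])}

    labels = np.array([remap.get(int(v), 0) for v in raw], dtype=np.int64)
    relabelled = np.zeros_like(components)
    for old, new in remap.items():
        relabelled[components == old] = new
    label_image = RenderedImage(geometry, relabelled, mode="labels")
    params = {
        "bandwidth": bandwidth,
        "density_threshold": density_threshold,
        "min_size": min_size,
    }
    return ClusterLabeling(labels, "kde", params, label_image=label_image)


# ---------------------------------------------------------------------------
# Voronoi tile-area thresholding


def voronoi_tile_areas(points: np.ndarray) -> np.ndarray:
    """Area (nm²) of each point's Voronoi tile; inf for unbounded border tiles."""
    try:
        vor = Voronoi(points)
    except QhullError as e:
        raise GeometryError(f"Voronoi tessellation failed: {e}") from e
    areas = np.full(len(points), np.inf)
    for k, region_idx in enumerate(vor.point_region):
        region = vor.regions[region_idx]
        if -1 in region or len(region) < 3:
            continue
        areas[k] = Polygon(vor.vertices[region]).area
    return areas


def cluster_voronoi(
    table: LocalizationTable, threshold_factor: float = 2.0, min_size: int = 5
) -> ClusterLabeling:
    """Cluster by Voronoi tile-area thresholding.

    A localization is selected as clustered iff its Voronoi tile area is
    below ``threshold_factor`` (default 2) times the median tile area;
    unbounded border tiles are excluded from the median and never selected.
    Selected points are grouped into clusters wherever they are Delaunay
    neighbors, and groups smaller than ``min_size`` become noise.
    """
    if threshold_factor <= 0:
        raise ValueError("threshold_factor must be > 0")
    n = len(table)
    if n < 3:
        raise GeometryError("Voronoi clustering requires at least 3 points")
    points = table.xy
    areas = voronoi_tile_areas(points)
    bounded = np.isfinite(areas)
    labels = np.zeros(n, dtype=np.int64)
    params = {"threshold_factor": threshold_factor, "min_size": min_size}
    if not bounded.any():
        return ClusterLabeling(labels, "voronoi", params)
    median_area = float(np.median(areas[bounded]))
    selected = areas < threshold_factor * median_area

    if selected.sum() == 0:
        return ClusterLabeling(labels, "voronoi", params)

    # union-find over Delaunay edges restricted to selected points
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    tri = Delaunay(points)
    indptr, indices = tri.vertex_neighbor_vertices
    for a in np.flatnonzero(selected):
        for b in indices[indptr[a] : indptr[a + 1]]:
            if selected[b]:
                ra, rb = find(a), int(find(b))
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    roots = np.array([find(a) if selected[a] else -1 for a in range(n)])
    next_id = 1
    assigned: dict[int, int] = {}
    for a in range(n):  # first-appearance order keeps ids deterministic
        r = roots[a]
        if r < 0 or r in assigned:
            continue
        size = int((roots == r).sum())
        if size >= min_size:
            assigned[r] = next_id
            next_id += 1
    labels = np.array([assigned.get(int(r), 0) if r >= 0 else 0 for r in roots])
    return ClusterLabeling(labels, "voronoi", params)


# ---------------------------------------------------------------------------
# features


def _principal_axes(xy: np.ndarray) -> tuple[float, float, float]:
    """(sd_major, sd_minor, orientation) from the population covariance."""
    cov = np.cov(xy, rowvar=False, bias=True)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    sd_minor = float(np.sqrt(max(evals[0], 0.0)))
    sd_major = float(np.sqrt(max(evals[1], 0.0)))
    vx, vy = evecs[:, 1]
    theta = float(np.arctan2(vy, vx))
    if theta <= -np.pi / 2:
        theta += np.pi
    elif theta > np.pi / 2:
        theta -= np.pi
    return sd_major, sd_minor, theta


def _hull_area(xy: np.ndarray) -> float:
    if len(xy) < 3:
        return 0.0
    try:
        return float(ConvexHull(xy).volume)  # "volume" is area in 2D
    except QhullError:
        return 0.0  # collinear points span no area


def cluster_features(
    table: LocalizationTable,
    labeling: ClusterLabeling,
    label_image: RenderedImage | None = None,
) -> list[ClusterFeatureRecord]:
    """Per-cluster descriptors for every cluster id in the labeling.

    Singleton clusters report zero spread and NaN elongation rather than
    raising.  When a label image is supplied (or carried by the labeling),
    ``pixel_area`` = number of mask pixels × pixel_size².
    """
    if len(labeling.labels) != len(table):
        raise ValueError("labeling does not align with table")
    if label_image is None:
        label_image = labeling.label_image
    records = []
    for cid in range(1, labeling.n_clusters + 1):
        idx = labeling.members(cid)
        if idx.size == 0:
            raise ValueError(f"cluster ids not contiguous: {cid} empty")
        xy = table.xy[idx]
        prec = table.precision[idx]
        if idx.size == 1:
            sd_major = sd_minor = 0.0
            orientation = 0.0
        else:
            sd_major, sd_minor, orientation = _principal_axes(xy)
        elongation = sd_major / sd_minor if sd_minor > 0 else float("nan")
        fwhm = FWHM_FACTOR * float(np.sqrt(sd_major * sd_minor))
        pixel_area = float("nan")
        if label_image is not None:
            npix = int((label_image.pixels == cid).sum())
            pixel_area = npix * label_image.geometry.pixel_size**2
        records.append(
            ClusterFeatureRecord(
                cluster_id=cid,
                n_localizations=int(idx.size),
                centroid_x=float(xy[:, 0].mean()),
                centroid_y=float(xy[:, 1].mean()),
                mean_precision=float(prec.mean()),
                sd_major=sd_major,
                sd_minor=sd_minor,
                orientation=orientation,
                elongation=elongation,
                fwhm=fwhm,
                hull_area=_hull_area(xy),
                pixel_area=pixel_area,
            )
        )
    return records


def features_to_frame(records: Sequence[ClusterFeatureRecord]) -> pd.DataFrame:
    """Feature records as a DataFrame, one row per cluster (for CSV export)."""
    cols = [
        "cluster_id", "n_localizations", "centroid_x", "centroid_y",
        "mean_precision", "sd_major", "sd_minor", "orientation",
        "elongation", "fwhm", "hull_area", "pixel_area",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])


# ---------------------------------------------------------------------------
# scoring against ground truth


def score_clustering(labeling: ClusterLabeling, truth) -> PerformanceReport:
    """Score a labeling against per-localization ground-truth components.

    ``truth`` is either an integer array (0 = noise, >= 1 = true cluster
    component) or an object with a ``component`` attribute holding one.

    Matching rule: a true cluster is *detected* iff at least half of its
    members share a single non-noise detected label.  True clusters whose
    majority label coincides are fused and count once.  A detected cluster
    is *false* iff fewer than half of its members are signal localizations.
    """
    component = np.asarray(getattr(truth, "component", truth), dtype=np.int64)
    labels = labeling.labels
    if len(component) != len(labels):
        raise ValueError(
            f"truth length {len(component)} does not match labeling {len(labels)}"
        )

    signal = component > 0
    noise = ~signal

    matched_labels: set[int] = set()
    for comp in np.unique(component[signal]):
        member_labels = labels[component == comp]
        clustered = member_labels[member_labels > 0]
        if clustered.size == 0:
            continue
        ids, counts = np.unique(clustered, return_counts=True)
        best = int(ids[np.argmax(counts)])
        if counts.max() >= 0.5 * member_labels.size:
            matched_labels.add(best)

    n_false = 0
    for cid in range(1, labeling.n_clusters + 1):
        members = labels == cid
        if signal[members].sum() < 0.5 * members.sum():
            n_false += 1

    pct_noise = 100.0 * (labels[noise] > 0).mean() if noise.any() else 0.0
    pct_signal = 100.0 * (labels[signal] > 0).mean() if signal.any() else 0.0
    return PerformanceReport(
        n_positive_detected=len(matched_labels),
        n_false_clusters=n_false,
        pct_noise_clustered=float(pct_noise),
        pct_signal_clustered=float(pct_signal),
    )
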