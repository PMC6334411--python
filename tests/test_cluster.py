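import numpy as np
import pytest
from scipy.spatial import Voronoi

from smlmkit import (
    ClusterLabeling,
    ImageGeometry,
    LocalizationTable,
    cluster_dbscan,
    cluster_features,
    cluster_kde,
    cluster_voronoi,
    features_to_frame,
    score_clustering,
    sample_cluster,
    sample_uniform_noise,
)
from smlmkit.cluster import GeometryError, voronoi_tile_areas

FWHM = 2 * np.sqrt(2 * np.log(2))


# ---------------------------------------------------------------------------
# independent oracles


def dbscan_oracle(xy, eps, min_pts):
    """Brute-force O(n²) DBSCAN from the distance matrix.

    Core components are found by DFS over the core-core adjacency graph in
    ascending row order; border points join the lowest-id cluster among
    their core neighbors (the first cluster grown that can reach them).
    """
    n = len(xy)
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    adj = d2 <= eps**2
    core = adj.sum(axis=1) >= min_pts
    labels = np.zeros(n, dtype=int)
    cid = 0
    for i in range(n):
        if not core[i] or labels[i]:
            continue
        cid += 1
        stack = [i]
        labels[i] = cid
        while stack:
            p = stack.pop()
            for q in np.flatnonzero(adj[p] & core):
                if labels[q] == 0:
                    labels[q] = cid
                    stack.append(q)
    for i in range(n):
        if not core[i]:
            reach = np.flatnonzero(adj[i] & core)
            if reach.size:
                labels[i] = labels[reach].min()
    return labels


def shoelace(vertices):
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def voronoi_selected_oracle(xy, factor):
    """Tile-area thresholding with polygon areas from the shoelace formula."""
    vor = Voronoi(xy)
    areas = np.full(len(xy), np.inf)
    for k, ridx in enumerate(vor.point_region):
        region = vor.regions[ridx]
        if -1 in region or len(region) < 3:
            continue
        areas[k] = shoelace(vor.vertices[region])
    finite = np.isfinite(areas)
    median = np.median(areas[finite])
    return areas < factor * median


def flood_fill_components(mask):
    """4/8-connected component labelling by explicit BFS (8-connectivity)."""
    labels = np.zeros(mask.shape, dtype=int)
    cid = 0
    for j0 in range(mask.shape[0]):
        for i0 in range(mask.shape[1]):
            if not mask[j0, i0] or labels[j0, i0]:
                continue
            cid += 1
            stack = [(j0, i0)]
            labels[j0, i0] = cid
            while stack:
                j, i = stack.pop()
                for dj in (-1, 0, 1):
                    for di in (-1, 0, 1):
                        jj, ii = j + dj, i + di
                        if (
                            0 <= jj < mask.shape[0]
                            and 0 <= ii < mask.shape[1]
                            and mask[jj, ii]
                            and not labels[jj, ii]
                        ):
                            labels[jj, ii] = cid
                            stack.append((jj, ii))
    return labels


def same_partition(a, b):
    """Identical partitions up to cluster-label permutation (0 stays 0)."""
    a, b = np.asarray(a), np.asarray(b)
    if not np.array_equal(a == 0, b == 0):
        return False
    forward, backward = {}, {}
    for x, y in zip(a[a > 0], b[a > 0]):
        if forward.setdefault(x, y) != y or backward.setdefault(y, x) != x:
            return False
    return True


# ---------------------------------------------------------------------------
# DBSCAN


class TestDBSCAN:
    def test_chain_of_three(self):
        t = LocalizationTable.from_arrays([0, 0, 0], [0, 5, 10], [10, 10, 10])
        lab = cluster_dbscan(t, eps=6, min_pts=2)
        assert lab.labels.tolist() == [1, 1, 1]

    def test_isolated_point_is_noise(self):
        t = LocalizationTable.from_arrays([0.0], [0.0], [10.0])
        assert cluster_dbscan(t, eps=50, min_pts=2).labels.tolist() == [0]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 100))
        xy = rng.uniform(0, 300, (n, 2))
        eps = float(rng.uniform(5, 60))
        min_pts = int(rng.integers(1, 8))
        t = LocalizationTable.from_arrays(xy[:, 0], xy[:, 1], np.full(n, 10.0))
        lab = cluster_dbscan(t, eps=eps, min_pts=min_pts)
        np.testing.assert_array_equal(lab.labels, dbscan_oracle(xy, eps, min_pts))

    def test_row_permutation_permutes_labels(self, rng):
        xy = rng.uniform(0, 200, (80, 2))
        t = LocalizationTable.from_arrays(xy[:, 0], xy[:, 1], np.full(80, 10.0))
        perm = rng.permutation(80)
        t2 = LocalizationTable.from_arrays(
            xy[perm, 0], xy[perm, 1], np.full(80, 10.0)
        )
        a = cluster_dbscan(t, eps=30, min_pts=3).labels
        b = cluster_dbscan(t2, eps=30, min_pts=3).labels
        assert same_partition(a[perm], b)


# ---------------------------------------------------------------------------
# binary-KDE segmentation


def two_cluster_table(seed=0, sep=1000.0, sd=25.0, n=50):
    rng = np.random.default_rng(seed)
    a = sample_cluster(n, (500.0, 500.0), sd, rng)
    b = sample_cluster(n, (500.0 + sep, 500.0), sd, rng)
    return a.concat(b)


class TestClusterKDE:
    def test_two_separated_clusters(self):
        t = two_cluster_table()
        geom = ImageGeometry(200, 200, 10.0, 200, 60)
        lab = cluster_kde(t, geom, bandwidth=20.0, density_threshold=500.0, min_size=5)
        assert lab.n_clusters == 2
        # each cluster captures nearly all of its 50 points
        for cid in (1, 2):
            assert lab.members(cid).size >= 45

    def test_threshold_ladder_merges_then_splits(self):
        # with a bandwidth comparable to the separation the clusters blend:
        # a low threshold keeps one connected component, a higher one two,
        # an extreme one none
        t = two_cluster_table(sep=400.0)
        geom = ImageGeometry(200, 200, 10.0, 130, 60)
        ks = [
            cluster_kde(t, geom, bandwidth=80.0, density_threshold=thr, min_size=5).n_clusters
            for thr in (30.0, 300.0, 1e7)
        ]
        assert ks == [1, 2, 0]

    def test_sparse_field_below_threshold_all_noise(self, rng):
        t = sample_uniform_noise(10, 2000.0, rng)
        geom = ImageGeometry(0, 0, 10.0, 200, 200)
        lab = cluster_kde(t, geom, bandwidth=20.0, density_threshold=1e6, min_size=1)
        assert not lab.labels.any()
        assert lab.n_clusters == 0

    def test_single_cluster_single_component(self, rng):
        t = sample_cluster(60, (300.0, 300.0), 20.0, rng)
        geom = ImageGeometry(0, 0, 10.0, 60, 60)
        lab = cluster_kde(t, geom, bandwidth=20.0, density_threshold=500.0, min_size=5)
        assert lab.n_clusters == 1
        assert lab.label_image.pixels.max() == 1

    def test_localization_labels_match_flood_fill_oracle(self):
        from smlmkit.render import render_kde

        t = two_cluster_table(seed=3)
        geom = ImageGeometry(200, 200, 10.0, 200, 60)
        thr = 500.0
        lab = cluster_kde(t, geom, bandwidth=20.0, density_threshold=thr, min_size=1)
        mask = render_kde(t, geom, bandwidth=20.0).pixels >= thr
        oracle_img = flood_fill_components(mask)
        i, j = geom.pixel_of(t.x, t.y)
        inside = (i >= 0) & (i < geom.width) & (j >= 0) & (j < geom.height)
        oracle = np.zeros(len(t), dtype=int)
        oracle[inside] = oracle_img[j[inside], i[inside]]
        assert same_partition(lab.labels, oracle)


# ---------------------------------------------------------------------------
# Voronoi


class TestVoronoi:
    def test_dense_cluster_selected_sparse_rejected(self, rng):
        cluster = sample_cluster(50, (1000.0, 1000.0), 20.0, rng)
        noise = sample_uniform_noise(50, 2000.0, rng)
        t = cluster.concat(noise)
        lab = cluster_voronoi(t, threshold_factor=2.0, min_size=5)
        selected = lab.labels > 0
        # the dense cluster dominates the selection
        assert selected[:50].mean() > 0.9
        assert selected[50:].mean() < 0.3

    @pytest.mark.parametrize("seed", range(10))
    def test_selection_matches_shoelace_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cluster = sample_cluster(40, (1000.0, 1000.0), 25.0, rng)
        noise = sample_uniform_noise(60, 2000.0, rng)
        t = cluster.concat(noise)
        lab = cluster_voronoi(t, threshold_factor=2.0, min_size=1)
        np.testing.assert_array_equal(
            lab.labels > 0, voronoi_selected_oracle(t.xy, 2.0)
        )

    def test_uniform_grid_interior_selected_one_cluster(self):
        xs, ys = np.meshgrid(np.arange(10) * 100.0, np.arange(10) * 100.0)
        t = LocalizationTable.from_arrays(xs.ravel(), ys.ravel(), np.full(100, 10.0))
        lab = cluster_voronoi(t, threshold_factor=2.0, min_size=1)
        areas = voronoi_tile_areas(t.xy)
        interior = np.isfinite(areas)
        # all interior tiles have the same area (100x100), below 2x median
        np.testing.assert_allclose(areas[interior], 100.0 * 100.0)
        assert (lab.labels[interior] > 0).all()
        assert len(np.unique(lab.labels[interior])) == 1

    def test_three_points_all_unbounded_all_noise(self):
        t = LocalizationTable.from_arrays([0, 100, 50], [0, 0, 100], [10, 10, 10])
        lab = cluster_voronoi(t, threshold_factor=2.0, min_size=1)
        assert not lab.labels.any()

    def test_too_few_or_collinear_points_error(self):
        t = LocalizationTable.from_arrays([0, 1], [0, 1], [10, 10])
        with pytest.raises(GeometryError):
            cluster_voronoi(t)
        col = LocalizationTable.from_arrays([0, 1, 2, 3], [0, 1, 2, 3], [10] * 4)
        with pytest.raises(GeometryError):
            cluster_voronoi(col)


# ---------------------------------------------------------------------------
# features


class TestFeatures:
    def test_square_corner_worked_example(self):
        t = LocalizationTable.from_arrays(
            [0, 0, 10, 10], [0, 10, 0, 10], [8.0, 10.0, 12.0, 10.0]
        )
        recs = cluster_features(t, ClusterLabeling(np.ones(4), "manual"))
        r = recs[0]
        assert r.n_localizations == 4
        assert r.centroid_x == pytest.approx(5.0, abs=1e-12)
        assert r.centroid_y == pytest.approx(5.0, abs=1e-12)
        assert r.mean_precision == pytest.approx(10.0)
        assert r.hull_area == pytest.approx(100.0, rel=1e-9)
        assert r.sd_major == pytest.approx(5.0, rel=1e-9)
        assert r.sd_minor == pytest.approx(5.0, rel=1e-9)
        assert r.elongation == pytest.approx(1.0, rel=1e-9)
        assert r.fwhm == pytest.approx(FWHM * 5.0, rel=1e-9)

    def test_collinear_cluster_degenerate(self):
        t = LocalizationTable.from_arrays([0, 10, 20], [0, 0, 0], [10] * 3)
        r = cluster_features(t, ClusterLabeling(np.ones(3), "manual"))[0]
        assert r.hull_area == 0.0
        assert np.isnan(r.elongation)
        assert r.sd_minor == 0.0

    def test_singleton_cluster_no_exception(self):
        t = LocalizationTable.from_arrays([5.0], [7.0], [10.0])
        r = cluster_features(t, ClusterLabeling(np.ones(1), "manual"))[0]
        assert r.sd_major == 0.0 and np.isnan(r.elongation)
        assert r.centroid_x == 5.0 and r.centroid_y == 7.0

    @pytest.mark.parametrize("seed", range(5))
    def test_rotation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        xy = rng.normal(0, 30, (40, 2)) * [2.0, 1.0]
        t = LocalizationTable.from_arrays(xy[:, 0], xy[:, 1], np.full(40, 10.0))
        angle = rng.uniform(0, 2 * np.pi)
        c, s = np.cos(angle), np.sin(angle)
        rot = LocalizationTable.from_arrays(
            c * xy[:, 0] - s * xy[:, 1], s * xy[:, 0] + c * xy[:, 1], np.full(40, 10.0)
        )
        lab = ClusterLabeling(np.ones(40), "manual")
        a = cluster_features(t, lab)[0]
        b = cluster_features(rot, lab)[0]
        for attr in ("hull_area", "fwhm", "elongation", "sd_major", "sd_minor"):
            assert getattr(b, attr) == pytest.approx(getattr(a, attr), rel=1e-9)

    def test_translation_invariance(self, rng):
        xy = rng.normal(0, 25, (30, 2))
        t = LocalizationTable.from_arrays(xy[:, 0], xy[:, 1], np.full(30, 10.0))
        moved = t.with_xy(t.x + 1234.5, t.y - 987.6)
        lab = ClusterLabeling(np.ones(30), "manual")
        a, b = cluster_features(t, lab)[0], cluster_features(moved, lab)[0]
        for attr in ("hull_area", "fwhm", "elongation", "orientation", "sd_major"):
            assert getattr(b, attr) == pytest.approx(getattr(a, attr), rel=1e-9)
        assert b.centroid_x == pytest.approx(a.centroid_x + 1234.5)

    def test_pixel_area_from_label_image(self, rng):
        t = sample_cluster(60, (300.0, 300.0), 20.0, rng)
        geom = ImageGeometry(0, 0, 10.0, 60, 60)
        lab = cluster_kde(t, geom, bandwidth=20.0, density_threshold=500.0, min_size=5)
        r = cluster_features(t, lab)[0]
        expected = (lab.label_image.pixels == 1).sum() * 10.0**2
        assert r.pixel_area == expected
        assert expected > 0

    def test_features_frame_columns(self):
        t = LocalizationTable.from_arrays([0, 1, 2], [0, 1, 0], [10] * 3)
        frame = features_to_frame(cluster_features(t, ClusterLabeling(np.ones(3), "m")))
        assert list(frame["cluster_id"]) == [1]
        assert "fwhm" in frame.columns and "hull_area" in frame.columns


# ---------------------------------------------------------------------------
# performance scoring


class TestScoring:
    def make_truth(self):
        # 7 components of 10 rows each + 30 noise rows
        comp = np.concatenate([np.repeat(np.arange(1, 8), 10), np.zeros(30, int)])
        return comp

    def test_identity_labeling_is_perfect(self):
        comp = self.make_truth()
        rep = score_clustering(ClusterLabeling(comp.copy(), "manual"), comp)
        assert rep.n_positive_detected == 7
        assert rep.n_false_clusters == 0
        assert rep.pct_noise_clustered == 0.0
        assert rep.pct_signal_clustered == 100.0

    def test_everything_noise(self):
        comp = self.make_truth()
        rep = score_clustering(ClusterLabeling(np.zeros_like(comp), "manual"), comp)
        assert (rep.n_positive_detected, rep.n_false_clusters) == (0, 0)
        assert rep.pct_noise_clustered == 0.0 and rep.pct_signal_clustered == 0.0

    def test_fused_clusters_count_once(self):
        comp = self.make_truth()
        labels = comp.copy()
        labels[labels == 2] = 1  # components 1 and 2 merged under one label
        labels[labels > 2] -= 1  # keep ids contiguous
        rep = score_clustering(ClusterLabeling(labels, "manual"), comp)
        assert rep.n_positive_detected == 6

    def test_noise_only_cluster_is_false(self):
        comp = self.make_truth()
        labels = np.zeros_like(comp)
        labels[comp == 0][:] = 0
        labels[-10:] = 1  # a cluster made purely of noise rows
        rep = score_clustering(ClusterLabeling(labels, "manual"), comp)
        assert rep.n_false_clusters == 1
        assert rep.n_positive_detected == 0
        assert rep.pct_noise_clustered == pytest.approx(100 * 10 / 30)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_clustering(ClusterLabeling(np.zeros(5), "m"), np.zeros(6))
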