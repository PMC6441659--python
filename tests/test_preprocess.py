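"""Preprocessing: alignment, rasterization, ground removal, SOR, DBSCAN."""
import math

import numpy as np
import pytest

from shrubshape.io import BoundingBox, PointCloud, crop_box
from shrubshape.preprocess import (HeightHistogram, PreprocessConfig,
                                   align_cloud, clean_bush,
                                   detect_row_direction, fit_ground_plane,
                                   ground_threshold, height_histogram,
                                   largest_cluster, rasterize_depth,
                                   remove_ground, segment_bushes, sor_filter)


def eq2_oracle(counts, bin_m=0.01, t=5.0):
    """Exhaustive evaluation of the adaptive ground-threshold rule."""
    counts = np.asarray(counts, dtype=int)
    h = bin_m * np.arange(len(counts))
    G = np.diff(counts)
    h_G = h[:-1]
    h_steepest = h_G[int(np.argmin(G))]
    best = None
    for hi, gi in zip(h_G, G):
        if 0 < abs(gi) < t and hi > h_steepest:
            if best is None or hi < best:
                best = hi
    return best


class TestGroundPlane:
    def test_flat_plane_with_outliers(self, rng):
        plane = np.column_stack([rng.uniform(0, 10, 2000),
                                 rng.uniform(0, 10, 2000),
                                 np.zeros(2000)])
        outliers = rng.uniform(0, 10, size=(20, 3))
        cloud = PointCloud(np.vstack([plane, outliers]))
        normal, inliers = fit_ground_plane(cloud)
        np.testing.assert_allclose(normal, [0, 0, 1], atol=1e-6)
        assert inliers[:2000].mean() >= 0.99

    def test_tilted_plane_normal_recovered(self, rng):
        theta = math.radians(5.0)
        xy = rng.uniform(0, 10, size=(3000, 2))
        z = xy[:, 1] * math.tan(theta) + rng.normal(scale=0.005, size=3000)
        cloud = PointCloud(np.column_stack([xy, z]))
        normal, _ = fit_ground_plane(cloud)
        expected = np.array([0, -math.sin(theta), math.cos(theta)])
        angle = math.degrees(math.acos(abs(normal @ expected)))
        assert angle < 0.5

    def test_no_dominant_plane_raises(self, rng):
        cloud = PointCloud(rng.uniform(0, 1, size=(500, 3)))
        with pytest.raises(ValueError, match="dominant plane"):
            fit_ground_plane(cloud, tol_m=0.001)


class TestDepthRaster:
    def test_single_point_single_cell(self):
        raster = rasterize_depth(PointCloud([[0.1, 0.2, 1.5]]))
        occupied = ~np.isnan(raster.depth)
        assert occupied.sum() == 1
        assert raster.depth[occupied][0] == 1.5

    def test_max_rule_in_shared_cell(self):
        cloud = PointCloud([[0.1, 0.1, 0.2], [0.2, 0.2, 0.9]])
        raster = rasterize_depth(cloud)
        assert np.nanmax(raster.depth) == 0.9
        assert (~np.isnan(raster.depth)).sum() == 1

    def test_occupied_cells_match_bruteforce(self, rng):
        pts = rng.uniform(0, 8, size=(5000, 3))
        raster = rasterize_depth(PointCloud(pts), cell_size_m=0.5)
        ix = np.floor((pts[:, 0] - pts[:, 0].min()) / 0.5).astype(int)
        iy = np.floor((pts[:, 1] - pts[:, 1].min()) / 0.5).astype(int)
        assert (~np.isnan(raster.depth)).sum() == len(set(zip(iy, ix)))
        for (r, c) in {(1, 1), (3, 5)}:
            sel = (iy == r) & (ix == c)
            if sel.any():
                assert raster.depth[r, c] == pts[sel, 2].max()


class TestRowDetection:
    @staticmethod
    def _raster_from_line(heading_deg, n=40):
        t = np.linspace(0, 12, n)
        x = t * math.cos(math.radians(heading_deg))
        y = t * math.sin(math.radians(heading_deg))
        pts = np.column_stack([x, y, np.full(n, 1.0)])
        return rasterize_depth(PointCloud(pts), cell_size_m=0.5)

    def test_axis_aligned_row_heading_zero(self):
        det = detect_row_direction(self._raster_from_line(0.0))
        assert abs(math.degrees(det.heading_rad)) <= 1.0

    def test_thirty_degree_line(self):
        det = detect_row_direction(self._raster_from_line(30.0))
        assert math.degrees(det.heading_rad) == pytest.approx(30.0, abs=2.0)

    def test_too_few_bush_pixels_raises(self):
        raster = rasterize_depth(PointCloud([[0, 0, 0.1], [3, 3, 0.2]]))
        with pytest.raises(ValueError, match="bush cells"):
            detect_row_direction(raster)


class TestAlignCloud:
    def test_already_aligned_is_near_identity(self):
        from shrubshape.synthetic import BushSpec, FieldSpec, generate_field
        spec = FieldSpec(bush_specs=[[BushSpec()] * 4] * 2, seed=3)
        cloud, _, _ = generate_field(spec)
        aligned, res = align_cloud(cloud)
        assert abs(res.theta_x) < math.radians(0.5)
        assert abs(res.theta_y) < math.radians(0.5)
        assert abs(res.theta_z) < math.radians(0.5)

    def test_recovers_known_field_orientation(self, small_field):
        cloud, _, _ = small_field
        aligned, res = align_cloud(cloud)
        # the generated field slopes 5 degrees and heads 20 degrees
        assert -math.degrees(res.theta_z) == pytest.approx(20.0, abs=1.0)
        ground = aligned.points[aligned.attributes["label"] == 0]
        assert ground[:, 2].std() < 3 * 0.02 + 0.01

    def test_rotation_matrices_orthonormal(self, small_field):
        cloud, _, _ = small_field
        _, res = align_cloud(cloud)
        for T in (res.T_x, res.T_y, res.T_z):
            np.testing.assert_allclose(T @ T.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(T) == pytest.approx(1.0)

    def test_rigidity_pairwise_distances(self, small_field, rng):
        cloud, _, _ = small_field
        aligned, _ = align_cloud(cloud)
        i = rng.integers(0, len(cloud), 100)
        j = rng.integers(0, len(cloud), 100)
        d0 = np.linalg.norm(cloud.points[i] - cloud.points[j], axis=1)
        d1 = np.linalg.norm(aligned.points[i] - aligned.points[j], axis=1)
        np.testing.assert_allclose(d1, d0, rtol=1e-9, atol=1e-9)


class TestGroundThreshold:
    def test_worked_histogram_example(self):
        """counts [5,100,60,3,2,2,8,9] at 0.01 m bins, t=5: the steepest
        drop is 100→60 at h=0.01; the first small nonzero gradient above it
        is 3→2 at h=0.03."""
        counts = [5, 100, 60, 3, 2, 2, 8, 9]
        hist = HeightHistogram(
            bin_lower_limits=0.01 * np.arange(8),
            counts=np.array(counts),
            gradients=np.diff(counts),
        )
        expected = eq2_oracle(counts)
        assert expected == pytest.approx(0.03)
        assert ground_threshold(hist, t=5) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle_on_random_histograms(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 30, size=rng.integers(5, 40))
        counts[1] = 200  # a dominant ground peak so a steep drop exists
        hist = HeightHistogram(0.01 * np.arange(len(counts)),
                               counts, np.diff(counts))
        expected = eq2_oracle(counts)
        if expected is None:
            with pytest.raises(ValueError):
                ground_threshold(hist)
        else:
            assert ground_threshold(hist) == pytest.approx(expected)

    def test_no_qualifying_bin_raises(self):
        counts = np.array([100, 10, 110])  # gradients -90, +100: none small
        hist = HeightHistogram(0.01 * np.arange(3), counts, np.diff(counts))
        with pytest.raises(ValueError, match="noise factor"):
            ground_threshold(hist)

    def test_bush_on_flat_ground_split(self):
        """Ground removal keeps nearly all bush points and discards nearly
        all ground points, using the generator's labels as truth."""
        from shrubshape.synthetic import BushSpec, FieldSpec, generate_field
        spec = FieldSpec(bush_specs=[[BushSpec(noise_sigma_m=0.005)] * 3],
                         ground_roughness_m=0.01, seed=21)
        cloud, truths, boxes = generate_field(spec)
        raw = crop_box(cloud, boxes[1])
        hist = height_histogram(raw)
        h_ground = ground_threshold(hist)
        bush = remove_ground(raw, h_ground)
        lab_in = raw.attributes["label"]
        lab_out = bush.attributes["label"]
        ground_kept = (lab_out == 0).sum() / max((lab_in == 0).sum(), 1)
        bush_lost = 1 - (lab_out > 0).sum() / (lab_in > 0).sum()
        assert ground_kept <= 0.01
        assert bush_lost <= 0.02


class TestRemoveGround:
    def test_threshold_below_min_is_identity(self, random_cloud):
        out = remove_ground(random_cloud, random_cloud.points[:, 2].min() - 1)
        assert len(out) == len(random_cloud)

    def test_median_threshold_keeps_upper_half(self, rng):
        z = rng.uniform(0, 1, 1001)
        cloud = PointCloud(np.column_stack([np.zeros(1001), np.zeros(1001), z]))
        out = remove_ground(cloud, np.median(z))
        assert len(out) == 501

    def test_partition_against_bruteforce(self, rng):
        pts = rng.uniform(-1, 1, size=(10_000, 3))
        cloud = PointCloud(pts)
        h = 0.123
        out = remove_ground(cloud, h)
        assert len(out) == (pts[:, 2] >= h).sum()
        assert (out.points[:, 2] >= h).all()

    def test_all_removed_raises(self, random_cloud):
        with pytest.raises(ValueError):
            remove_ground(random_cloud, 99.0)


def sor_oracle(pts, k, n):
    """Brute-force O(N^2) statistical outlier removal."""
    dists = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    np.fill_diagonal(dists, np.inf)
    D = np.sort(dists, axis=1)[:, :k].mean(axis=1)
    return D <= D.mean() + n * D.std()


class TestSorFilter:
    def test_uniform_cluster_mostly_retained(self, rng):
        pts = rng.uniform(0, 1, size=(2000, 3))
        out = sor_filter(PointCloud(pts), k=10, n=3)
        assert len(out) / 2000 >= 0.99

    def test_single_far_point_removed(self, rng):
        pts = np.vstack([rng.normal(scale=0.2, size=(500, 3)),
                         [[10.0, 10.0, 10.0]]])
        out = sor_filter(PointCloud(pts), k=10, n=1)
        assert len(out) < 501
        assert not np.any(np.all(out.points == [10.0, 10.0, 10.0], axis=1))

    def test_equals_bruteforce_oracle_exactly(self, rng):
        pts = rng.uniform(0, 1, size=(300, 3))
        out = sor_filter(PointCloud(pts), k=10, n=1)
        keep = sor_oracle(pts, k=10, n=1)
        np.testing.assert_array_equal(out.points, pts[keep])

    def test_never_adds_points(self, rng):
        pts = rng.normal(size=(400, 3))
        once = sor_filter(PointCloud(pts))
        assert len(once) <= 400
        twice = sor_filter(once)
        assert len(twice) <= len(once)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            sor_filter(PointCloud(np.zeros((5, 3))), k=10)


class TestLargestCluster:
    def test_single_blob_identity_minus_noise(self, rng):
        pts = rng.uniform(0, 0.5, size=(800, 3))
        out = largest_cluster(PointCloud(pts), eps_m=0.1, min_points=10)
        assert len(out) >= 0.99 * 800

    def test_bush_beats_weed_blob(self, rng):
        bush = rng.normal(scale=0.2, size=(5000, 3))
        weed = rng.normal(scale=0.05, size=(300, 3)) + [1.5, 0, 0]
        cloud = PointCloud(np.vstack([bush, weed]),
                           attributes={"label": np.r_[np.ones(5000),
                                                      np.zeros(300)]})
        out = largest_cluster(cloud, eps_m=0.1, min_points=10)
        assert (out.attributes["label"] == 1).all()

    def test_tie_goes_to_lowest_point_index(self, rng):
        a = rng.normal(scale=0.05, size=(200, 3))
        b = rng.normal(scale=0.05, size=(200, 3)) + [5, 5, 5]
        out = largest_cluster(PointCloud(np.vstack([a, b])),
                              eps_m=0.5, min_points=5)
        assert len(out) == 200
        np.testing.assert_allclose(out.points, a)

    def test_no_cluster_raises(self, rng):
        pts = rng.uniform(0, 100, size=(50, 3))
        with pytest.raises(ValueError, match="eps"):
            largest_cluster(PointCloud(pts), eps_m=0.01, min_points=10)


class TestFullPreprocess:
    def test_field_recovery_and_contamination(self, small_field):
        """Aligned, segmented and cleaned bushes keep >= 95% of true bush
        points with <= 1% ground/weed contamination."""
        cloud, truths, boxes = small_field
        aligned, res = align_cloud(cloud)
        rot = res.rotation
        aligned_boxes = []
        for b in boxes:
            corners = np.array([
                [x, y, z]
                for x in (b.min_corner[0], b.max_corner[0])
                for y in (b.min_corner[1], b.max_corner[1])
                for z in (b.min_corner[2], b.max_corner[2])
            ]) @ rot - [0, 0, res.z_shift]
            aligned_boxes.append(BoundingBox(corners.min(axis=0),
                                             corners.max(axis=0)))
        bushes = segment_bushes(aligned, aligned_boxes)
        assert len(bushes) == len(truths)
        all_labels = cloud.attributes["label"]
        for raw, truth in zip(bushes, truths):
            clean = clean_bush(raw)
            lab = clean.attributes["label"]
            recovery = (lab == truth.bush_id + 1).sum() / \
                (all_labels == truth.bush_id + 1).sum()
            contamination = ((lab == 0) | (lab == -1)).sum() / len(clean)
            assert recovery >= 0.95
            assert contamination <= 0.01

    def test_empty_box_skipped_with_warning(self, small_field):
        cloud, _, _ = small_field
        far = BoundingBox([500, 500, 500], [501, 501, 501])
        out = segment_bushes(cloud, [far])
        assert out == []


class TestConfig:
    def test_rejects_nonpositive_values(self):
        with pytest.raises(ValueError):
            PreprocessConfig(sor_k=0)
        with pytest.raises(ValueError):
            PreprocessConfig(hist_bin_m=-0.01)
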