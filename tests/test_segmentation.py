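"""Segmentation chain: per-operation oracles plus ground-truth recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from ms2burst.segmentation import (
    SegmentationConfig,
    adaptive_threshold,
    attach_dots,
    centered_crop_box,
    crop_frame,
    detect_ms2_dots,
    max_project,
    preprocess_nuclei,
    segment_movie,
    voronoi_partition,
)


class TestMaxProject:
    def test_single_plane_identity(self):
        img = np.random.default_rng(0).random((1, 8, 8))
        np.testing.assert_array_equal(max_project(img), img[0])

    def test_matches_exhaustive_loop(self):
        stack = np.random.default_rng(1).random((26, 64, 64))
        proj = max_project(stack)
        for i in range(64):
            for j in range(64):
                assert proj[i, j] == max(stack[z, i, j] for z in range(26))

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            max_project(np.empty((0, 4, 4)))


class TestCropFrame:
    def test_full_frame_identity(self):
        img = np.arange(12.0).reshape(3, 4)
        np.testing.assert_array_equal(crop_frame(img, (0, 0, 3, 4)), img)

    def test_standard_edge_trim_shape(self):
        # 512x512 projection cropped to 300x430 to drop edge nuclei
        img = np.zeros((512, 512))
        box = centered_crop_box((512, 512), (300, 430))
        assert crop_frame(img, box).shape == (300, 430)

    def test_single_pixel_and_out_of_bounds(self):
        img = np.arange(12.0).reshape(3, 4)
        assert crop_frame(img, (1, 2, 1, 1))[0, 0] == img[1, 2]
        with pytest.raises(ValueError):
            crop_frame(img, (2, 2, 3, 3))


class TestPreprocess:
    def test_noop_configuration_is_identity(self):
        img = np.random.default_rng(2).random((16, 16))
        np.testing.assert_array_equal(
            preprocess_nuclei(img, blur_sigma=0, bright_tail_fraction=0), img
        )

    def test_constant_image_unchanged(self):
        img = np.full((10, 10), 7.0)
        np.testing.assert_allclose(preprocess_nuclei(img, 2.0, 0.05), img)

    def test_outlier_clipped_to_quantile(self):
        rng = np.random.default_rng(3)
        img = rng.normal(100, 1, (20, 20))
        img[5, 5] = 1e6
        out = preprocess_nuclei(img, blur_sigma=0, bright_tail_fraction=0.05)
        cutoff = np.sort(img.ravel())[int(np.ceil(0.95 * img.size)) - 1]  # sorting oracle
        assert out.max() <= np.quantile(img, 0.95) + 1e-9
        assert abs(out.max() - cutoff) < 0.1  # quantile interpolation slack
        assert out[5, 5] == out.max()

    def test_absolute_mode_cutoff(self):
        img = np.zeros((10, 10))
        img[0, 0] = 100.0
        img[0, 1] = 96.0
        out = preprocess_nuclei(img, 0, 0.05, mode="absolute")
        assert out.max() == 95.0


class TestAdaptiveThreshold:
    def test_synthetic_disks_counted_exactly(self, small_sim):
        movie, truth = small_sim
        proj = max_project(movie.nuclei_channel[0])
        pre = preprocess_nuclei(proj, 1.5, 0.05)
        mask, thr, degraded = adaptive_threshold(pre, (8, 20), (50, 1000))
        from scipy import ndimage

        _, n = ndimage.label(mask)
        assert n == truth.centroids.shape[1]
        assert not degraded

    def test_blank_image_degraded(self):
        mask, thr, degraded = adaptive_threshold(np.zeros((20, 20)), (1, 5), (1, 100))
        assert degraded and not mask.any()

    def test_touching_disks_split_by_higher_threshold(self):
        # two overlapping soft blobs: low thresholds merge them, higher split
        yy, xx = np.mgrid[0:40, 0:60]
        img = np.exp(-((yy - 20) ** 2 + (xx - 22) ** 2) / 50) + np.exp(
            -((yy - 20) ** 2 + (xx - 38) ** 2) / 50
        )
        mask, thr, degraded = adaptive_threshold(img, (2, 2), (10, 2000))
        from scipy import ndimage

        _, n = ndimage.label(mask)
        assert n == 2
        assert not degraded


class TestDetectDots:
    def test_constant_image_no_dots(self):
        mask, cents = detect_ms2_dots(np.full((10, 10), 5.0))
        assert not mask.any() and len(cents) == 0

    def test_bright_patch_detected_exactly(self):
        img = np.full((50, 50), 100.0)
        img[10:15, 20:25] = 1000.0
        mask, cents = detect_ms2_dots(img)
        expect = np.zeros_like(img, dtype=bool)
        expect[10:15, 20:25] = True
        np.testing.assert_array_equal(mask, expect)
        np.testing.assert_allclose(cents, [[12.0, 22.0]])

    def test_one_component_per_true_spot(self, small_sim):
        movie, truth = small_sim
        # pick a frame where many nuclei are bright
        t = int(np.argmax((truth.traces > 0).sum(axis=0)))
        active = truth.traces[:, t] > 2000  # strong spots only
        _, cents = detect_ms2_dots(max_project(movie.ms2_channel[t]))
        d = cdist(truth.spot_positions[t][active], cents)
        assert np.all(d.min(axis=1) < 2.0)


class TestAttachDots:
    def test_dot_inside_region_leaves_mask_unchanged(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[5:10, 5:10] = 1
        out = attach_dots(labels, np.array([[7.0, 7.0]]))
        np.testing.assert_array_equal(out, labels)

    def test_outside_dot_attached_to_nearest_nucleus(self):
        labels = np.zeros((30, 40), dtype=int)
        labels[5:15, 5:15] = 1
        labels[5:15, 25:35] = 2
        dot = np.array([[10.0, 18.0]])  # 3 px right of region 1's edge
        out = attach_dots(labels, dot)
        assert out[10, 18] == 1
        # disjointness preserved: region 2 untouched
        np.testing.assert_array_equal(out[labels == 2], labels[labels == 2])
        assert np.all(out[labels > 0] == labels[labels > 0])

    def test_no_nuclei_logs_and_leaves_unassigned(self, caplog):
        labels = np.zeros((10, 10), dtype=int)
        with caplog.at_level("WARNING"):
            out = attach_dots(labels, np.array([[5.0, 5.0]]))
        assert not out.any()
        assert any("unassigned" in r.message for r in caplog.records)


class TestVoronoi:
    def test_single_centroid_owns_image(self):
        out = voronoi_partition(np.array([[3.0, 3.0]]), (8, 8))
        assert np.all(out == 1)

    def test_two_centroids_vertical_bisector(self):
        out = voronoi_partition(np.array([[5.0, 2.0], [5.0, 8.0]]), (11, 11))
        assert np.all(out[:, :5] == 1)
        assert np.all(out[:, 6:] == 2)
        assert np.all(out[:, 5] == 1)  # tie -> lower label

    def test_zero_centroids_rejected(self):
        with pytest.raises(ValueError):
            voronoi_partition(np.empty((0, 2)), (5, 5))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(1, 20), st.integers(0, 2**31 - 1))
    def test_matches_exhaustive_nearest_centroid(self, n_pts, seed):
        rng = np.random.default_rng(seed)
        shape = (32, 48)
        pts = rng.uniform([0, 0], shape, size=(n_pts, 2))
        out = voronoi_partition(pts, shape)
        for i in range(0, shape[0], 5):
            for j in range(0, shape[1], 7):
                d = (pts[:, 0] - i) ** 2 + (pts[:, 1] - j) ** 2
                assert out[i, j] == int(np.argmin(d)) + 1


class TestSegmentMovie:
    def test_ground_truth_recovery(self, small_sim, small_frames):
        movie, truth = small_sim
        n_true = truth.centroids.shape[1]
        for lf in small_frames:
            assert len(lf.centroids) == n_true
            got = np.array([lf.centroids[i] for i in lf.region_labels])
            d = cdist(truth.centroids[lf.frame_index], got)
            assert d.min(axis=1).max() < 1.0

    def test_regions_disjoint_and_labels_positive(self, small_frames):
        for lf in small_frames[:5]:
            assert lf.labels.min() >= 0
            assert set(lf.centroids) == set(np.unique(lf.labels)) - {0}

    def test_every_dot_inside_one_region(self, small_sim, small_frames):
        movie, _ = small_sim
        for lf in small_frames[:10]:
            _, dots = detect_ms2_dots(max_project(movie.ms2_channel[lf.frame_index]))
            for dy, dx in dots:
                assert lf.labels[int(round(dy)), int(round(dx))] > 0

    def test_blank_movie_all_degraded(self):
        from ms2burst.movie import MovieStack

        blank = np.zeros((3, 2, 40, 40))
        movie = MovieStack(ms2_channel=blank, nuclei_channel=blank.copy())
        frames = segment_movie(movie, SegmentationConfig())
        assert all(f.degraded for f in frames)
        assert all(len(f.centroids) == 0 for f in frames)

    def test_mask_override_used_verbatim(self, small_sim):
        movie, _ = small_sim
        override = np.zeros(movie.frame_shape, dtype=np.int32)
        override[10:20, 10:20] = 3
        cfg = SegmentationConfig(mask_override={0: override})
        lf = segment_movie(
            MovieStackSlice(movie, 1), cfg
        )[0]
        assert set(lf.centroids) == {3}


class MovieStackSlice:
    """First-n-frames view of a MovieStack, for cheap single-frame tests."""

    def __init__(self, movie, n):
        self.ms2_channel = movie.ms2_channel[:n]
        self.nuclei_channel = movie.nuclei_channel[:n]
        self.n_frames = n
        self.frame_interval = movie.frame_interval
        self.frame_shape = movie.frame_shape
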