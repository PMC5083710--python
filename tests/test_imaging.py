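"""Segmentation, trace extraction, resting intensity, elongation."""

import numpy as np
import pytest

from calscreen import (
    CellGeometry,
    CellROI,
    SegmentationParams,
    TraceSeries,
    average_stack,
    elongation_factor,
    extract_traces,
    make_image_stack,
    random_cell_geometries,
    resting_intensity,
    segment_cells,
)
from conftest import chord_elongation_oracle


def disk_roi(radius: float, center=(0.0, 0.0)) -> CellROI:
    r = int(np.ceil(radius)) + 1
    rr, cc = np.mgrid[-r : r + 1, -r : r + 1]
    inside = rr**2 + cc**2 <= radius**2
    return CellROI.from_pixels(
        0, rr[inside] + 100 + int(center[0]), cc[inside] + 100 + int(center[1])
    )


def ellipse_roi(a: float, b: float, theta: float = 0.0) -> CellROI:
    r = int(np.ceil(max(a, b))) + 1
    rr, cc = np.mgrid[-r : r + 1, -r : r + 1]
    u = rr * np.cos(theta) + cc * np.sin(theta)
    v = -rr * np.sin(theta) + cc * np.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return CellROI.from_pixels(0, rr[inside] + 200, cc[inside] + 200)


class TestAverageStack:
    def test_identical_frames_idempotent(self):
        frame = np.arange(12.0).reshape(3, 4)
        stack = np.stack([frame] * 5)
        assert np.array_equal(average_stack(stack), frame)

    def test_two_frame_mean(self):
        stack = np.stack([np.zeros((2, 2)), np.full((2, 2), 10.0)])
        assert np.all(average_stack(stack) == 5.0)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            average_stack(np.empty((0, 4, 4)))


class TestSegmentCells:
    def test_all_background_yields_no_rois(self):
        img = np.full((50, 50), 7.0)
        assert segment_cells(img, SegmentationParams(min_area=5, max_area=100)) == []

    def test_fifty_disks_recovered_with_subpixel_centroids(self):
        rng = np.random.default_rng(3)
        geoms = random_cell_geometries(50, frame_shape=(256, 256), rng=rng)
        traces = [TraceSeries("w", i, np.full(3, 300.0)) for i in range(50)]
        stack = make_image_stack(geoms, traces, frame_shape=(256, 256),
                                 background=5.0, noise_sd=0.0, dtype=np.float64)
        rois = segment_cells(
            average_stack(stack),
            SegmentationParams(min_area=10, max_area=2000,
                               initial_threshold_quantile=0.5),
        )
        assert len(rois) == 50
        centers = np.array([g.center for g in geoms])
        found = np.array([r.centroid for r in rois])
        # match each true center to its nearest recovered centroid
        d = np.linalg.norm(centers[:, None, :] - found[None, :, :], axis=2)
        assert np.all(d.min(axis=1) < 1.0)
        # ROI disjointness: no pixel claimed twice
        seen = set()
        for r in rois:
            px = set(zip(r.pixels[0].tolist(), r.pixels[1].tolist()))
            assert not (px & seen)
            seen |= px

    def test_touching_cells_split_by_iterative_rethresholding(self):
        # Two bright 10x10 plateaus joined by a dimmer bridge merge at
        # the global threshold; the local re-threshold separates them.
        img = np.zeros((40, 50))
        img[15:25, 10:20] = 200.0
        img[15:25, 23:33] = 200.0
        img[18:22, 20:23] = 60.0  # bridge
        # brute-force oracle: some higher threshold yields exactly two
        # in-bounds components
        from scipy import ndimage

        split_exists = any(
            ndimage.label(img > thr)[1] == 2 for thr in range(0, 200, 5)
        )
        assert split_exists
        rois = segment_cells(
            img,
            SegmentationParams(min_area=20, max_area=150,
                               initial_threshold_quantile=0.5,
                               threshold_step=10.0),
        )
        assert len(rois) == 2
        assert all(20 <= r.area <= 150 for r in rois)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SegmentationParams(min_area=100, max_area=50)
        with pytest.raises(ValueError):
            SegmentationParams(initial_threshold_quantile=1.5)


class TestExtractTraces:
    def _one_cell_stack(self, values, noise_sd=0.0, seed=0):
        geom = CellGeometry((32.0, 32.0), (8.0, 8.0))
        trace = TraceSeries("w", 0, np.asarray(values, float))
        stack = make_image_stack([geom], [trace], frame_shape=(64, 64),
                                 background=2.0, noise_sd=noise_sd, seed=seed,
                                 dtype=np.float64)
        rr, cc = np.nonzero(geom.mask((64, 64)))
        roi = CellROI.from_pixels(0, rr, cc)
        return stack, roi, trace

    def test_constant_cell_constant_trace(self):
        stack, roi, _ = self._one_cell_stack([42.0, 42.0, 42.0])
        (tr,) = extract_traces(stack, [roi])
        assert np.allclose(tr.values, 42.0)

    def test_noise_free_recovery_is_exact(self):
        values = np.linspace(100.0, 400.0, 6)
        stack, roi, truth = self._one_cell_stack(values)
        (tr,) = extract_traces(stack, [roi])
        assert np.allclose(tr.values, truth.values, rtol=0, atol=1e-9)

    def test_extraction_commutes_with_averaging(self):
        values = np.linspace(100.0, 400.0, 6)
        stack, roi, _ = self._one_cell_stack(values, noise_sd=5.0, seed=4)
        (tr,) = extract_traces(stack, [roi])
        avg = average_stack(stack)
        assert tr.values.mean() == pytest.approx(avg[roi.pixels].mean(), rel=1e-12)

    def test_noise_attenuated_by_mask_area(self):
        sigma = 8.0
        values = np.full(200, 150.0)
        stack, roi, truth = self._one_cell_stack(values, noise_sd=sigma, seed=9)
        (tr,) = extract_traces(stack, [roi])
        dev = np.std(tr.values - truth.values)
        assert dev == pytest.approx(sigma / np.sqrt(roi.area), rel=0.25)

    def test_out_of_bounds_mask_rejected(self):
        stack = np.zeros((2, 10, 10))
        roi = CellROI.from_pixels(0, np.array([9, 10]), np.array([2, 3]))
        with pytest.raises(ValueError, match="bounds"):
            extract_traces(stack, [roi])


class TestRestingIntensity:
    def test_single_uniform_cell(self):
        stack = np.full((3, 20, 20), 420.0)
        roi = CellROI.from_pixels(0, np.arange(5, 10), np.arange(5, 10))
        per_cell, well = resting_intensity(stack, [roi])
        assert per_cell[0] == pytest.approx(420.0)
        assert well == pytest.approx(420.0)

    def test_well_mean_of_two_cells(self):
        stack = np.zeros((2, 20, 40))
        stack[0, :, :20] = 400.0
        stack[0, :, 20:] = 440.0
        r1 = CellROI.from_pixels(0, np.array([5, 5]), np.array([5, 6]))
        r2 = CellROI.from_pixels(1, np.array([5, 5]), np.array([25, 26]))
        _, well = resting_intensity(stack, [r1, r2])
        assert well == pytest.approx(420.0)

    def test_no_rois_is_missing_not_zero(self):
        per_cell, well = resting_intensity(np.zeros((1, 5, 5)), [])
        assert per_cell.size == 0
        assert well is None


class TestElongationFactor:
    def test_disk_scores_one(self):
        assert elongation_factor(disk_roi(20.0)) == pytest.approx(1.0, abs=0.05)

    def test_ellipse_matches_chord_oracle(self):
        roi = ellipse_roi(40.0, 10.0)
        value = elongation_factor(roi)
        oracle = chord_elongation_oracle(*roi.pixels)
        assert value == pytest.approx(oracle, rel=0.08)
        assert value == pytest.approx(40.0 / 10.0, rel=0.10)

    def test_rotation_robust_within_five_percent(self):
        v0 = elongation_factor(ellipse_roi(40.0, 10.0))
        v30 = elongation_factor(ellipse_roi(40.0, 10.0, np.deg2rad(30)))
        assert abs(v30 - v0) / v0 < 0.05

    def test_scale_invariant_within_two_percent(self):
        v1 = elongation_factor(ellipse_roi(20.0, 5.0))
        v2 = elongation_factor(ellipse_roi(40.0, 10.0))
        assert abs(v2 - v1) / v1 < 0.02

    def test_degenerate_line_mask_warns(self):
        roi = CellROI.from_pixels(0, np.full(12, 3), np.arange(12))
        with pytest.warns(UserWarning, match="degenerate"):
            value = elongation_factor(roi)
        assert np.isfinite(value)
        assert roi.degenerate

    def test_tiny_mask_rejected(self):
        roi = CellROI.from_pixels(0, np.array([0, 0]), np.array([0, 1]))
        with pytest.raises(ValueError):
            elongation_factor(roi)
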