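import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from echoblob.blob import (
    ThresholdSet,
    binarize,
    cohort_metrics,
    compute_echointensity,
    frame_report,
    label_blobs,
    reference_thresholds,
    subject_report,
)
from echoblob.synth import simulate_cohort_in_memory
from echoblob.types import RoiMask

from .conftest import TEST_SIZE, full_mask, make_frame, make_scan

THRESHOLDS = ThresholdSet(t95=100.0, t99=150.0, source_n_pixels=1000)


def flood_fill_components(binary, connectivity):
    """Independent oracle: stack-based flood fill, returns set of frozensets."""
    binary = np.asarray(binary) != 0
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    rows, cols = binary.shape
    for r in range(rows):
        for c in range(cols):
            if binary[r, c] and not seen[r, c]:
                comp, stack = set(), [(r, c)]
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    comp.add((rr, cc))
                    for dr, dc in nbrs:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < rows and 0 <= nc < cols and binary[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                comps.append(frozenset(comp))
    return set(comps)


class TestEchointensity:
    def test_constant_frame(self):
        f = make_frame(np.full((32, 32), 100))
        assert compute_echointensity(f, full_mask(f)) == 100.0

    def test_forced_arithmetic(self):
        f = make_frame(np.array([[0, 255], [100, 45]]))
        assert compute_echointensity(f, full_mask(f)) == pytest.approx(100.0)

    def test_roi_restriction(self):
        f = make_frame(np.array([[10, 200], [200, 10]]))
        roi = RoiMask.from_array(np.array([[True, False], [False, False]]), f)
        assert compute_echointensity(f, roi) == 10.0

    def test_shape_mismatch(self):
        f = make_frame(np.zeros((4, 4)))
        roi = full_mask(make_frame(np.zeros((4, 5))))
        with pytest.raises(ValueError, match="does not match"):
            compute_echointensity(f, roi)


class TestReferenceThresholds:
    def test_degenerate_distribution(self):
        scan = make_scan("h1", "healthy", [np.full((10, 10), 42)] * 3)
        ts = reference_thresholds([scan])
        assert ts.t95 == ts.t99 == 42.0

    def test_linear_interpolation_oracle(self):
        # pooled values exactly 1..100 spread over three frames
        values = np.arange(1, 101, dtype=np.uint8)
        frames = [values[:34].reshape(1, -1), values[34:67].reshape(1, -1), values[67:].reshape(1, -1)]
        # pad to reach the 100-pixel pooled floor is unnecessary: exactly 100 values
        scan = make_scan("h1", "healthy", frames)
        ts = reference_thresholds([scan])
        assert ts.t95 == pytest.approx(95.05)
        assert ts.t99 == pytest.approx(99.01)
        assert ts.source_n_pixels == 100

    def test_monotone_and_pooling_invariance(self, small_cohort):
        scans, _ = small_cohort
        healthy = [s for s in scans if s.group == "healthy"]
        ts = reference_thresholds(healthy)
        assert ts.t95 <= ts.t99
        ts_rev = reference_thresholds(healthy[::-1])
        assert (ts.t95, ts.t99) == (ts_rev.t95, ts_rev.t99)

    def test_no_healthy_subjects(self):
        with pytest.raises(ValueError, match="no healthy"):
            reference_thresholds([])

    def test_rejects_non_healthy(self):
        scan = make_scan("p1", "fm", [np.full((10, 10), 42)] * 3)
        with pytest.raises(ValueError, match="non-healthy"):
            reference_thresholds([scan])

    def test_pooled_floor(self):
        scan = make_scan("h1", "healthy", [np.full((3, 3), 9)] * 3)
        with pytest.raises(ValueError, match="below floor"):
            reference_thresholds([scan])


class TestBinarize:
    def test_threshold_zero_equals_roi(self):
        f = make_frame(np.random.default_rng(0).integers(0, 256, (16, 16)))
        roi = full_mask(f)
        assert (binarize(f, roi, 0) == roi.mask.astype(np.uint8)).all()

    def test_above_max_all_zero(self):
        f = make_frame(np.full((8, 8), 255))
        assert binarize(f, full_mask(f), 255.5).sum() == 0

    def test_forced_case(self):
        f = make_frame(np.array([[10, 200], [200, 10]]))
        assert (binarize(f, full_mask(f), 100) == np.array([[0, 1], [1, 0]])).all()

    def test_ties_included_as_bright(self):
        f = make_frame(np.full((4, 4), 100))
        assert binarize(f, full_mask(f), 100).all()

    def test_outside_roi_always_zero(self):
        f = make_frame(np.full((4, 4), 255))
        roi = RoiMask.from_array(np.eye(4, dtype=bool), f)
        out = binarize(f, roi, 0)
        assert (out == np.eye(4)).all()


class TestLabelBlobs:
    def test_empty(self):
        assert label_blobs(np.zeros((5, 5))) == []

    def test_full(self):
        blobs = label_blobs(np.ones((6, 7)))
        assert len(blobs) == 1
        assert blobs[0].size_px == 42

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_diagonal_pair(self, connectivity):
        binary = np.array([[1, 0], [0, 1]])
        blobs = label_blobs(binary, connectivity)
        assert len(blobs) == (2 if connectivity == 4 else 1)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_flood_fill_oracle_small(self, connectivity):
        rng = np.random.default_rng(11)
        for _ in range(50):
            binary = rng.random((20, 20)) < 0.4
            blobs = label_blobs(binary, connectivity)
            oracle = flood_fill_components(binary, connectivity)
            assert len(blobs) == len(oracle)
            assert sorted(b.size_px for b in blobs) == sorted(len(c) for c in oracle)
            assert sum(b.size_px for b in blobs) == int(binary.sum())

    def test_raster_label_order(self):
        binary = np.zeros((5, 5), dtype=int)
        binary[4, 0] = 1  # later in raster order
        binary[0, 4] = 1  # earlier
        blobs = label_blobs(binary, 8)
        assert [b.centroid for b in blobs] == [(0.0, 4.0), (4.0, 0.0)]

    def test_bad_connectivity(self):
        with pytest.raises(ValueError, match="connectivity"):
            label_blobs(np.ones((3, 3)), 6)

    @settings(max_examples=30, deadline=None)
    @given(hnp.arrays(dtype=bool, shape=(12, 12)), st.sampled_from([4, 8]))
    def test_conservation_property(self, binary, connectivity):
        blobs = label_blobs(binary, connectivity)
        assert sum(b.size_px for b in blobs) == int(binary.sum())


class TestFrameReport:
    def test_unit_pixel_area(self):
        rng = np.random.default_rng(2)
        f = make_frame(rng.integers(0, 256, (20, 20)), spacing=(1.0, 1.0))
        roi = full_mask(f)
        rep = frame_report(f, roi, THRESHOLDS)
        for lvl in (95, 99):
            assert rep.metrics[f"total_blob_size_per_mm2_p{lvl}"] == pytest.approx(
                rep.metrics[f"total_blob_size_px_p{lvl}"] / roi.n_pixels
            )
            assert rep.metrics[f"total_blob_size_mm2_p{lvl}"] == pytest.approx(
                rep.metrics[f"total_blob_size_px_p{lvl}"]
            )

    def test_single_bright_square(self):
        px = np.full((20, 20), 30)
        px[5:8, 5:8] = 255
        f = make_frame(px)
        rep = frame_report(f, full_mask(f), ThresholdSet(t95=200, t99=250, source_n_pixels=400))
        assert rep.metrics["blob_count_p95"] == 1
        assert rep.metrics["total_blob_size_px_p95"] == 9

    def test_threshold_monotonicity(self, small_cohort):
        scans, _ = small_cohort
        frame, roi = scans[0].frames[0]
        ts = reference_thresholds([s for s in scans if s.group == "healthy"])
        rep = frame_report(frame, roi, ts)
        assert rep.metrics["total_blob_size_px_p99"] <= rep.metrics["total_blob_size_px_p95"]
        assert 0 <= rep.echointensity <= 255
        assert rep.metrics["total_blob_size_px_p95"] <= roi.n_pixels

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        px = rng.integers(0, 256, (20, 20))
        f1 = make_frame(px, spacing=(0.4, 0.4))
        f2 = make_frame(px, spacing=(0.8, 0.8))
        r1 = frame_report(f1, full_mask(f1), THRESHOLDS)
        r2 = frame_report(f2, full_mask(f2), THRESHOLDS)
        assert r2.roi_area_mm2 == pytest.approx(4 * r1.roi_area_mm2)
        for lvl in (95, 99):
            assert r2.metrics[f"blob_count_p{lvl}"] == r1.metrics[f"blob_count_p{lvl}"]
            assert r2.metrics[f"total_blob_size_px_p{lvl}"] == r1.metrics[f"total_blob_size_px_p{lvl}"]
            assert r2.metrics[f"blob_count_per_mm2_p{lvl}"] == pytest.approx(
                r1.metrics[f"blob_count_per_mm2_p{lvl}"] / 4
            )
            assert r2.metrics[f"total_blob_size_per_mm2_p{lvl}"] == pytest.approx(
                r1.metrics[f"total_blob_size_per_mm2_p{lvl}"] / 4
            )

    def test_min_blob_floor(self):
        px = np.full((20, 20), 30)
        px[5:8, 5:8] = 255  # 9 px blob
        px[15, 15] = 255  # isolated pixel
        f = make_frame(px)
        ts = ThresholdSet(t95=200, t99=250, source_n_pixels=400)
        default = frame_report(f, full_mask(f), ts)
        floored = frame_report(f, full_mask(f), ts, min_blob_px=2)
        assert default.metrics["blob_count_p95"] == 2
        assert floored.metrics["blob_count_p95"] == 1
        assert floored.metrics["total_blob_size_px_p95"] == 9


class TestSubjectReport:
    def test_identical_frames(self):
        px = np.random.default_rng(4).integers(0, 256, (16, 16))
        scan = make_scan("s1", "healthy", [px, px, px])
        rep = subject_report(scan, THRESHOLDS)
        frame_rep = frame_report(scan.frames[0][0], scan.frames[0][1], THRESHOLDS)
        assert rep["echointensity"] == pytest.approx(frame_rep.echointensity)
        assert rep["blob_count_p95"] == frame_rep.metrics["blob_count_p95"]

    def test_mean_aggregation_forced(self):
        rng = np.random.default_rng(5)

        def frame_with_blobs(n):
            px = np.full((30, 30), 10)
            for i in range(n):
                px[1 + 3 * i, 1] = 255
            return px

        scan = make_scan("s1", "healthy", [frame_with_blobs(2), frame_with_blobs(4), frame_with_blobs(6)])
        rep = subject_report(scan, THRESHOLDS)
        assert rep["blob_count_p95"] == pytest.approx(4.0)

    def test_frame_order_symmetry(self):
        rng = np.random.default_rng(6)
        frames = [rng.integers(0, 256, (16, 16)) for _ in range(3)]
        a = subject_report(make_scan("s", "healthy", frames), THRESHOLDS)
        b = subject_report(make_scan("s", "healthy", frames[::-1]), THRESHOLDS)
        assert a == b

    def test_metric_within_frame_range(self, small_cohort):
        scans, _ = small_cohort
        ts = reference_thresholds([s for s in scans if s.group == "healthy"])
        scan = scans[0]
        rep = subject_report(scan, ts)
        per_frame = [frame_report(f, r, ts).metrics["total_blob_size_px_p95"] for f, r in scan.frames]
        assert min(per_frame) <= rep["total_blob_size_px_p95"] <= max(per_frame)


class TestCohortMetrics:
    def test_complete_table(self, small_cohort):
        scans, cov = small_cohort
        ts = reference_thresholds([s for s in scans if s.group == "healthy"])
        table = cohort_metrics(scans, ts, covariates=cov)
        assert len(table) == 12
        assert table["blob_count_p95"].notna().all()
        assert (table.groupby("group").size() == 6).all()
        assert "csi_total" in table.columns

    def test_healthy_only_closure(self, small_cohort):
        scans, _ = small_cohort
        healthy = [s for s in scans if s.group == "healthy"]
        ts = reference_thresholds(healthy)
        table = cohort_metrics(healthy, ts)
        assert set(table["group"]) == {"healthy"}

    def test_determinism(self, paper_preset):
        kw = dict(n_per_group=2, seed=9, size=(64, 96))
        a = simulate_cohort_in_memory(
            paper_preset["healthy"], paper_preset["fm"], paper_preset["covariates"], **kw
        )
        b = simulate_cohort_in_memory(
            paper_preset["healthy"], paper_preset["fm"], paper_preset["covariates"], **kw
        )
        ts_a = reference_thresholds([s for s in a[0] if s.group == "healthy"])
        ts_b = reference_thresholds([s for s in b[0] if s.group == "healthy"])
        ta = cohort_metrics(a[0], ts_a, covariates=a[1])
        tb = cohort_metrics(b[0], ts_b, covariates=b[1])
        import pandas as pd

        pd.testing.assert_frame_equal(ta, tb)

    def test_empty_cohort(self):
        with pytest.raises(ValueError, match="empty"):
            cohort_metrics([], THRESHOLDS)
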