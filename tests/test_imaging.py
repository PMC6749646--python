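from collections import deque

import numpy as np
import pandas as pd
import pytest

from fluorplate import simulate
from fluorplate.imaging import (
    FormatError,
    FrameStack,
    assign_sample_ids,
    extract_pulse_records,
    read_dataset,
    segment_plate,
)


def brute_force_components(mask):
    """Independent 8-connectivity component count via BFS flood fill."""
    seen = np.zeros_like(mask, dtype=bool)
    count = 0
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                count += 1
                queue = deque([(r, c)])
                seen[r, c] = True
                while queue:
                    i, j = queue.popleft()
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ni, nj = i + di, j + dj
                            if (0 <= ni < h and 0 <= nj < w and mask[ni, nj]
                                    and not seen[ni, nj]):
                                seen[ni, nj] = True
                                queue.append((ni, nj))
    return count


class TestFrameStackValidation:
    @staticmethod
    def _meta(labels):
        n = len(labels)
        return pd.DataFrame({
            "pulse_index": range(n), "time_s": np.arange(n) * 60.0,
            "ppfd": [0.0] * n, "f_page": range(n), "fm_page": range(n),
            "label": labels,
        })

    def test_requires_exactly_one_dark_pulse(self):
        frames = np.ones((2, 2, 4, 4))
        with pytest.raises(ValueError, match="dark"):
            FrameStack(frames, self._meta(["dark", "dark"]))
        with pytest.raises(ValueError, match="dark"):
            FrameStack(frames, self._meta(["a", "b"]))

    def test_rejects_negative_counts_and_bad_shape(self):
        with pytest.raises(ValueError, match=">= 0"):
            FrameStack(-np.ones((1, 2, 4, 4)), self._meta(["dark"]))
        with pytest.raises(ValueError, match="shape"):
            FrameStack(np.ones((1, 3, 4, 4)), self._meta(["dark"]))


class TestReadDataset:
    def test_roundtrip_from_simulator(self, tmp_path, noiseless_plate):
        _, stack, truth = noiseless_plate
        simulate.write_dataset(stack, truth, tmp_path, dtype="float64")
        back = read_dataset(tmp_path)
        assert np.array_equal(back.frames, stack.frames)

    def test_metadata_referencing_absent_page_errors(self, tmp_path, noiseless_plate):
        _, stack, truth = noiseless_plate
        simulate.write_dataset(stack, truth, tmp_path, dtype="float64")
        meta = pd.read_csv(tmp_path / "pulses.csv")
        meta.loc[0, "fm_page"] = 999
        meta.to_csv(tmp_path / "pulses.csv", index=False)
        with pytest.raises(FormatError, match="pulse 0"):
            read_dataset(tmp_path)

    def test_extra_unreferenced_pages_warn_but_load(self, tmp_path, noiseless_plate):
        _, stack, truth = noiseless_plate
        simulate.write_dataset(stack, truth, tmp_path, dtype="float64")
        meta = pd.read_csv(tmp_path / "pulses.csv").iloc[:-1]  # drop last pulse
        meta.to_csv(tmp_path / "pulses.csv", index=False)
        with pytest.warns(RuntimeWarning, match="not referenced"):
            back = read_dataset(tmp_path)
        assert back.n_pulses == stack.n_pulses - 1

    def test_missing_files_error_with_path(self, tmp_path):
        with pytest.raises(FormatError, match=str(tmp_path)):
            read_dataset(tmp_path)


class TestSegmentPlate:
    def test_synthetic_rectangles_recovered_exactly(self, noiseless_plate):
        layout, stack, _ = noiseless_plate
        rois = segment_plate(stack.fm_dark_frame(), min_area=50)
        assert rois.n_rois == layout.n_sections == 25
        expected_area = next(iter(layout.sections.values()))[2] * \
            next(iter(layout.sections.values()))[3]
        assert set(rois.table["area_px"]) == {expected_area}

    def test_blank_frame_yields_empty_roiset_with_warning(self):
        with pytest.warns(RuntimeWarning, match="no components"):
            rois = segment_plate(np.zeros((32, 32)), threshold_method="fixed",
                                 threshold=10.0, min_area=4)
        assert rois.n_rois == 0

    def test_sections_two_pixels_apart_never_merge(self):
        frame = np.zeros((20, 30))
        frame[4:16, 2:12] = 1000.0
        frame[4:16, 14:24] = 1000.0  # gap of 2 background columns
        rois = segment_plate(frame, min_area=10, threshold_method="fixed",
                             threshold=100.0)
        assert rois.n_rois == brute_force_components(frame > 100.0) == 2

    def test_holes_are_filled(self):
        frame = np.zeros((30, 30))
        frame[5:25, 5:25] = 800.0
        frame[12:16, 12:16] = 0.0  # hole inside the section
        rois = segment_plate(frame, min_area=10, threshold_method="fixed",
                             threshold=100.0)
        assert rois.n_rois == 1
        assert rois.table["area_px"].iloc[0] == 400

    def test_min_area_filters_specks(self):
        frame = np.zeros((40, 40))
        frame[5:25, 5:25] = 800.0
        frame[30, 30] = 900.0  # single hot pixel
        rois = segment_plate(frame, min_area=10, threshold_method="fixed",
                             threshold=100.0)
        assert rois.n_rois == 1

    def test_segmentation_is_deterministic_and_count_matches_under_noise(self, fig5):
        layout = simulate.grid_layout(3, 3, (120, 120))
        params = simulate.GenotypeParams(noise_cv=0.1)
        stack, _ = simulate.render_plate(layout, params, fig5, seed=5)
        min_area = min(h * w for _, _, h, w in layout.sections.values()) // 2
        r1 = segment_plate(stack.fm_dark_frame(), min_area=min_area)
        r2 = segment_plate(stack.fm_dark_frame(), min_area=min_area)
        assert np.array_equal(r1.label_map, r2.label_map)
        assert r1.n_rois == layout.n_sections
        assert r1.table["area_px"].sum() <= stack.shape[0] * stack.shape[1]


class TestAssignSampleIds:
    def brute_force_nearest_slot(self, rois, n_rows, n_cols, shape):
        """Oracle: match centroids to the nearest grid-slot centre."""
        h, w = shape
        slots = {}
        for i in range(n_rows):
            for j in range(n_cols):
                slots[i * n_cols + j + 1] = ((i + 0.5) * h / n_rows,
                                             (j + 0.5) * w / n_cols)
        out = {}
        for _, row in rois.table.iterrows():
            cr, cc = row["centroid_row"], row["centroid_col"]
            sid = min(slots, key=lambda s: (slots[s][0] - cr) ** 2
                      + (slots[s][1] - cc) ** 2)
            out[int(row["label"])] = sid
        return out

    def test_regular_grid_reading_order(self, noiseless_plate):
        layout, stack, _ = noiseless_plate
        rois = segment_plate(stack.fm_dark_frame(), min_area=50)
        rois = assign_sample_ids(rois, 5, 5)
        by_centroid = rois.table.sort_values(["centroid_row", "centroid_col"])
        assert list(by_centroid["sample_id"]) == list(range(1, 26))

    def test_single_roi_gets_id_one(self):
        frame = np.zeros((30, 30))
        frame[5:15, 5:15] = 500.0
        rois = segment_plate(frame, min_area=10, threshold_method="fixed",
                             threshold=100.0)
        rois = assign_sample_ids(rois, 3, 3)
        assert list(rois.table["sample_id"]) == [1]

    def test_jittered_grid_matches_nearest_slot_oracle(self, fig5):
        layout = simulate.grid_layout(4, 4, (160, 160), jitter_px=4, seed=21)
        stack, _ = simulate.render_plate(
            layout, simulate.GenotypeParams(), fig5, seed=21
        )
        rois = segment_plate(stack.fm_dark_frame(), min_area=50)
        rois = assign_sample_ids(rois, 4, 4)
        oracle = self.brute_force_nearest_slot(rois, 4, 4, stack.shape)
        got = dict(zip(rois.table["label"].astype(int), rois.table["sample_id"]))
        assert got == oracle

    def test_too_many_rois_for_grid_errors(self, noiseless_plate):
        _, stack, _ = noiseless_plate
        rois = segment_plate(stack.fm_dark_frame(), min_area=50)
        with pytest.raises(ValueError, match="min_area"):
            assign_sample_ids(rois, 2, 2)


class TestExtractPulseRecords:
    def test_noiseless_means_equal_ground_truth(self, noiseless_plate):
        layout, stack, truth = noiseless_plate
        rois = assign_sample_ids(segment_plate(stack.fm_dark_frame(), min_area=50),
                                 5, 5)
        records = extract_pulse_records(stack, rois)
        gt = truth.per_pulse
        merged = records.merge(
            gt, on=["sample_id", "time_s"], suffixes=("", "_true")
        )
        assert len(merged) == len(gt) == 25 * 36
        np.testing.assert_allclose(merged["f_mean"], merged["f_prime"], rtol=1e-12)
        np.testing.assert_allclose(merged["fm_mean"], merged["fm_prime"], rtol=1e-12)

    def test_single_pixel_roi_mean_is_pixel_value(self):
        frames = np.zeros((1, 2, 4, 4))
        frames[0, 0, 1, 1] = 123.0
        frames[0, 1, 1, 1] = 456.0
        meta = pd.DataFrame({"pulse_index": [0], "time_s": [0.0], "ppfd": [0.0],
                             "f_page": [0], "fm_page": [1], "label": ["dark"]})
        stack = FrameStack(frames, meta)
        label_map = np.zeros((4, 4), dtype=int)
        label_map[1, 1] = 1
        from fluorplate.imaging import ROISet
        rois = ROISet(label_map, pd.DataFrame([{
            "label": 1, "sample_id": 1, "centroid_row": 1.0, "centroid_col": 1.0,
            "area_px": 1}]))
        rec = extract_pulse_records(stack, rois)
        assert rec["f_mean"].iloc[0] == 123.0 and rec["fm_mean"].iloc[0] == 456.0

    def test_swapped_frame_pair_is_flagged(self, noiseless_plate):
        layout, stack, _ = noiseless_plate
        meta = stack.metadata.copy()
        # swap the F'/Fm' page assignment of pulse 1
        meta.loc[1, ["f_page", "fm_page"]] = meta.loc[1, ["fm_page", "f_page"]].values
        frames = stack.frames.copy()
        frames[1] = frames[1, ::-1]
        swapped = FrameStack(frames, meta)
        rois = assign_sample_ids(segment_plate(swapped.fm_dark_frame(), min_area=50),
                                 5, 5)
        records = extract_pulse_records(swapped, rois)
        t1 = stack.metadata["time_s"].iloc[1]
        flagged = records[records["time_s"] == t1]
        assert (flagged["flags"] == "fm_lt_f").all()
        assert (records[records["time_s"] != t1]["flags"] == "").all()

    def test_geometry_mismatch_errors(self, noiseless_plate):
        _, stack, _ = noiseless_plate
        from fluorplate.imaging import ROISet
        rois = ROISet(np.zeros((10, 10), dtype=int),
                      pd.DataFrame(columns=["label", "sample_id", "centroid_row",
                                            "centroid_col", "area_px"]))
        with pytest.raises(ValueError, match="shape"):
            extract_pulse_records(stack, rois)
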