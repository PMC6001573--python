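import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from skimage.draw import disk

from gliaquant.errors import InvalidShapeError, UndefinedMetricError
from gliaquant.motility import (
    CellTrack,
    SegmentationParams,
    TimeLapseMovie,
    analyze_movie,
    classify_morphology,
    compute_cell_speed,
    compute_membrane_change,
    compute_morphing_speed,
    count_state_transitions,
    segment_frame,
    shape_from_mask,
    summarize_movie,
    track_cells,
)
from gliaquant.motility.metrics import metrics_for_track
from gliaquant.motility.shapes import CellShape
from gliaquant.synth.movie import _Branch, _Cell, _render_cell

from conftest import match_tracks_to_truth


def _disk_frame(shape, centers, radius=10.0, value=1.0):
    frame = np.zeros(shape, dtype=float)
    for c in centers:
        rr, cc = disk(c, radius, shape=shape)
        frame[rr, cc] = value
    return frame


def _square_shape(frame_index, area_px, perim_px, centroid=(0.0, 0.0), state="roundish"):
    """CellShape with prescribed A/p in px units (pixel size 1 um)."""
    mask = np.ones((1, 1), dtype=bool)
    s = CellShape.__new__(CellShape)
    s.frame_index = frame_index
    s.mask = mask
    s.area_um2 = float(area_px)
    s.perimeter_um = float(perim_px)
    s.centroid_um = centroid
    s.state = state
    s.n_ramifications = 0
    return s


class TestSegmentation:
    def test_uniform_frame_empty(self):
        assert segment_frame(np.zeros((64, 64))) == []

    def test_single_disk_pixel_count_oracle(self):
        shape = (128, 128)
        rr, cc = disk((64, 64), 10.0, shape=shape)
        frame = np.zeros(shape)
        frame[rr, cc] = 1.0
        masks = segment_frame(frame, SegmentationParams(smoothing_sigma_px=0))
        assert len(masks) == 1
        assert masks[0].sum() == rr.size  # exact rasterized-disk pixel count

    def test_two_disks_two_masks(self):
        frame = _disk_frame((128, 256), [(64, 64), (64, 192)])
        masks = segment_frame(frame, SegmentationParams(smoothing_sigma_px=0))
        assert len(masks) == 2

    def test_min_area_filter(self):
        frame = _disk_frame((64, 64), [(32, 32)], radius=3.0)
        assert segment_frame(frame, SegmentationParams(smoothing_sigma_px=0, min_object_area_px=100)) == []


class TestClassification:
    def test_perfect_disk_roundish(self):
        mask = np.zeros((64, 64), dtype=bool)
        rr, cc = disk((32, 32), 12.0)
        mask[rr, cc] = True
        state, n = classify_morphology(mask)
        assert (state, n) == ("roundish", 0)

    def test_one_protrusion_still_roundish(self):
        # boundary rule: polarized requires at least two ramifications
        cell = _Cell(center=np.array([40.0, 40.0]), branches=[_Branch(0.0, 25.0)], tile=(0, 0, 0, 0))
        mask = _render_cell(cell, (96, 96))
        state, n = classify_morphology(mask)
        assert n == 1
        assert state == "roundish"

    def test_three_branches_polarized(self):
        cell = _Cell(
            center=np.array([48.0, 48.0]),
            branches=[_Branch(a, 22.0) for a in (0.3, 2.4, 4.5)],
            tile=(0, 0, 0, 0),
        )
        mask = _render_cell(cell, (96, 96))
        state, n = classify_morphology(mask)
        assert state == "polarized"
        assert n == 3  # skeleton-endpoint count oracle on the rendered shape

    def test_tiny_mask_invalid(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[8, 8] = True
        with pytest.raises(InvalidShapeError):
            classify_morphology(mask)


class TestTracking:
    def test_static_single_cell(self):
        frames = [_disk_frame((64, 64), [(32, 32)]) for _ in range(10)]
        shapes = [[shape_from_mask(m, f, 1.0) for m in segment_frame(fr, SegmentationParams(0))] for f, fr in enumerate(frames)]
        tracks = track_cells(shapes)
        assert len(tracks) == 1
        assert len(tracks[0]) == 10

    def test_planted_cells_hungarian_oracle(self, small_movie, noise_free_seg):
        spec, movie, gt = small_movie
        tracks, _ = analyze_movie(movie, seg_params=noise_free_seg, max_step_um=6.0)
        assert len(tracks) == spec.n_cells
        # oracle: optimal assignment between track starts and true centroids
        starts = np.array([t.centroids_um[0] for t in tracks]) / spec.pixel_size_um
        truth0 = gt.table[gt.table.frame == 0][["x_px", "y_px"]].to_numpy()
        cost = np.linalg.norm(starts[:, None, :] - truth0[None, :, :], axis=2)
        rows, cols = linear_sum_assignment(cost)
        assert cost[rows, cols].max() < 2.0  # every track starts on a true cell
        greedy = match_tracks_to_truth(tracks, gt, spec.pixel_size_um)
        assert sorted(greedy.values()) == sorted(cols.tolist())

    def test_disappearing_cell_ends_track(self):
        frames = [_disk_frame((64, 64), [(32, 32)]) for _ in range(5)]
        frames += [np.zeros((64, 64)) for _ in range(3)]
        shapes = [[shape_from_mask(m, f, 1.0) for m in segment_frame(fr, SegmentationParams(0))] for f, fr in enumerate(frames)]
        tracks = track_cells(shapes)
        assert len(tracks) == 1
        assert tracks[0].frame_indices.max() == 4


class TestMetrics:
    def test_static_track_zero_speed(self):
        shapes = [_square_shape(f, 100, 40, centroid=(5.0, 5.0)) for f in range(5)]
        assert compute_cell_speed(CellTrack(0, shapes), 60.0) == 0.0

    def test_speed_unit_arithmetic(self):
        # 2 px/frame at 1 um/px and 60 s interval -> 2 um/min
        shapes = [_square_shape(f, 100, 40, centroid=(2.0 * f, 0.0)) for f in range(10)]
        assert compute_cell_speed(CellTrack(0, shapes), 60.0) == pytest.approx(2.0)

    def test_speed_random_walk_brute_force(self):
        rng = np.random.default_rng(0)
        pts = np.cumsum(rng.normal(0, 1.5, (100, 2)), axis=0)
        shapes = [_square_shape(f, 100, 40, centroid=tuple(p)) for f, p in enumerate(pts)]
        speed = compute_cell_speed(CellTrack(0, shapes), 30.0)
        brute = np.mean(np.linalg.norm(np.diff(pts, axis=0), axis=1)) / 0.5
        assert speed == pytest.approx(brute, abs=1e-9)

    def test_short_track_error(self):
        with pytest.raises(UndefinedMetricError):
            compute_cell_speed(CellTrack(0, [_square_shape(0, 100, 40)]), 60.0)

    def test_membrane_change_identical_masks_zero(self):
        shapes = [_square_shape(f, 100, 40) for f in range(5)]
        series, mean = compute_membrane_change(CellTrack(0, shapes))
        assert np.allclose(series, 0.0)
        assert mean == 0.0

    def test_membrane_change_hand_arithmetic(self):
        # area 100 -> 120 px^2, perimeters 40 and 44 px, 1 um/px: 20/42
        shapes = [_square_shape(0, 100, 40), _square_shape(1, 120, 44)]
        series, mean = compute_membrane_change(CellTrack(0, shapes))
        assert series[0] == pytest.approx(20.0 / 42.0)
        assert mean == pytest.approx(20.0 / 42.0)

    def test_membrane_change_symmetric_oscillation(self):
        shapes = [
            _square_shape(f, 100 if f % 2 == 0 else 120, 40 if f % 2 == 0 else 44)
            for f in range(8)
        ]
        series, _ = compute_membrane_change(CellTrack(0, shapes))
        assert np.allclose(series, series[0])

    def test_morphing_constant_state(self):
        shapes = [_square_shape(f, 100, 40, state="roundish") for f in range(60)]
        rate, n = compute_morphing_speed(CellTrack(0, shapes), 60.0)
        assert (rate, n) == (0.0, 0)

    def test_morphing_r_p_r_over_one_hour(self):
        # 3 frames spanning 1 h: R,P,R -> 2 transitions/h
        shapes = [
            _square_shape(0, 100, 40, state="roundish"),
            _square_shape(1, 100, 40, state="polarized"),
            _square_shape(2, 100, 40, state="roundish"),
        ]
        rate, n = compute_morphing_speed(CellTrack(0, shapes), 1800.0)
        assert n == 2
        assert rate == pytest.approx(2.0)

    def test_morphing_random_sequence_brute_force(self):
        rng = np.random.default_rng(12)
        states = ["roundish" if b else "polarized" for b in rng.integers(0, 2, 50)]
        brute = sum(a != b for a, b in zip(states[:-1], states[1:]))
        assert count_state_transitions(states) == brute

    def test_morphing_per_hour_invariant_to_interval_relabeling(self):
        states = ["roundish", "polarized", "roundish", "roundish", "polarized"]
        shapes = [_square_shape(f, 100, 40, state=s) for f, s in enumerate(states)]
        r30, n30 = compute_morphing_speed(CellTrack(0, shapes), 30.0)
        r60, n60 = compute_morphing_speed(CellTrack(0, shapes), 60.0)
        assert n30 == n60
        assert r30 == pytest.approx(2 * r60)  # same count, half the duration

    def test_debounce_merges_short_runs(self):
        states = ["roundish"] * 5 + ["polarized"] + ["roundish"] * 5
        assert count_state_transitions(states, debounce_frames=1) == 2
        assert count_state_transitions(states, debounce_frames=2) == 0


class TestSummary:
    def test_single_cell_summary(self):
        shapes = [_square_shape(f, 100, 40, centroid=(float(f), 0.0)) for f in range(5)]
        m = metrics_for_track(CellTrack(3, shapes), 60.0)
        per_cell, summary = summarize_movie([m])
        assert len(per_cell) == 1
        row = summary[summary.metric == "cell_speed_um_min"].iloc[0]
        assert row["mean"] == pytest.approx(m.cell_speed_um_min)
        assert row["sd"] == 0.0
        assert row["n"] == 1

    def test_two_cell_mean_sd(self):
        tracks = []
        for speed_px in (1.0, 3.0):
            shapes = [_square_shape(f, 100, 40, centroid=(speed_px * f, 0.0)) for f in range(5)]
            tracks.append(CellTrack(int(speed_px), shapes))
        metrics = [metrics_for_track(t, 60.0) for t in tracks]
        _, summary = summarize_movie(metrics)
        row = summary[summary.metric == "cell_speed_um_min"].iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sd"] == pytest.approx(np.sqrt(2.0))


class TestScaleConsistency:
    def test_doubling_pixel_size_doubles_linear_metrics(self, small_movie, noise_free_seg):
        spec, movie, _ = small_movie
        doubled = TimeLapseMovie(movie.frames, movie.pixel_size_um * 2, movie.frame_interval_s)
        _, m1 = analyze_movie(movie, seg_params=noise_free_seg, max_step_um=6.0)
        _, m2 = analyze_movie(doubled, seg_params=noise_free_seg, max_step_um=12.0)
        s1 = sorted(m.cell_speed_um_min for m in m1)
        s2 = sorted(m.cell_speed_um_min for m in m2)
        assert np.allclose(np.array(s2), 2 * np.array(s1))
        d1 = sorted(m.membrane_change_um for m in m1)
        d2 = sorted(m.membrane_change_um for m in m2)
        assert np.allclose(np.array(d2), 2 * np.array(d1))
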