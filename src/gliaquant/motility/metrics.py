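"""The three motility statistics and the per-movie summary.

cell_speed:        mean centroid step length per unit time, um/min.
membrane change:   |dA| between consecutive frames over the mean of the two
                   frames' perimeters, um; mean over frame pairs.
morphing speed:    roundish <-> polarized transitions per hour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import InvalidShapeError, UndefinedMetricError
from .movie import TimeLapseMovie
from .segment import SegmentationParams, segment_frame
from .shapes import shape_from_mask
from .track import CellTrack, track_cells


@dataclass
class MotilityMetrics:
    cell_id: int
    n_frames: int
    cell_speed_um_min: float
    membrane_change_um: float       # mean |dA|/p over frame pairs
    membrane_change_series_um: np.ndarray
    morphing_speed_per_h: float
    n_transitions: int


def compute_cell_speed(track: CellTrack, frame_interval_s: float) -> float:
    """Mean Euclidean centroid displacement per frame pair, in um/min."""
    if len(track) < 2:
        raise UndefinedMetricError("cell speed undefined for a track shorter than 2 frames")
    steps = np.linalg.norm(np.diff(track.centroids_um, axis=0), axis=1)
    return float(steps.mean() / (frame_interval_s / 60.0))


def compute_membrane_change(track: CellTrack) -> tuple[np.ndarray, float]:
    """Per-pair |dA| / mean(p_t, p_t+1) series (um) and its mean.

    The absolute difference makes extension and retraction both count; the
    divisor is the mean of the two frames' perimeters.
    """
    if len(track) < 2:
        raise UndefinedMetricError("membrane change undefined for a track shorter than 2 frames")
    a = track.areas_um2
    p = track.perimeters_um
    if np.any(p <= 0):
        raise InvalidShapeError("zero perimeter in track")
    series = np.abs(np.diff(a)) / (0.5 * (p[:-1] + p[1:]))
    return series, float(series.mean())


def count_state_transitions(states: list[str], debounce_frames: int = 1) -> int:
    """Number of state changes; with debounce d > 1 a new state must persist
    for at least d frames before it counts (runs shorter than d are merged
    into the preceding state)."""
    if debounce_frames > 1:
        filtered: list[str] = []
        i = 0
        while i < len(states):
            j = i
            while j < len(states) and states[j] == states[i]:
                j += 1
            run = j - i
            if run >= debounce_frames or not filtered:
                filtered.extend([states[i]] * run)
            else:
                filtered.extend([filtered[-1]] * run)
            i = j
        states = filtered
    return int(sum(a != b for a, b in zip(states[:-1], states[1:])))


def compute_morphing_speed(
    track: CellTrack, frame_interval_s: float, debounce_frames: int = 1
) -> tuple[float, int]:
    """(transitions per hour, raw transition count) for one track."""
    n = count_state_transitions(track.states, debounce_frames)
    duration_h = (len(track) - 1) * frame_interval_s / 3600.0
    if duration_h <= 0:
        raise UndefinedMetricError("morphing speed undefined for a single-frame track")
    return n / duration_h, n


def metrics_for_track(
    track: CellTrack, frame_interval_s: float, debounce_frames: int = 1
) -> MotilityMetrics:
    series, mean_dap = compute_membrane_change(track)
    morph, n_trans = compute_morphing_speed(track, frame_interval_s, debounce_frames)
    return MotilityMetrics(
        cell_id=track.cell_id,
        n_frames=len(track),
        cell_speed_um_min=compute_cell_speed(track, frame_interval_s),
        membrane_change_um=mean_dap,
        membrane_change_series_um=series,
        morphing_speed_per_h=morph,
        n_transitions=n_trans,
    )


def analyze_movie(
    movie: TimeLapseMovie,
    seg_params: SegmentationParams = SegmentationParams(),
    max_step_um: float = 20.0,
    min_track_length: int = 2,
    min_branch_length_px: float = 5.0,
    resample_stride: int = 1,
) -> tuple[list[CellTrack], list[MotilityMetrics]]:
    """Full pipeline: segment every frame, track, compute the three metrics.

    ``resample_stride=2`` reproduces a 1 frame/min analysis cadence from a
    30 s acquisition cadence.
    """
    if resample_stride > 1:
        movie = movie.resampled(resample_stride)
    shapes_per_frame = []
    for f in range(movie.n_frames):
        masks = segment_frame(movie.frames[f], seg_params)
        shapes_per_frame.append(
            [
                shape_from_mask(
                    m,
                    f,
                    movie.pixel_size_um,
                    min_branch_length_px=min_branch_length_px,
                    min_object_area_px=seg_params.min_object_area_px,
                )
                for m in masks
            ]
        )
    tracks = track_cells(shapes_per_frame, max_step_um=max_step_um, min_track_length=max(2, min_track_length))
    metrics = [metrics_for_track(t, movie.frame_interval_s) for t in tracks]
    return tracks, metrics


def summarize_movie(metrics: list[MotilityMetrics]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(per-cell tidy table, group summary with mean / SD / n per metric)."""
    if not metrics:
        raise UndefinedMetricError("summarize_movie needs at least one track")
    per_cell = pd.DataFrame(
        {
            "cell_id": [m.cell_id for m in metrics],
            "n_frames": [m.n_frames for m in metrics],
            "cell_speed_um_min": [m.cell_speed_um_min for m in metrics],
            "mean_dA_over_p_um": [m.membrane_change_um for m in metrics],
            "morphing_speed_per_h": [m.morphing_speed_per_h for m in metrics],
        }
    )
    cols = ["cell_speed_um_min", "mean_dA_over_p_um", "morphing_speed_per_h"]
    summary = pd.DataFrame(
        {
            "metric": cols,
            "mean": [per_cell[c].mean() for c in cols],
            "sd": [per_cell[c].std(ddof=1) if len(per_cell) > 1 else 0.0 for c in cols],
            "n": len(per_cell),
        }
    )
    return per_cell, summary
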