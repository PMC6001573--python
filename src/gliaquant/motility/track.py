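"""Greedy nearest-centroid linking of per-frame masks into tracks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .shapes import CellShape


@dataclass
class CellTrack:
    cell_id: int
    shapes: list[CellShape] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = self.frame_indices
        if idx.size > 1 and np.any(np.diff(idx) <= 0):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.shapes)

    @property
    def frame_indices(self) -> np.ndarray:
        return np.array([s.frame_index for s in self.shapes], dtype=int)

    @property
    def centroids_um(self) -> np.ndarray:
        return np.array([s.centroid_um for s in self.shapes], dtype=float)

    @property
    def areas_um2(self) -> np.ndarray:
        return np.array([s.area_um2 for s in self.shapes], dtype=float)

    @property
    def perimeters_um(self) -> np.ndarray:
        return np.array([s.perimeter_um for s in self.shapes], dtype=float)

    @property
    def states(self) -> list[str]:
        return [s.state for s in self.shapes]


def track_cells(
    shapes_per_frame: list[list[CellShape]],
    max_step_um: float = 20.0,
    min_track_length: int = 2,
) -> list[CellTrack]:
    """Link shapes across frames by nearest centroid.

    Greedy globally-shortest-link assignment per frame pair with a maximum
    step distance; unlinked shapes start new tracks; tracks shorter than
    ``min_track_length`` are dropped. Distance ties break toward the larger
    mask-overlap pair, then the lower existing cell_id, for determinism.
    """
    if len(shapes_per_frame) < 2:
        raise ValueError("tracking needs at least 2 frames of masks")

    tracks: list[CellTrack] = []
    active: list[CellTrack] = []
    next_id = 0

    for shapes in shapes_per_frame:
        if not active:
            for s in shapes:
                t = CellTrack(next_id, [s])
                next_id += 1
                active.append(t)
                tracks.append(t)
            continue

        candidates = []
        for ti, t in enumerate(active):
            cx, cy = t.shapes[-1].centroid_um
            for si, s in enumerate(shapes):
                d = float(np.hypot(s.centroid_um[0] - cx, s.centroid_um[1] - cy))
                if d <= max_step_um:
                    overlap = int(np.logical_and(t.shapes[-1].mask, s.mask).sum())
                    candidates.append((d, -overlap, t.cell_id, ti, si))
        candidates.sort()

        used_tracks: set[int] = set()
        used_shapes: set[int] = set()
        assigned: dict[int, int] = {}
        for d, _neg_overlap, _cid, ti, si in candidates:
            if ti in used_tracks or si in used_shapes:
                continue
            used_tracks.add(ti)
            used_shapes.add(si)
            assigned[si] = ti

        new_active: list[CellTrack] = []
        for si, s in enumerate(shapes):
            if si in assigned:
                t = active[assigned[si]]
                t.shapes.append(s)
                new_active.append(t)
            else:
                t = CellTrack(next_id, [s])
                next_id += 1
                new_active.append(t)
                tracks.append(t)
        active = new_active  # tracks that missed this frame are terminated

    return [t for t in tracks if len(t) >= min_track_length]
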