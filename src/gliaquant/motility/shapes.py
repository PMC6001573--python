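"""Per-frame cell shape measurements and roundish/polarized classification.

A cell counts as "polarized" when its skeleton carries at least two
ramifications: skeleton branches longer than a minimum length whose
endpoint lies outside the soma (the maximal inscribed disk of the mask).
Anything with fewer than two ramifications is "roundish".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import perimeter as _mask_perimeter
from skimage.morphology import skeletonize

from ..errors import InvalidShapeError

ROUNDISH = "roundish"
POLARIZED = "polarized"

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class CellShape:
    frame_index: int
    mask: np.ndarray
    area_um2: float
    perimeter_um: float
    centroid_um: tuple[float, float]  # (x, y)
    state: str
    n_ramifications: int

    def __post_init__(self) -> None:
        if self.area_um2 <= 0 or self.perimeter_um <= 0:
            raise InvalidShapeError("cell shape must have positive area and perimeter")


def count_ramifications(mask: np.ndarray, min_branch_length_px: float = 5.0) -> int:
    """Count skeleton endpoints terminating a branch of at least the minimum
    length, excluding endpoints inside the maximal inscribed soma disk."""
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return 0
    mask = mask[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]
    skel = skeletonize(mask)
    if not skel.any():
        return 0

    dt = ndimage.distance_transform_edt(mask)
    soma_center = np.unravel_index(np.argmax(dt), dt.shape)
    soma_radius = float(dt.max())

    skel_set = set(zip(*np.nonzero(skel)))
    degree = {p: sum(((p[0] + dr, p[1] + dc) in skel_set) for dr, dc in _NEIGHBORS) for p in skel_set}

    def in_soma(p: tuple[int, int]) -> bool:
        return (p[0] - soma_center[0]) ** 2 + (p[1] - soma_center[1]) ** 2 <= soma_radius**2

    count = 0
    for tip, deg in degree.items():
        if deg != 1 or in_soma(tip):
            continue
        # walk from the tip toward the soma / first junction
        length = 0.0
        prev, cur = None, tip
        while True:
            nxt = [
                (cur[0] + dr, cur[1] + dc)
                for dr, dc in _NEIGHBORS
                if (cur[0] + dr, cur[1] + dc) in skel_set and (cur[0] + dr, cur[1] + dc) != prev
            ]
            if not nxt:
                break
            step = nxt[0]
            length += np.hypot(step[0] - cur[0], step[1] - cur[1])
            prev, cur = cur, step
            if in_soma(cur) or degree[cur] >= 3:
                break
            if length > 10 * max(mask.shape):  # safety against cycles
                break
        if length >= min_branch_length_px:
            count += 1
    return count


def classify_morphology(
    mask: np.ndarray,
    min_branch_length_px: float = 5.0,
    min_object_area_px: int = 50,
) -> tuple[str, int]:
    """Return (state, n_ramifications); polarized iff >= 2 ramifications."""
    if mask.sum() < min_object_area_px:
        raise InvalidShapeError(
            f"mask of {int(mask.sum())} px below minimum area {min_object_area_px}"
        )
    n = count_ramifications(mask, min_branch_length_px)
    return (POLARIZED if n >= 2 else ROUNDISH), n


def shape_from_mask(
    mask: np.ndarray,
    frame_index: int,
    pixel_size_um: float,
    min_branch_length_px: float = 5.0,
    min_object_area_px: int = 50,
) -> CellShape:
    """Measure area, perimeter, centroid and shape state of one mask."""
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise InvalidShapeError("empty mask")
    crop = mask[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]
    area = float(ys.size) * pixel_size_um**2
    perim = float(_mask_perimeter(crop)) * pixel_size_um
    state, n_ram = classify_morphology(mask, min_branch_length_px, min_object_area_px)
    return CellShape(
        frame_index=frame_index,
        mask=mask,
        area_um2=area,
        perimeter_um=perim,
        centroid_um=(float(xs.mean()) * pixel_size_um, float(ys.mean()) * pixel_size_um),
        state=state,
        n_ramifications=n_ram,
    )
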