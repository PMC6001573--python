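"""Synthetic time-lapse movies of motile, shape-shifting cells.

Each cell is rendered as a filled soma disk plus 0-4 tapered branches.
"Polarized" cells carry >=2 branches, "roundish" cells <=1, so the planted
shape state is unambiguous for a ramification-counting classifier. Per
frame, cells random-walk inside their own territory (keeping masks
disjoint), branch lengths fluctuate stochastically (membrane dynamics),
and the shape state toggles with a fixed per-frame probability.

The branch-fluctuation magnitude is driven by a per-cell closed-loop
controller so the realized mean |dA|/p (computed on the true masks)
tracks ``membrane_change_rate``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import perimeter as _mask_perimeter

from ..errors import SizingError
from ..motility.movie import TimeLapseMovie

SOMA_RADIUS_PX = 8.0
BRANCH_WIDTH_PX = 3.0
BRANCH_LEN_MIN_PX = 10.0
BRANCH_LEN_MAX_PX = 30.0
MIN_BRANCH_ANGLE_SEP = math.radians(55.0)
FOREGROUND = 1.0

ROUNDISH = "roundish"
POLARIZED = "polarized"


@dataclass(frozen=True)
class MovieSpec:
    n_cells: int = 10
    duration_frames: int = 60
    frame_interval_s: float = 60.0
    pixel_size_um: float = 0.5
    image_shape: tuple[int, int] = (768, 768)
    translocation_speed_um_min: float = 1.0
    membrane_change_rate: float = 0.1  # target mean |dA|/p per frame pair, um
    morph_transition_prob: float = 0.0
    noise_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.duration_frames < 2:
            raise ValueError("duration_frames must be >= 2")
        if not 0 <= self.morph_transition_prob <= 1:
            raise ValueError("morph_transition_prob must lie in [0, 1]")
        for name in ("frame_interval_s", "pixel_size_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("translocation_speed_um_min", "membrane_change_rate", "noise_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class MovieGroundTruth:
    """Everything planted by the generator, per cell and per frame."""

    table: pd.DataFrame  # cell_id, frame, x_px, y_px, area_px2, perimeter_px, state
    transition_counts: dict[int, int]
    spec: MovieSpec

    def cell(self, cell_id: int) -> pd.DataFrame:
        return self.table[self.table.cell_id == cell_id].sort_values("frame")

    def membrane_change_series_um(self, cell_id: int) -> np.ndarray:
        """|dA|/p per consecutive frame pair from the true masks' A and p."""
        sub = self.cell(cell_id)
        px = self.spec.pixel_size_um
        a = sub.area_px2.to_numpy() * px**2
        p = sub.perimeter_px.to_numpy() * px
        da = np.abs(np.diff(a))
        p_mean = 0.5 * (p[:-1] + p[1:])
        return da / p_mean

    def speed_um_min(self, cell_id: int) -> float:
        """Mean true-centroid step length per minute."""
        sub = self.cell(cell_id)
        px = self.spec.pixel_size_um
        xy = sub[["x_px", "y_px"]].to_numpy() * px
        steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        return float(steps.mean() / (self.spec.frame_interval_s / 60.0))


@dataclass
class _Branch:
    angle: float
    length: float


@dataclass
class _Cell:
    center: np.ndarray  # (row, col) float
    branches: list[_Branch]
    tile: tuple[float, float, float, float]  # row_lo, row_hi, col_lo, col_hi
    dA_scale: float = 0.0
    realized_ema: float | None = None

    @property
    def state(self) -> str:
        return POLARIZED if len(self.branches) >= 2 else ROUNDISH


def _sample_angles(rng: np.random.Generator, n: int) -> list[float]:
    angles: list[float] = []
    for _ in range(200):
        if len(angles) == n:
            break
        cand = rng.uniform(0, 2 * math.pi)
        if all(
            min(abs(cand - a), 2 * math.pi - abs(cand - a)) >= MIN_BRANCH_ANGLE_SEP
            for a in angles
        ):
            angles.append(cand)
    while len(angles) < n:  # extremely unlikely fallback
        angles.append(rng.uniform(0, 2 * math.pi))
    return angles


def _new_branches(rng: np.random.Generator, state: str) -> list[_Branch]:
    if state == POLARIZED:
        n = int(rng.integers(2, 5))
    else:
        n = 1  # one branch keeps a lever for membrane dynamics; still roundish
    lengths = rng.uniform(BRANCH_LEN_MIN_PX + 2, BRANCH_LEN_MAX_PX - 2, n)
    return [_Branch(a, float(l)) for a, l in zip(_sample_angles(rng, n), lengths)]


def _render_cell(cell: _Cell, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize soma + tapered branches as a boolean mask."""
    rows, cols = shape
    r0, c0 = cell.center
    # bounding box big enough for soma + longest branch
    reach = SOMA_RADIUS_PX + BRANCH_LEN_MAX_PX + BRANCH_WIDTH_PX + 2
    lo_r = max(0, int(r0 - reach))
    hi_r = min(rows, int(r0 + reach) + 1)
    lo_c = max(0, int(c0 - reach))
    hi_c = min(cols, int(c0 + reach) + 1)
    rr, cc = np.mgrid[lo_r:hi_r, lo_c:hi_c]
    local = (rr - r0) ** 2 + (cc - c0) ** 2 <= SOMA_RADIUS_PX**2

    for br in cell.branches:
        dr, dc = math.sin(br.angle), math.cos(br.angle)
        # stamp disks of tapering radius along the centreline
        n_steps = max(2, int(br.length / 0.75))
        for i in range(n_steps + 1):
            frac = i / n_steps
            dist = SOMA_RADIUS_PX - 1 + frac * br.length
            radius = BRANCH_WIDTH_PX * (1.0 - 0.6 * frac) / 2.0 + 0.5
            pr = r0 + dr * dist
            pc = c0 + dc * dist
            local |= (rr - pr) ** 2 + (cc - pc) ** 2 <= radius**2

    mask = np.zeros(shape, dtype=bool)
    mask[lo_r:hi_r, lo_c:hi_c] = local
    return mask


def _tile_layout(spec: MovieSpec) -> list[tuple[float, float, float, float]]:
    rows, cols = spec.image_shape
    n = spec.n_cells
    ncols = max(1, int(math.ceil(math.sqrt(n * cols / rows))))
    nrows = int(math.ceil(n / ncols))
    tile_h, tile_w = rows / nrows, cols / ncols
    margin = SOMA_RADIUS_PX + BRANCH_LEN_MAX_PX + BRANCH_WIDTH_PX + 2
    if tile_h < 2 * margin + 4 or tile_w < 2 * margin + 4:
        raise SizingError(
            f"image {spec.image_shape} too small for {n} non-overlapping cells "
            f"(needs tiles of at least {int(2 * margin + 4)} px)"
        )
    tiles = []
    for k in range(n):
        i, j = divmod(k, ncols)
        tiles.append(
            (i * tile_h + margin, (i + 1) * tile_h - margin, j * tile_w + margin, (j + 1) * tile_w - margin)
        )
    return tiles


def _measure(mask: np.ndarray) -> tuple[float, float, float, float]:
    """(x_px, y_px, area_px2, perimeter_px) of a boolean mask."""
    ys, xs = np.nonzero(mask)
    crop = mask[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]
    return float(xs.mean()), float(ys.mean()), float(len(ys)), float(_mask_perimeter(crop))


def generate_cell_movie(spec: MovieSpec) -> tuple[TimeLapseMovie, MovieGroundTruth]:
    """Render a movie plus complete ground truth; deterministic in spec+seed."""
    rng = np.random.default_rng(spec.seed)
    tiles = _tile_layout(spec)
    step_px = (
        spec.translocation_speed_um_min * (spec.frame_interval_s / 60.0) / spec.pixel_size_um
    )

    cells: list[_Cell] = []
    for tile in tiles:
        r_lo, r_hi, c_lo, c_hi = tile
        center = np.array(
            [
                rng.uniform(r_lo + 0.25 * (r_hi - r_lo), r_hi - 0.25 * (r_hi - r_lo)),
                rng.uniform(c_lo + 0.25 * (c_hi - c_lo), c_hi - 0.25 * (c_hi - c_lo)),
            ]
        )
        state = POLARIZED if rng.random() < 0.5 else ROUNDISH
        cells.append(_Cell(center=center, branches=_new_branches(rng, state), tile=tile))

    # initial guess for the branch-fluctuation scale from the target dA
    for cell in cells:
        mask0 = _render_cell(cell, spec.image_shape)
        p_um = _measure(mask0)[3] * spec.pixel_size_um
        target_dA_px2 = spec.membrane_change_rate * p_um / spec.pixel_size_um**2
        n_b = max(1, len(cell.branches))
        cell.dA_scale = target_dA_px2 / (n_b * 2.0 * 0.8) if spec.membrane_change_rate > 0 else 0.0

    frames = np.zeros((spec.duration_frames,) + tuple(spec.image_shape), dtype=np.float32)
    records: list[tuple] = []
    prev_measures: list[tuple[float, float]] = [(0.0, 0.0)] * len(cells)  # (area, perim) px
    states: list[list[str]] = [[] for _ in cells]

    for f in range(spec.duration_frames):
        frame = np.zeros(spec.image_shape, dtype=np.float32)
        for cid, cell in enumerate(cells):
            transitioned = False
            if f > 0:
                # translocation: fixed step length, random heading, reflected
                if step_px > 0:
                    theta = rng.uniform(0, 2 * math.pi)
                    cell.center = cell.center + step_px * np.array(
                        [math.sin(theta), math.cos(theta)]
                    )
                    r_lo, r_hi, c_lo, c_hi = cell.tile
                    cell.center[0] = _reflect(cell.center[0], r_lo, r_hi)
                    cell.center[1] = _reflect(cell.center[1], c_lo, c_hi)
                # morphology transition
                if rng.random() < spec.morph_transition_prob:
                    new_state = ROUNDISH if cell.state == POLARIZED else POLARIZED
                    cell.branches = _new_branches(rng, new_state)
                    transitioned = True
                # membrane dynamics: per-branch length fluctuation
                elif cell.dA_scale > 0 and cell.branches:
                    per_branch = cell.dA_scale / len(cell.branches)
                    for br in cell.branches:
                        br.length = float(
                            np.clip(
                                br.length + per_branch / 2.0 * rng.normal(),
                                BRANCH_LEN_MIN_PX,
                                BRANCH_LEN_MAX_PX,
                            )
                        )
            mask = _render_cell(cell, spec.image_shape)
            frame[mask] = FOREGROUND
            x, y, area, perim = _measure(mask)
            states[cid].append(cell.state)
            records.append((cid, f, x, y, area, perim, cell.state))

            # closed-loop calibration of the fluctuation magnitude
            if f > 0 and not transitioned and spec.membrane_change_rate > 0:
                prev_a, prev_p = prev_measures[cid]
                realized = (
                    abs(area - prev_a)
                    * spec.pixel_size_um**2
                    / (0.5 * (perim + prev_p) * spec.pixel_size_um)
                )
                ema = cell.realized_ema
                cell.realized_ema = realized if ema is None else 0.7 * ema + 0.3 * realized
                if cell.realized_ema > 1e-9:
                    gain = spec.membrane_change_rate / cell.realized_ema
                    cell.dA_scale *= float(np.clip(gain, 0.7, 1.4))
            prev_measures[cid] = (area, perim)
        frames[f] = frame

    if spec.noise_level > 0:
        frames = frames + rng.normal(
            0.0, spec.noise_level * FOREGROUND, frames.shape
        ).astype(np.float32)

    table = pd.DataFrame(
        records, columns=["cell_id", "frame", "x_px", "y_px", "area_px2", "perimeter_px", "state"]
    )
    transitions = {
        cid: int(sum(a != b for a, b in zip(seq[:-1], seq[1:]))) for cid, seq in enumerate(states)
    }
    movie = TimeLapseMovie(
        frames=frames, pixel_size_um=spec.pixel_size_um, frame_interval_s=spec.frame_interval_s
    )
    return movie, MovieGroundTruth(table=table, transition_counts=transitions, spec=spec)


def _reflect(x: float, lo: float, hi: float) -> float:
    if x < lo:
        return lo + (lo - x)
    if x > hi:
        return hi - (x - hi)
    return x
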