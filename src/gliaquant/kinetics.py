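"""Uptake/washout accounting: per-interval degradation and release deltas.

Internal (densitometry) and supernatant (ELISA) levels live in
incommensurate units unless an explicit calibration factor (internal units
per supernatant unit) is supplied; mass-balance decomposition is only
performed when it is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GliaquantError
from .omics import GroupComparison, compare_groups


def normalize_to_housekeeping(raw_band: float, housekeeping_band: float) -> float:
    """Densitometry normalization: raw / housekeeping."""
    if housekeeping_band <= 0:
        raise GliaquantError("housekeeping band must be positive")
    return raw_band / housekeeping_band


@dataclass
class KineticsTimecourse:
    time_points_h: np.ndarray
    internal_level: np.ndarray
    supernatant_level: np.ndarray | None = None
    replicate: int = 1
    condition: str = ""

    def __post_init__(self) -> None:
        self.time_points_h = np.asarray(self.time_points_h, dtype=float)
        self.internal_level = np.asarray(self.internal_level, dtype=float)
        if np.any(np.diff(self.time_points_h) <= 0):
            raise GliaquantError("time points must be strictly increasing")
        if self.internal_level.shape != self.time_points_h.shape:
            raise GliaquantError("internal levels do not match time points")
        if self.supernatant_level is not None:
            self.supernatant_level = np.asarray(self.supernatant_level, dtype=float)
            if self.supernatant_level.shape != self.time_points_h.shape:
                raise GliaquantError("supernatant levels do not match time points")


@dataclass
class DegradationSummary:
    interval_starts_h: np.ndarray
    interval_ends_h: np.ndarray
    delta_internal: np.ndarray           # internal(n) - internal(n+1), internal units
    delta_released: np.ndarray | None    # supernatant increments, supernatant units
    delta_digested: np.ndarray           # internal units (calibrated if possible)
    cumulative_digested: np.ndarray
    cumulative_released: np.ndarray | None
    calibrated: bool
    negative_delta_flags: np.ndarray     # apparent gains preserved, flagged

    def to_frame(self) -> pd.DataFrame:
        d = {
            "t_start_h": self.interval_starts_h,
            "t_end_h": self.interval_ends_h,
            "delta_internal": self.delta_internal,
            "delta_digested": self.delta_digested,
            "negative_delta": self.negative_delta_flags,
        }
        if self.delta_released is not None:
            d["delta_released"] = self.delta_released
        return pd.DataFrame(d)


def degradation_deltas(
    tc: KineticsTimecourse, calibration: float | None = None
) -> DegradationSummary:
    """Per-interval losses from the internal pool, split into digestion and
    release when a calibration factor (internal units per supernatant unit)
    allows the two assays to be compared.

    Without calibration, delta_digested is simply the internal-level drop
    per interval and release is reported separately in its own units.
    Negative deltas (apparent gains on noisy data) are kept and flagged,
    never clipped.
    """
    t = tc.time_points_h
    if t.size < 2:
        raise GliaquantError("need at least 2 time points")
    internal = tc.internal_level
    d_internal = internal[:-1] - internal[1:]

    d_released = None
    if tc.supernatant_level is not None:
        d_released = tc.supernatant_level[1:] - tc.supernatant_level[:-1]

    if calibration is not None:
        if d_released is None:
            raise GliaquantError("calibration supplied but no supernatant levels")
        d_digested = d_internal - calibration * d_released
    else:
        d_digested = d_internal.copy()

    return DegradationSummary(
        interval_starts_h=t[:-1],
        interval_ends_h=t[1:],
        delta_internal=d_internal,
        delta_released=d_released,
        delta_digested=d_digested,
        cumulative_digested=np.cumsum(d_digested),
        cumulative_released=np.cumsum(d_released) if d_released is not None else None,
        calibrated=calibration is not None,
        negative_delta_flags=d_digested < 0,
    )


def timecourses_from_table(table: pd.DataFrame) -> list[KineticsTimecourse]:
    """Split a tidy table (condition, replicate, time_h, internal_level,
    [supernatant_level]) into per-replicate time courses."""
    out = []
    has_sup = "supernatant_level" in table.columns
    for (cond, rep), sub in table.groupby(["condition", "replicate"], sort=True):
        sub = sub.sort_values("time_h")
        out.append(
            KineticsTimecourse(
                time_points_h=sub["time_h"].to_numpy(),
                internal_level=sub["internal_level"].to_numpy(),
                supernatant_level=sub["supernatant_level"].to_numpy() if has_sup else None,
                replicate=int(rep),
                condition=str(cond),
            )
        )
    return out


@dataclass
class ConditionComparison:
    interval_starts_h: np.ndarray
    mean_difference: np.ndarray          # treated - control digested per interval
    tests: list[GroupComparison] | None  # one per interval, None when untestable
    descriptive_only: bool


def compare_conditions(
    treated: list[DegradationSummary],
    control: list[DegradationSummary],
    design: str = "unpaired",
) -> ConditionComparison:
    """Per-interval mean digested-delta difference with a two-sample test.

    Deltas are computed per replicate then averaged (preserving the
    parallel-experiment pairing); with a single replicate per arm only the
    descriptive difference is reported, with a warning.
    """
    if not treated or not control:
        raise GliaquantError("each condition needs at least one replicate summary")
    t_mat = np.vstack([s.delta_digested for s in treated])
    c_mat = np.vstack([s.delta_digested for s in control])
    if t_mat.shape[1] != c_mat.shape[1]:
        raise GliaquantError("conditions measured on different interval grids")
    starts = treated[0].interval_starts_h
    diff = t_mat.mean(axis=0) - c_mat.mean(axis=0)

    if t_mat.shape[0] < 2 or c_mat.shape[0] < 2:
        warnings.warn(
            "fewer than 2 replicates per condition: descriptive output only, no test",
            stacklevel=2,
        )
        return ConditionComparison(starts, diff, None, descriptive_only=True)

    tests = [
        compare_groups({"treated": t_mat[:, j], "control": c_mat[:, j]}, design=design)
        for j in range(t_mat.shape[1])
    ]
    return ConditionComparison(starts, diff, tests, descriptive_only=False)
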