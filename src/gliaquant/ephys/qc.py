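"""Recording quality control: series-resistance stability."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import InvalidQCError


@dataclass
class RecordingQC:
    series_resistance_MOhm: np.ndarray
    threshold_fraction: float = 0.25
    passed: bool | None = None

    def __post_init__(self) -> None:
        self.series_resistance_MOhm = np.asarray(self.series_resistance_MOhm, dtype=float)


def check_rs_stability(
    rs_MOhm: np.ndarray, threshold_fraction: float = 0.25
) -> RecordingQC:
    """Discard a recording when Rs drifts by more than the threshold
    fraction of its initial value (default 25%)."""
    rs = np.asarray(rs_MOhm, dtype=float)
    if rs.size < 2:
        raise InvalidQCError("Rs stability needs at least 2 readings")
    if np.any(rs <= 0) or not np.all(np.isfinite(rs)):
        raise InvalidQCError("Rs readings must be positive and finite")
    drift = np.max(np.abs(rs - rs[0])) / rs[0]
    return RecordingQC(
        series_resistance_MOhm=rs,
        threshold_fraction=threshold_fraction,
        passed=bool(drift <= threshold_fraction),
    )
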