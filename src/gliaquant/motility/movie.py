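"""Time-lapse movie container with physical calibration."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class TimeLapseMovie:
    """Single-channel frame stack with pixel size and frame interval.

    frames: array of shape (n_frames, rows, cols), intensity units arbitrary.
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("movie needs >=2 frames of identical shape")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def resampled(self, stride: int) -> "TimeLapseMovie":
        """Every ``stride``-th frame, e.g. stride=2 turns a 30 s acquisition
        cadence into a 1 frame/min analysis cadence."""
        if stride < 1:
            raise ValueError("stride must be >= 1")
        return TimeLapseMovie(
            frames=self.frames[::stride],
            pixel_size_um=self.pixel_size_um,
            frame_interval_s=self.frame_interval_s * stride,
        )
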