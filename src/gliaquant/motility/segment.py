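"""Frame segmentation: smoothing + thresholding + cleanup.

The default chain is Gaussian smoothing, Otsu threshold, hole filling and a
minimum-area filter; every piece is overridable through SegmentationParams.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationParams:
    smoothing_sigma_px: float = 1.0     # 0 disables smoothing
    threshold_method: str = "otsu"      # "otsu" | "fixed"
    fixed_threshold: float = 0.5        # used when threshold_method == "fixed"
    min_object_area_px: int = 50

    def __post_init__(self) -> None:
        if self.smoothing_sigma_px < 0:
            raise ValueError("smoothing_sigma_px must be nonnegative")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")
        if self.min_object_area_px < 1:
            raise ValueError("min_object_area_px must be >= 1")


def segment_frame(
    frame: np.ndarray, params: SegmentationParams = SegmentationParams()
) -> list[np.ndarray]:
    """Segment one frame into disjoint hole-free binary masks.

    Returns a list of boolean masks (possibly empty); no object above the
    minimum area is a warning, not an error. Masks are ordered by label.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_frame expects a single 2-D frame")
    if params.smoothing_sigma_px > 0:
        img = gaussian(img, sigma=params.smoothing_sigma_px, preserve_range=True)

    if params.threshold_method == "fixed":
        thresh = params.fixed_threshold
    else:
        if np.allclose(img, img.flat[0]):
            log.warning("uniform frame: no objects found")
            return []
        thresh = threshold_otsu(img)

    binary = img > thresh
    binary = ndimage.binary_fill_holes(binary)
    labels, n = ndimage.label(binary)
    masks = []
    for lab in range(1, n + 1):
        mask = labels == lab
        if mask.sum() >= params.min_object_area_px:
            masks.append(mask)
    if not masks:
        log.warning("no object above min area %d px", params.min_object_area_px)
    return masks
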