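"""Miniature-EPSC detection with noise-scaled amplitude and area thresholds.

Events are inward (negative) deflections; the detector works on the
baseline-subtracted, sign-flipped trace and reports peak magnitudes in pA.
A candidate is accepted when its peak exceeds ``k * noise SD`` AND its area
exceeds ``k * noise SD * nominal event width`` (the OR combination is
available via ``combine="or"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from ..errors import InsufficientBaselineError
from .protocol import CurrentTrace, EventList, MEPSCEvent


@dataclass
class NoiseEstimate:
    sd_pA: float
    segments: list[tuple[float, float]]  # (start_s, stop_s) windows used

    def __post_init__(self) -> None:
        if self.sd_pA < 0:
            raise ValueError("noise SD must be nonnegative")


def estimate_noise_sd(
    trace: CurrentTrace,
    segments: list[tuple[float, float]] | None = None,
    window_s: float = 0.1,
) -> NoiseEstimate:
    """Noise SD from event-free stretches.

    With explicit segments: SD of the mean-subtracted samples inside them.
    Otherwise the trace is cut into ``window_s`` windows and the median of
    the per-window SDs is taken — robust to event contamination as long as
    fewer than half the windows contain an event.
    """
    fs = trace.sampling_hz
    x = trace.samples_pA
    if segments is not None:
        picked = []
        total = 0.0
        for t0, t1 in segments:
            i0, i1 = int(t0 * fs), int(t1 * fs)
            seg = x[i0:i1]
            if seg.size:
                picked.append(seg - seg.mean())
                total += seg.size / fs
        if total < 0.1:
            raise InsufficientBaselineError(
                f"only {total * 1000:.0f} ms of baseline supplied; need >= 100 ms"
            )
        return NoiseEstimate(sd_pA=float(np.concatenate(picked).std(ddof=1)), segments=list(segments))

    w = int(round(window_s * fs))
    n_windows = x.size // w
    if n_windows * w < 0.1 * fs or n_windows < 1:
        raise InsufficientBaselineError(
            f"trace of {x.size / fs * 1000:.0f} ms too short to estimate noise (need >= 100 ms)"
        )
    sds = np.array(
        [x[j * w : (j + 1) * w].std(ddof=1) for j in range(n_windows)]
    )
    med = float(np.median(sds))
    chosen = [
        (j * w / fs, (j + 1) * w / fs) for j in range(n_windows) if sds[j] <= med
    ]
    return NoiseEstimate(sd_pA=med, segments=chosen)


def rolling_baseline(x: np.ndarray, sampling_hz: float, window_s: float = 0.2) -> np.ndarray:
    """Piecewise rolling-median baseline: block medians linearly interpolated
    back to full rate (fast approximation of a dense rolling median)."""
    block = max(1, int(round(window_s * sampling_hz / 2)))
    n_blocks = max(1, x.size // block)
    centers = np.array([(j + 0.5) * block for j in range(n_blocks)])
    meds = np.array([np.median(x[j * block : (j + 1) * block]) for j in range(n_blocks)])
    if n_blocks == 1:
        return np.full_like(x, meds[0])
    return np.interp(np.arange(x.size), centers, meds)


def detect_mepscs(
    trace: CurrentTrace,
    noise: NoiseEstimate,
    k: float = 3.5,
    nominal_width_ms: float = 10.0,
    baseline_window_s: float = 0.2,
    refractory_ms: float = 5.0,
    combine: str = "and",
) -> EventList:
    """Threshold detection of inward events.

    Candidate peaks on the smoothed, baseline-subtracted magnitude signal
    must clear the amplitude threshold ``k * sd``; their integrated area
    (pA*ms, between half-threshold crossings) must clear
    ``k * sd * nominal_width_ms``; candidates closer than the refractory
    window are merged by ``find_peaks`` distance.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if combine not in ("and", "or"):
        raise ValueError("combine must be 'and' or 'or'")
    x = trace.samples_pA
    if x.size == 0:
        raise ValueError("empty trace")
    fs = trace.sampling_hz

    baseline = rolling_baseline(x, fs, baseline_window_s)
    y = baseline - x  # positive = inward deflection magnitude

    # light smoothing (0.5 ms boxcar) stabilizes peak amplitudes against
    # single-sample noise without attenuating ~ms-scale events
    box = max(1, int(round(0.0005 * fs)))
    if box > 1:
        y_s = np.convolve(y, np.ones(box) / box, mode="same")
    else:
        y_s = y

    amp_thresh = k * noise.sd_pA
    area_thresh = k * noise.sd_pA * nominal_width_ms
    distance = max(1, int(round(refractory_ms / 1000.0 * fs)))
    peaks, props = find_peaks(y_s, height=amp_thresh, distance=distance)

    half = 0.5 * amp_thresh
    events: list[MEPSCEvent] = []
    max_half_width = int(round(0.05 * fs))  # 50 ms search bound each side
    for pk in peaks:
        i0 = pk
        lo = max(0, pk - max_half_width)
        while i0 > lo and y_s[i0 - 1] > half:
            i0 -= 1
        i1 = pk
        hi = min(y_s.size - 1, pk + max_half_width)
        while i1 < hi and y_s[i1 + 1] > half:
            i1 += 1
        area = float(y[i0 : i1 + 1].sum() / fs * 1000.0)
        amp = float(y_s[pk])
        amp_ok = amp >= amp_thresh
        area_ok = area >= area_thresh
        keep = (amp_ok and area_ok) if combine == "and" else (amp_ok or area_ok)
        if keep:
            events.append(
                MEPSCEvent(
                    onset_s=i0 / fs, peak_amplitude_pA=amp, area_pA_ms=area, peak_time_s=pk / fs
                )
            )

    # events come out ordered by peak index; overlapping candidates can share
    # an onset sample, so nudge onsets to keep them strictly increasing
    # (distinct peaks are distinct events)
    for j in range(1, len(events)):
        if events[j].onset_s <= events[j - 1].onset_s:
            events[j].onset_s = events[j - 1].onset_s + 1.0 / fs
    return EventList(events=events, duration_s=trace.duration_s)


@dataclass
class MepscSummary:
    n_events: int
    duration_s: float
    frequency_hz: float
    amplitude_mean_pA: float | None
    amplitude_sem_pA: float | None

    @property
    def amplitude_defined(self) -> bool:
        return self.amplitude_mean_pA is not None


def summarize_mepscs(events: EventList, duration_s: float | None = None) -> MepscSummary:
    """Frequency = count / duration; amplitude mean +/- SEM over peaks.

    An empty list gives frequency 0 with amplitude flagged undefined.
    """
    dur = duration_s if duration_s is not None else events.duration_s
    if dur <= 0:
        raise ValueError("duration must be positive")
    n = len(events)
    if n == 0:
        return MepscSummary(0, dur, 0.0, None, None)
    amps = events.amplitudes_pA
    sem = float(amps.std(ddof=1) / np.sqrt(n)) if n > 1 else None
    return MepscSummary(n, dur, n / dur, float(amps.mean()), sem)
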