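"""Synthetic miniature-EPSC traces: biexponential inward events at Poisson times.

Each event is ``-a * k(t - t0)`` where the kernel

    k(t) = (exp(-t/tau_decay) - exp(-t/tau_rise)) / peak_factor

is normalized so its maximum is exactly 1; the planted amplitude ``a`` is
therefore the true peak magnitude in pA. Overlapping events sum linearly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..ephys.protocol import CurrentTrace, EventList, MEPSCEvent


@dataclass(frozen=True)
class MepscSpec:
    duration_s: float = 60.0
    sampling_hz: float = 10_000.0
    event_rate_hz: float = 5.0
    amplitude_mean_pA: float = 20.0
    amplitude_cv: float = 0.2
    tau_rise_ms: float = 0.5
    tau_decay_ms: float = 5.0
    noise_sd_pA: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.event_rate_hz < 0:
            raise ValueError("event_rate_hz must be nonnegative")
        if not self.tau_rise_ms < self.tau_decay_ms:
            raise ValueError("tau_rise_ms must be smaller than tau_decay_ms")
        if self.sampling_hz < 1000:
            raise ValueError("sampling_hz must be at least 1000")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


def biexp_peak_factor(tau_rise_ms: float, tau_decay_ms: float) -> float:
    """Peak value of exp(-t/tau_d) - exp(-t/tau_r) over t >= 0 (closed form)."""
    tr, td = tau_rise_ms, tau_decay_ms
    t_peak = tr * td / (td - tr) * math.log(td / tr)
    return math.exp(-t_peak / td) - math.exp(-t_peak / tr)


def generate_mepsc_trace(spec: MepscSpec) -> tuple[CurrentTrace, EventList]:
    """Return (trace, planted ground truth). Deterministic in spec + seed."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.sampling_hz))
    current = np.zeros(n)

    # Poisson process via exponential gaps; amplitudes lognormal-free: normal
    # truncated at a small positive floor to keep magnitudes positive.
    onsets: list[float] = []
    if spec.event_rate_hz > 0:
        t = rng.exponential(1.0 / spec.event_rate_hz)
        while t < spec.duration_s:
            onsets.append(t)
            t += rng.exponential(1.0 / spec.event_rate_hz)
    amps = np.maximum(
        rng.normal(spec.amplitude_mean_pA, spec.amplitude_cv * spec.amplitude_mean_pA, len(onsets)),
        0.05 * spec.amplitude_mean_pA,
    )

    peak = biexp_peak_factor(spec.tau_rise_ms, spec.tau_decay_ms)
    tr, td = spec.tau_rise_ms, spec.tau_decay_ms
    t_peak_s = tr * td / (td - tr) * math.log(td / tr) / 1000.0
    kernel_len = int(round(8 * spec.tau_decay_ms / 1000.0 * spec.sampling_hz))
    t_ms = np.arange(kernel_len) / spec.sampling_hz * 1000.0
    kernel = (np.exp(-t_ms / spec.tau_decay_ms) - np.exp(-t_ms / spec.tau_rise_ms)) / peak

    events = []
    for t0, a in zip(onsets, amps):
        i0 = int(round(t0 * spec.sampling_hz))
        seg = kernel[: max(0, min(kernel_len, n - i0))]
        current[i0 : i0 + seg.size] -= a * seg
        events.append(
            MEPSCEvent(
                onset_s=t0,
                peak_amplitude_pA=float(a),
                area_pA_ms=float(a * seg.sum() / spec.sampling_hz * 1000.0),
                peak_time_s=t0 + t_peak_s,
            )
        )

    if spec.noise_sd_pA > 0:
        current += rng.normal(0.0, spec.noise_sd_pA, n)

    trace = CurrentTrace(current, spec.sampling_hz)
    truth = EventList(events=events, duration_s=spec.duration_s)
    return trace, truth
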