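"""Core voltage-clamp data structures shared by generators and analysis.

Conventions: currents in pA, voltages in mV, conductances in nS (so that
``g * V`` is directly in pA), time in seconds unless a unit suffix says
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ProtocolMismatchError


@dataclass(frozen=True)
class VoltageStepProtocol:
    """Family of rectangular voltage steps from a fixed holding potential."""

    holding_mV: float = -20.0
    step_start_mV: float = -140.0
    step_stop_mV: float = 60.0
    step_increment_mV: float = 20.0
    step_duration_ms: float = 250.0
    inter_step_interval_s: float = 5.0

    def __post_init__(self) -> None:
        if self.step_duration_ms <= 0:
            raise ValueError("step_duration_ms must be positive")
        if self.step_increment_mV <= 0:
            raise ValueError("step_increment_mV must be positive")
        span = self.step_stop_mV - self.step_start_mV
        n = span / self.step_increment_mV
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                "step_increment_mV must evenly divide (stop - start); "
                f"got {self.step_increment_mV} over {span}"
            )

    @property
    def step_voltages_mV(self) -> np.ndarray:
        n = int(round((self.step_stop_mV - self.step_start_mV) / self.step_increment_mV))
        return self.step_start_mV + self.step_increment_mV * np.arange(n + 1)

    @property
    def n_steps(self) -> int:
        return self.step_voltages_mV.size


@dataclass
class CurrentTrace:
    """A sampled current recording, optionally with its command voltage."""

    samples_pA: np.ndarray
    sampling_hz: float
    command_mV: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples_pA = np.asarray(self.samples_pA, dtype=float)
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")
        if not np.all(np.isfinite(self.samples_pA)):
            raise ValueError("trace contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples_pA.size / self.sampling_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.samples_pA.size) / self.sampling_hz


@dataclass
class SweepSet:
    """One current trace per protocol step, in protocol step order."""

    protocol: VoltageStepProtocol
    traces: list[CurrentTrace]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.traces) != self.protocol.n_steps:
            raise ProtocolMismatchError(
                f"{len(self.traces)} traces for a {self.protocol.n_steps}-step protocol"
            )


@dataclass
class IVCurve:
    """Current/voltage pairs measured in a stated window of each step."""

    voltages_mV: np.ndarray
    currents_pA: np.ndarray
    window: str = ""
    reversal_potential_mV: float | None = None
    reversal_ambiguous: bool = False

    def __post_init__(self) -> None:
        self.voltages_mV = np.asarray(self.voltages_mV, dtype=float)
        self.currents_pA = np.asarray(self.currents_pA, dtype=float)
        if self.voltages_mV.shape != self.currents_pA.shape:
            raise ValueError("voltage and current arrays differ in shape")
        if np.any(np.diff(self.voltages_mV) <= 0):
            raise ValueError("voltages must be strictly increasing")


@dataclass
class MEPSCEvent:
    onset_s: float
    peak_amplitude_pA: float
    area_pA_ms: float
    peak_time_s: float | None = None


@dataclass
class EventList:
    """Detected (or planted) synaptic events over a recording of known length."""

    events: list[MEPSCEvent] = field(default_factory=list)
    duration_s: float = 0.0

    def __post_init__(self) -> None:
        onsets = self.onsets_s
        if onsets.size > 1 and np.any(np.diff(onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def onsets_s(self) -> np.ndarray:
        return np.array([e.onset_s for e in self.events], dtype=float)

    @property
    def amplitudes_pA(self) -> np.ndarray:
        return np.array([e.peak_amplitude_pA for e in self.events], dtype=float)

    @property
    def areas_pA_ms(self) -> np.ndarray:
        return np.array([e.area_pA_ms for e in self.events], dtype=float)

    @property
    def peak_times_s(self) -> np.ndarray:
        return np.array(
            [e.peak_time_s if e.peak_time_s is not None else e.onset_s for e in self.events],
            dtype=float,
        )
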