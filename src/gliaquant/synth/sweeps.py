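"""Synthetic voltage-step sweep sets with planted conductances.

The noise-free steady-state current at step voltage V is

    I(V) = g_leak * (V - E_leak) + r(V) * g_add * (V - E_add)

with r(V) an optional outward-rectification gain (> 1 for V above E_add),
plus a capacitive transient A * exp(-t / tau) whose amplitude scales with
the voltage jump from holding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..ephys.protocol import CurrentTrace, SweepSet, VoltageStepProtocol


@dataclass(frozen=True)
class SweepSpec:
    protocol: VoltageStepProtocol
    leak_conductance_nS: float = 1.0
    leak_reversal_mV: float = -40.0
    added_conductance_nS: float = 0.0
    added_reversal_mV: float = 15.0
    rectification: str = "none"  # "none" | "outward"
    rectification_gain: float = 1.5  # multiplier at V > added_reversal when outward
    capacitance_tau_ms: float = 0.0  # 0 disables the transient
    capacitance_scale_pA_per_mV: float = 5.0
    noise_sd_pA: float = 0.0
    sampling_hz: float = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.leak_conductance_nS < 0 or self.added_conductance_nS < 0:
            raise ValueError("conductances must be nonnegative")
        if self.capacitance_tau_ms < 0:
            raise ValueError("capacitance_tau_ms must be nonnegative")
        if self.rectification not in ("none", "outward"):
            raise ValueError(f"unknown rectification mode {self.rectification!r}")
        if self.noise_sd_pA < 0:
            raise ValueError("noise_sd_pA must be nonnegative")


def steady_state_current_pA(spec: SweepSpec, voltage_mV: np.ndarray | float) -> np.ndarray:
    """Closed-form noise-free steady-state current at the given voltage(s)."""
    v = np.asarray(voltage_mV, dtype=float)
    leak = spec.leak_conductance_nS * (v - spec.leak_reversal_mV)
    gain = np.ones_like(v)
    if spec.rectification == "outward":
        gain = np.where(v > spec.added_reversal_mV, spec.rectification_gain, 1.0)
    added = gain * spec.added_conductance_nS * (v - spec.added_reversal_mV)
    return leak + added


def generate_sweepset(spec: SweepSpec, label: str = "") -> SweepSet:
    """Render one current trace per protocol step.

    Identical spec + seed gives bit-identical traces.
    """
    rng = np.random.default_rng(spec.seed)
    proto = spec.protocol
    n_samples = int(round(proto.step_duration_ms / 1000.0 * spec.sampling_hz))
    t_ms = np.arange(n_samples) / spec.sampling_hz * 1000.0

    traces = []
    for v in proto.step_voltages_mV:
        i_ss = float(steady_state_current_pA(spec, v))
        trace = np.full(n_samples, i_ss)
        if spec.capacitance_tau_ms > 0:
            amp = spec.capacitance_scale_pA_per_mV * (v - proto.holding_mV)
            trace = trace + amp * np.exp(-t_ms / spec.capacitance_tau_ms)
        if spec.noise_sd_pA > 0:
            trace = trace + rng.normal(0.0, spec.noise_sd_pA, n_samples)
        command = np.full(n_samples, v)
        traces.append(CurrentTrace(trace, spec.sampling_hz, command_mV=command))
    return SweepSet(protocol=proto, traces=traces, label=label)
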