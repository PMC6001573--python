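"""I/V curve measurement, difference currents and reversal potential."""

from __future__ import annotations

import numpy as np

from ..errors import GridMismatchError, NoReversalError, ProtocolMismatchError
from .protocol import IVCurve, SweepSet


def measure_step_currents(sweeps: SweepSet, window_fraction: float = 2.0 / 3.0) -> IVCurve:
    """Mean current over the final fraction of each step (default: the last
    two-thirds, excluding the capacitance-artefact-contaminated onset)."""
    proto = sweeps.protocol
    n_expected = int(round(proto.step_duration_ms / 1000.0 * sweeps.traces[0].sampling_hz))
    currents = []
    for trace in sweeps.traces:
        n = trace.samples_pA.size
        if n < n_expected:
            raise ProtocolMismatchError(
                f"trace of {n} samples shorter than the {n_expected}-sample step"
            )
        start = int(round(n_expected * (1.0 - window_fraction)))
        currents.append(float(trace.samples_pA[start:n_expected].mean()))
    order = np.argsort(proto.step_voltages_mV)
    return IVCurve(
        voltages_mV=proto.step_voltages_mV[order],
        currents_pA=np.asarray(currents)[order],
        window=f"last {window_fraction:.4g} of step",
    )


def difference_curve(after: IVCurve, before: IVCurve) -> IVCurve:
    """Pointwise after - before on a shared voltage grid."""
    if after.voltages_mV.shape != before.voltages_mV.shape or not np.allclose(
        after.voltages_mV, before.voltages_mV
    ):
        raise GridMismatchError("I/V curves are on different voltage grids")
    return IVCurve(
        voltages_mV=after.voltages_mV.copy(),
        currents_pA=after.currents_pA - before.currents_pA,
        window=after.window,
    )


def estimate_reversal_potential(curve: IVCurve) -> IVCurve:
    """Locate the zero-crossing of the curve by linear interpolation.

    With several sign changes the crossing nearest 0 mV is taken and the
    curve is flagged ambiguous. A curve without a sign change raises
    NoReversalError. Returns a copy with reversal fields filled in.
    """
    v, i = curve.voltages_mV, curve.currents_pA
    crossings = []
    for k in range(v.size - 1):
        if i[k] == 0.0:
            crossings.append(float(v[k]))
        elif i[k] * i[k + 1] < 0:
            frac = i[k] / (i[k] - i[k + 1])
            crossings.append(float(v[k] + frac * (v[k + 1] - v[k])))
    if i[-1] == 0.0:
        crossings.append(float(v[-1]))
    if not crossings:
        raise NoReversalError("I/V curve has no sign change; no reversal potential")
    crossings = sorted(set(crossings), key=abs)
    return IVCurve(
        voltages_mV=v.copy(),
        currents_pA=i.copy(),
        window=curve.window,
        reversal_potential_mV=crossings[0],
        reversal_ambiguous=len(crossings) > 1,
    )
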