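"""Synthetic uptake/washout time courses with planted digestion and release.

Per washout interval a fixed fraction of the current internal pool is
digested (disappears) and another fraction is released into the
supernatant, where it accumulates. Noise-free series therefore conserve
mass: internal(0) - internal(T) = sum(digested) + sum(released).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class KineticsSpec:
    initial_internal_level: float = 1.0
    digestion_fraction_per_interval: float = 0.3
    release_fraction_per_interval: float = 0.1
    interval_times_h: tuple[float, ...] = (3.0, 8.0, 12.0, 24.0)
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        d, r = self.digestion_fraction_per_interval, self.release_fraction_per_interval
        if not (0 <= d <= 1 and 0 <= r <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if d + r > 1:
            raise ValueError("digestion + release fractions must not exceed 1")
        times = np.asarray(self.interval_times_h)
        if times.size < 2 or np.any(np.diff(times) <= 0):
            raise ValueError("interval_times_h must be >=2 strictly increasing times")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")


@dataclass
class KineticsGroundTruth:
    internal: np.ndarray        # noise-free internal level per time point
    supernatant: np.ndarray     # noise-free cumulative released per time point
    digested_per_interval: np.ndarray
    released_per_interval: np.ndarray


def generate_degradation_timecourse(
    spec: KineticsSpec, replicate: int = 1, condition: str = "synthetic"
) -> tuple[pd.DataFrame, KineticsGroundTruth]:
    """Return (tidy table, ground truth).

    Table columns: condition, replicate, time_h, internal_level,
    supernatant_level — matching the analysis module's input contract.
    Supernatant is in the same (internal-equivalent) units; calibration
    factors are applied downstream when emulating incommensurate assays.
    """
    times = np.asarray(spec.interval_times_h, dtype=float)
    n = times.size
    internal = np.empty(n)
    supernatant = np.empty(n)
    digested = np.empty(n - 1)
    released = np.empty(n - 1)

    internal[0] = spec.initial_internal_level
    supernatant[0] = 0.0
    for i in range(n - 1):
        digested[i] = spec.digestion_fraction_per_interval * internal[i]
        released[i] = spec.release_fraction_per_interval * internal[i]
        internal[i + 1] = internal[i] - digested[i] - released[i]
        supernatant[i + 1] = supernatant[i] + released[i]

    truth = KineticsGroundTruth(internal, supernatant, digested, released)

    rng = np.random.default_rng(spec.seed)
    if spec.noise_cv > 0:
        obs_internal = internal * (1.0 + rng.normal(0.0, spec.noise_cv, n))
        obs_supernatant = supernatant * (1.0 + rng.normal(0.0, spec.noise_cv, n))
        obs_internal = np.maximum(obs_internal, 0.0)
        obs_supernatant = np.maximum(obs_supernatant, 0.0)
    else:
        obs_internal = internal.copy()
        obs_supernatant = supernatant.copy()

    table = pd.DataFrame(
        {
            "condition": condition,
            "replicate": replicate,
            "time_h": times,
            "internal_level": obs_internal,
            "supernatant_level": obs_supernatant,
        }
    )
    return table, truth
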