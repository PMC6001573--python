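"""Synthetic assay matrices (cytokine-array or expression flavor).

value(feature, sample) = baseline(feature) * effect(feature, condition)
                         * lognormal noise with the stated CV.

Expression flavor additionally marks a fraction of entries as
below-background (flag 0), mimicking scanner quality flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..omics import AssayTable


@dataclass(frozen=True)
class ConditionEffect:
    """One condition with per-feature multiplicative effects.

    ``effects`` may be a scalar (applied to all features) or an array of
    length n_features. All effects must be positive.
    """

    label: str
    effects: float | tuple[float, ...] = 1.0


@dataclass(frozen=True)
class AssaySpec:
    n_features: int = 40
    conditions: tuple[ConditionEffect, ...] = (
        ConditionEffect("control"),
        ConditionEffect("treated"),
    )
    n_replicates: int = 2
    noise_cv: float = 0.1
    flag_fraction: float = 0.0
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be at least 2")
        if not 0 <= self.flag_fraction <= 1:
            raise ValueError("flag_fraction must lie in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        for cond in self.conditions:
            eff = np.atleast_1d(np.asarray(cond.effects, dtype=float))
            if np.any(eff <= 0):
                raise ValueError(f"effects for condition {cond.label!r} must be positive")


def _effect_vector(cond: ConditionEffect, n_features: int) -> np.ndarray:
    eff = np.atleast_1d(np.asarray(cond.effects, dtype=float))
    if eff.size == 1:
        return np.full(n_features, eff[0])
    if eff.size != n_features:
        raise ValueError(
            f"condition {cond.label!r}: {eff.size} effects for {n_features} features"
        )
    return eff


def generate_assay_matrix(spec: AssaySpec) -> AssayTable:
    """Deterministic in spec + seed; returns an AssayTable with ground-truth
    effects recoverable from the spec itself.

    Lognormal noise uses sigma = sqrt(log(1 + cv^2)) with the mean
    correction so E[noise] = 1 and the planted effect is unbiased on the
    natural scale.
    """
    rng = np.random.default_rng(spec.seed)
    nf = spec.n_features
    baseline = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, nf)

    cols = []
    labels: list[str] = []
    conditions: list[str] = []
    replicates: list[int] = []
    sigma = float(np.sqrt(np.log1p(spec.noise_cv**2)))
    for cond in spec.conditions:
        eff = _effect_vector(cond, nf)
        for rep in range(1, spec.n_replicates + 1):
            if sigma > 0:
                noise = rng.lognormal(-(sigma**2) / 2.0, sigma, nf)
            else:
                noise = np.ones(nf)
            cols.append(baseline * eff * noise)
            labels.append(f"{cond.label}_r{rep}")
            conditions.append(cond.label)
            replicates.append(rep)

    values = np.column_stack(cols)
    n_samples = values.shape[1]
    if spec.flag_fraction > 0:
        flags = (rng.random((nf, n_samples)) >= spec.flag_fraction).astype(int)
    else:
        flags = np.ones((nf, n_samples), dtype=int)

    return AssayTable(
        values=values,
        feature_ids=[f"feat_{i:04d}" for i in range(nf)],
        sample_labels=labels,
        conditions=conditions,
        replicates=replicates,
        flags=flags,
    )
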