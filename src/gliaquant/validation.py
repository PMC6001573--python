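"""Self-validation benchmarks: every pipeline stage exercised end-to-end on
synthetic data with planted ground truth.

Each function generates its own inputs from a seed, runs the relevant
pipeline stage, and returns summary numbers; the test suite asserts the
documented tolerances on them.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from .errors import NoReversalError
from .ephys import (
    VoltageStepProtocol,
    detect_mepscs,
    difference_curve,
    estimate_noise_sd,
    estimate_reversal_potential,
    measure_step_currents,
)
from .kinetics import degradation_deltas, timecourses_from_table
from .motility import SegmentationParams, analyze_movie
from .omics import normalize_75th, pca_conditions, select_degs
from .omics import AssayTable
from .synth import (
    AssaySpec,
    ConditionEffect,
    KineticsSpec,
    MepscSpec,
    MovieSpec,
    SweepSpec,
    generate_assay_matrix,
    generate_cell_movie,
    generate_degradation_timecourse,
    generate_mepsc_trace,
    generate_sweepset,
    steady_state_current_pA,
)

_NOISE_FREE_SEG = SegmentationParams(smoothing_sigma_px=0.0)


def _match_tracks(tracks, gt, pixel_size_um):
    mapping = {}
    for t in tracks:
        f0 = int(t.frame_indices[0])
        c0 = np.asarray(t.centroids_um[0]) / pixel_size_um
        sub = gt.table[gt.table.frame == f0]
        d = np.hypot(sub.x_px - c0[0], sub.y_px - c0[1])
        mapping[t.cell_id] = int(sub.iloc[int(np.argmin(d.values))].cell_id)
    return mapping


def motility_oracle_check(seed: int = 0, n_cells: int = 10, n_frames: int = 60) -> dict:
    """Pipeline metrics vs direct recomputation from generator ground truth
    on a noise-free movie. Returns worst-case relative errors and whether
    every per-cell transition count matched exactly."""
    spec = MovieSpec(
        n_cells=n_cells, duration_frames=n_frames, image_shape=(768, 768),
        translocation_speed_um_min=2.0, membrane_change_rate=0.06,
        morph_transition_prob=0.04, noise_level=0.0, seed=seed,
    )
    movie, gt = generate_cell_movie(spec)
    tracks, metrics = analyze_movie(movie, seg_params=_NOISE_FREE_SEG, max_step_um=8.0)
    mapping = _match_tracks(tracks, gt, spec.pixel_size_um)
    by_id = {m.cell_id: m for m in metrics}

    dap_err, speed_err, trans_ok = [], [], []
    for t in tracks:
        m = by_id[t.cell_id]
        cid = mapping[t.cell_id]
        gt_dap = float(gt.membrane_change_series_um(cid).mean())
        gt_speed = gt.speed_um_min(cid)
        dap_err.append(abs(m.membrane_change_um - gt_dap) / gt_dap)
        speed_err.append(abs(m.cell_speed_um_min - gt_speed) / gt_speed)
        trans_ok.append(m.n_transitions == gt.transition_counts[cid])
    return {
        "n_tracks": len(tracks),
        "n_cells": n_cells,
        "max_dap_rel_err": float(max(dap_err)),
        "max_speed_rel_err": float(max(speed_err)),
        "transitions_all_exact": bool(all(trans_ok)) and len(tracks) == n_cells,
    }


def dissociation_sweep(
    seed: int = 0,
    levels: tuple[float, ...] = (0.02, 0.04, 0.06, 0.08, 0.10),
    n_cells: int = 10,
    n_frames: int = 40,
) -> dict:
    """Sweep the planted membrane-change level at fixed translocation speed:
    mean dA/p must track the level while mean speed stays put."""
    daps, speeds = [], []
    for level in levels:
        spec = MovieSpec(
            n_cells=n_cells, duration_frames=n_frames, image_shape=(768, 768),
            translocation_speed_um_min=3.0, membrane_change_rate=level,
            morph_transition_prob=0.0, noise_level=0.0, seed=seed,
        )
        movie, _ = generate_cell_movie(spec)
        _, metrics = analyze_movie(movie, seg_params=_NOISE_FREE_SEG, max_step_um=8.0)
        daps.append(float(np.mean([m.membrane_change_um for m in metrics])))
        speeds.append(float(np.mean([m.cell_speed_um_min for m in metrics])))
    rho = float(spearmanr(levels, daps).statistic)
    speed_rel_range = float((max(speeds) - min(speeds)) / np.mean(speeds))
    return {
        "levels": list(levels),
        "mean_dap": daps,
        "mean_speed": speeds,
        "spearman_rho": rho,
        "speed_rel_range": speed_rel_range,
    }


def reversal_recovery(seed: int = 0, n_trials: int = 100, noise_sd_pA: float = 5.0) -> dict:
    """Difference-current reversal estimation against planted reversals
    uniform in [-20, +30] mV on the 20 mV step grid."""
    rng = np.random.default_rng(seed)
    proto = VoltageStepProtocol()
    errors, failures = [], 0
    for trial in range(n_trials):
        true_e = float(rng.uniform(-20.0, 30.0))
        s_before = int(rng.integers(0, 2**31))
        s_after = int(rng.integers(0, 2**31))
        before = SweepSpec(
            protocol=proto, leak_conductance_nS=1.0, leak_reversal_mV=-40.0,
            noise_sd_pA=noise_sd_pA, seed=s_before,
        )
        after = SweepSpec(
            protocol=proto, leak_conductance_nS=1.0, leak_reversal_mV=-40.0,
            added_conductance_nS=0.5, added_reversal_mV=true_e,
            rectification="outward", rectification_gain=1.25,
            noise_sd_pA=noise_sd_pA, seed=s_after,
        )
        diff = difference_curve(
            measure_step_currents(generate_sweepset(after)),
            measure_step_currents(generate_sweepset(before)),
        )
        try:
            rev = estimate_reversal_potential(diff)
        except NoReversalError:
            failures += 1
            continue
        errors.append(abs(rev.reversal_potential_mV - true_e))
    return {
        "n_trials": n_trials,
        "median_abs_error_mV": float(np.median(errors)),
        "n_no_reversal": failures,
    }


def step_window_check(tau_values_ms: tuple[float, ...] = (1.0, 5.0, 10.0)) -> dict:
    """Measured last-two-thirds step currents vs the closed-form mean of the
    sampled steady-state + exponential transient (geometric series)."""
    proto = VoltageStepProtocol()
    worst = 0.0
    for tau in tau_values_ms:
        spec = SweepSpec(
            protocol=proto, leak_conductance_nS=1.0, leak_reversal_mV=0.0,
            capacitance_tau_ms=tau, noise_sd_pA=0.0,
        )
        iv = measure_step_currents(generate_sweepset(spec))
        fs = spec.sampling_hz
        n = int(round(proto.step_duration_ms / 1000.0 * fs))
        i0 = int(round(n / 3))
        q = np.exp(-(1000.0 / fs) / tau)
        order = np.argsort(proto.step_voltages_mV)
        for v, i_meas in zip(proto.step_voltages_mV[order], iv.currents_pA):
            s = float(steady_state_current_pA(spec, v))
            a = spec.capacitance_scale_pA_per_mV * (v - proto.holding_mV)
            expected = s + a * q**i0 * (1 - q ** (n - i0)) / ((n - i0) * (1 - q))
            if expected != 0:
                worst = max(worst, abs(i_meas - expected) / abs(expected))
    return {"max_rel_error": float(worst)}


def detector_operating_check(
    seed: int = 0,
    ks: tuple[float, ...] = (3.0, 3.5, 4.0),
    n_seeds: int = 10,
    duration_s: float = 60.0,
) -> dict:
    """Sensitivity/amplitude recovery at SNR 10 and the false-positive rate
    on pure noise, across the detection-threshold multipliers."""
    rng = np.random.default_rng(seed)
    signal_seeds = [int(rng.integers(0, 2**31)) for _ in range(n_seeds)]
    noise_seeds = [int(rng.integers(0, 2**31)) for _ in range(n_seeds)]

    sensitivity: dict[float, float] = {}
    amp_ratio: dict[float, float] = {}
    traces = []
    for s in signal_seeds:
        spec = MepscSpec(
            duration_s=duration_s, event_rate_hz=5.0, amplitude_mean_pA=20.0,
            amplitude_cv=0.0, noise_sd_pA=2.0, seed=s,
        )
        trace, truth = generate_mepsc_trace(spec)
        traces.append((trace, truth, estimate_noise_sd(trace)))
    for k in ks:
        sens, ratios = [], []
        for trace, truth, noise in traces:
            events = detect_mepscs(trace, noise, k=k)
            det = events.peak_times_s
            matched = 0
            for t, a in zip(truth.peak_times_s, truth.amplitudes_pA):
                if det.size and np.abs(det - t).min() < 0.005:
                    matched += 1
                    ratios.append(events.amplitudes_pA[np.abs(det - t).argmin()] / a)
            sens.append(matched / len(truth))
        sensitivity[k] = float(np.mean(sens))
        amp_ratio[k] = float(np.mean(ratios))

    fp_counts = []
    for s in noise_seeds:
        spec = MepscSpec(duration_s=duration_s, event_rate_hz=0.0, noise_sd_pA=2.0, seed=s)
        trace, _ = generate_mepsc_trace(spec)
        fp_counts.append(len(detect_mepscs(trace, estimate_noise_sd(trace), k=4.0)))
    fp_per_min = float(np.mean(fp_counts) / (duration_s / 60.0))

    k_sorted = sorted(ks)
    monotone = all(
        sensitivity[k_sorted[i]] >= sensitivity[k_sorted[i + 1]] - 1e-12
        for i in range(len(k_sorted) - 1)
    )
    return {
        "sensitivity_by_k": {str(k): sensitivity[k] for k in ks},
        "amplitude_ratio_by_k": {str(k): amp_ratio[k] for k in ks},
        "false_positives_per_min_k4": fp_per_min,
        "sensitivity_monotone_nonincreasing": bool(monotone),
    }


def kinetics_conservation_check() -> dict:
    """Noise-free calibrated time course: mass balance and exact recovery of
    the planted per-interval amounts."""
    spec = KineticsSpec(
        initial_internal_level=1.7, digestion_fraction_per_interval=0.35,
        release_fraction_per_interval=0.15, interval_times_h=(0.0, 5.0, 9.0, 21.0),
        noise_cv=0.0,
    )
    table, truth = generate_degradation_timecourse(spec)
    tc = timecourses_from_table(table)[0]
    summ = degradation_deltas(tc, calibration=1.0)
    lhs = tc.internal_level[0] - tc.internal_level[-1]
    rhs = summ.cumulative_digested[-1] + summ.cumulative_released[-1]
    return {
        "conservation_residual": float(abs(lhs - rhs)),
        "max_delta_error": float(
            np.max(np.abs(summ.delta_digested - truth.digested_per_interval))
        ),
    }


def deg_calibration_check(seed: int = 0, n_features: int = 2000, n_seeds: int = 20) -> dict:
    """Null type-I rate at shrinkage 0, plus the planted-fold selection rules."""
    rng = np.random.default_rng(seed)
    null_p = []
    four_selected, onefive_selected = [], []
    for _ in range(n_seeds):
        s = int(rng.integers(0, 2**31))
        null_table = generate_assay_matrix(
            AssaySpec(
                n_features=n_features, n_replicates=3, noise_cv=0.2, seed=s,
                conditions=(ConditionEffect("a", 1.0), ConditionEffect("b", 1.0)),
            )
        )
        res = select_degs(null_table, "a", "b", shrinkage_weight=0.0)
        null_p.append(res.p_values)

        eff4 = np.ones(50); eff4[0] = 4.0
        eff15 = np.ones(50); eff15[1] = 1.5
        planted = generate_assay_matrix(
            AssaySpec(
                n_features=50, n_replicates=3, noise_cv=0.05, seed=s + 1,
                conditions=(
                    ConditionEffect("b", 1.0),
                    ConditionEffect("a", tuple(eff4 * eff15)),
                ),
            )
        )
        res_p = select_degs(planted, "a", "b")
        four_selected.append(bool(res_p.selected[0]))
        onefive_selected.append(bool(res_p.selected[1]))

    null_p = np.concatenate(null_p)
    rate = float((null_p < 0.05).mean())
    se = float(np.sqrt(0.05 * 0.95 / null_p.size))
    return {
        "type_i_rate": rate,
        "type_i_se": se,
        "n_null_features": int(null_p.size),
        "fourfold_always_selected": bool(all(four_selected)),
        "onepointfive_never_selected": bool(not any(onefive_selected)),
    }


def normalization_pca_identity_check(seed: int = 0) -> dict:
    """Upper-quartile alignment/idempotence and PCA identities vs an
    independent eigen-solve on a 6x4 matrix."""
    rng = np.random.default_rng(seed)
    table = AssayTable(
        values=rng.lognormal(3, 1, (200, 6)),
        feature_ids=[f"f{i}" for i in range(200)],
        sample_labels=[f"s{j}" for j in range(6)],
        conditions=["c"] * 6,
        replicates=list(range(6)),
    )
    once = normalize_75th(table)
    q = np.percentile(once.values, 75, axis=0)
    percentile_spread = float(np.max(np.abs(q - q[0])))
    twice = normalize_75th(once)
    idempotence_err = float(np.max(np.abs(once.values - twice.values)))

    values = rng.normal(10, 3, (6, 4))
    pca_table = AssayTable(
        values=values,
        feature_ids=[f"g{i}" for i in range(6)],
        sample_labels=[f"p{j}" for j in range(4)],
        conditions=["c"] * 4,
        replicates=list(range(4)),
    )
    res = pca_conditions(pca_table)
    x = values.T - values.T.mean(axis=0)
    w, v = np.linalg.eigh(x.T @ x / (x.shape[0] - 1))
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    scores_oracle = x @ v
    k = res.scores.shape[1]
    score_err = float(
        np.max(np.abs(np.abs(res.scores[:, :k]) - np.abs(scores_oracle[:, :k])))
    )
    return {
        "percentile_spread": percentile_spread,
        "idempotence_err": idempotence_err,
        "pov_sum": float(res.pov.sum()),
        "pca_score_err_vs_eigh": score_err,
    }


def qc_rule_check() -> dict:
    from .ephys import check_rs_stability

    discard_30 = not check_rs_stability(np.array([10.0, 13.0])).passed
    pass_10 = check_rs_stability(np.array([10.0, 11.0])).passed
    return {"discards_30pct_drift": bool(discard_30), "passes_10pct_drift": bool(pass_10)}
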