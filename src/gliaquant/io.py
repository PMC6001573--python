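"""File round-tripping for the package's standard formats.

Movies: multi-page TIFF + JSON sidecar (pixel size, frame interval, seed).
Sweeps / traces: HDF5 (time_s, current_pA, command_mV) or two-column CSV.
Assay matrices: TSV with feature ids in the first column, plus a parallel
0/1 flag TSV and a sample-annotation CSV.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .ephys.protocol import CurrentTrace, EventList, SweepSet, VoltageStepProtocol
from .motility.movie import TimeLapseMovie
from .omics import AssayTable

# ---------------------------------------------------------------------------
# movies


def write_movie(movie: TimeLapseMovie, path: str | Path, metadata: dict | None = None) -> Path:
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32))
    sidecar = {
        "pixel_size_um": movie.pixel_size_um,
        "frame_interval_s": movie.frame_interval_s,
    }
    if metadata:
        sidecar.update(metadata)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))
    return path


def read_movie(
    path: str | Path,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
) -> TimeLapseMovie:
    """Read a TIFF stack; calibration comes from the JSON sidecar unless
    overridden explicitly."""
    path = Path(path)
    frames = tifffile.imread(path)
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        pixel_size_um = pixel_size_um or sidecar.get("pixel_size_um")
        frame_interval_s = frame_interval_s or sidecar.get("frame_interval_s")
    if pixel_size_um is None or frame_interval_s is None:
        raise ValueError("pixel size and frame interval required (sidecar missing)")
    return TimeLapseMovie(frames, pixel_size_um, frame_interval_s)


def write_ground_truth(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# traces and sweep sets


def write_trace_h5(trace: CurrentTrace, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("time_s", data=trace.time_s)
        f.create_dataset("current_pA", data=trace.samples_pA)
        if trace.command_mV is not None:
            f.create_dataset("command_mV", data=trace.command_mV)
        f.attrs["sampling_hz"] = trace.sampling_hz
    return path


def read_trace_h5(path: str | Path) -> CurrentTrace:
    with h5py.File(path, "r") as f:
        current = f["current_pA"][:]
        command = f["command_mV"][:] if "command_mV" in f else None
        fs = float(f.attrs["sampling_hz"])
    return CurrentTrace(current, fs, command_mV=command)


def write_trace_csv(trace: CurrentTrace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": trace.time_s, "current_pA": trace.samples_pA}).to_csv(
        path, index=False
    )
    return path


def read_trace_csv(path: str | Path) -> CurrentTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    return CurrentTrace(df["current_pA"].to_numpy(), fs)


def write_sweepset_h5(sweeps: SweepSet, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["label"] = sweeps.label
        for key, val in asdict(sweeps.protocol).items():
            f.attrs[f"protocol_{key}"] = val
        f.attrs["sampling_hz"] = sweeps.traces[0].sampling_hz
        for j, trace in enumerate(sweeps.traces):
            f.create_dataset(f"step_{j:02d}/current_pA", data=trace.samples_pA)
            if trace.command_mV is not None:
                f.create_dataset(f"step_{j:02d}/command_mV", data=trace.command_mV)
    return path


def read_sweepset_h5(path: str | Path) -> SweepSet:
    with h5py.File(path, "r") as f:
        proto = VoltageStepProtocol(
            holding_mV=float(f.attrs["protocol_holding_mV"]),
            step_start_mV=float(f.attrs["protocol_step_start_mV"]),
            step_stop_mV=float(f.attrs["protocol_step_stop_mV"]),
            step_increment_mV=float(f.attrs["protocol_step_increment_mV"]),
            step_duration_ms=float(f.attrs["protocol_step_duration_ms"]),
            inter_step_interval_s=float(f.attrs["protocol_inter_step_interval_s"]),
        )
        fs = float(f.attrs["sampling_hz"])
        traces = []
        for j in range(proto.n_steps):
            grp = f[f"step_{j:02d}"]
            command = grp["command_mV"][:] if "command_mV" in grp else None
            traces.append(CurrentTrace(grp["current_pA"][:], fs, command_mV=command))
        return SweepSet(protocol=proto, traces=traces, label=str(f.attrs["label"]))


def write_events_csv(events: EventList, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "onset_s": events.onsets_s,
            "amplitude_pA": events.amplitudes_pA,
            "area_pA_ms": events.areas_pA_ms,
        }
    ).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# assay matrices


def write_assay_table(table: AssayTable, prefix: str | Path) -> dict[str, Path]:
    """Write <prefix>.tsv, <prefix>.flags.tsv and <prefix>.samples.csv."""
    prefix = Path(prefix)
    values_path = prefix.with_suffix(".tsv")
    df = pd.DataFrame(table.values, index=table.feature_ids, columns=table.sample_labels)
    df.to_csv(values_path, sep="\t", index_label="feature")
    out = {"values": values_path}

    if table.flags is not None:
        flags_path = prefix.with_suffix(".flags.tsv")
        pd.DataFrame(table.flags, index=table.feature_ids, columns=table.sample_labels).to_csv(
            flags_path, sep="\t", index_label="feature"
        )
        out["flags"] = flags_path

    samples_path = prefix.with_suffix(".samples.csv")
    pd.DataFrame(
        {
            "sample": table.sample_labels,
            "condition": table.conditions,
            "replicate": table.replicates,
        }
    ).to_csv(samples_path, index=False)
    out["samples"] = samples_path
    return out


def read_assay_table(
    values_tsv: str | Path,
    flags_tsv: str | Path | None = None,
    samples_csv: str | Path | None = None,
) -> AssayTable:
    df = pd.read_csv(values_tsv, sep="\t", index_col=0)
    flags = None
    if flags_tsv is not None:
        flags = pd.read_csv(flags_tsv, sep="\t", index_col=0).to_numpy()
    if samples_csv is not None:
        ann = pd.read_csv(samples_csv).set_index("sample").loc[list(df.columns)]
        conditions = [str(c) for c in ann["condition"]]
        replicates = [int(r) for r in ann["replicate"]]
    else:
        # fall back to "<condition>_r<rep>" labels
        conditions, replicates = [], []
        for lbl in df.columns:
            cond, _, rep = str(lbl).rpartition("_r")
            conditions.append(cond or str(lbl))
            replicates.append(int(rep) if rep.isdigit() else 1)
    return AssayTable(
        values=df.to_numpy(),
        feature_ids=[str(i) for i in df.index],
        sample_labels=[str(c) for c in df.columns],
        conditions=conditions,
        replicates=replicates,
        flags=flags,
    )
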