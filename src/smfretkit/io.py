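"""File formats for trace sets: per-trace TSV, manifest CSV, truth JSON,
and an optional single-container HDF5 export."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import FretTrace, KineticModel

__all__ = ["write_trace", "read_trace", "write_trace_set", "read_trace_set",
           "write_truth", "read_truth", "export_hdf5", "import_hdf5"]

MANIFEST_COLUMNS = ["trace_id", "file", "condition", "frame_period_s", "seed"]


def write_trace(path, trace: FretTrace) -> None:
    df = pd.DataFrame({"frame_index": np.arange(len(trace)),
                       "donor": trace.donor, "acceptor": trace.acceptor})
    df.to_csv(path, sep="\t", index=False)


def read_trace(path, frame_period: float, meta: dict | None = None) -> FretTrace:
    df = pd.read_csv(path, sep="\t")
    return FretTrace(frame_period, df["donor"].to_numpy(),
                     df["acceptor"].to_numpy(), meta=dict(meta or {}))


def write_trace_set(directory, traces, manifest_name="manifest.csv") -> Path:
    """Write one TSV per trace plus a manifest CSV; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, trace in enumerate(traces):
        trace_id = trace.meta.get("trace_id", f"trace-{i:05d}")
        fname = f"{trace_id}.tsv"
        write_trace(directory / fname, trace)
        rows.append({"trace_id": trace_id, "file": fname,
                     "condition": trace.meta.get("condition", ""),
                     "frame_period_s": trace.frame_period,
                     "seed": trace.meta.get("seed", "")})
    manifest = directory / manifest_name
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def read_trace_set(manifest_path) -> list:
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    traces = []
    for _, row in manifest.iterrows():
        meta = {"trace_id": row["trace_id"], "condition": row["condition"],
                "seed": row["seed"]}
        traces.append(read_trace(manifest_path.parent / row["file"],
                                 float(row["frame_period_s"]), meta))
    return traces


def write_truth(path, model: KineticModel, truths) -> None:
    """Ground-truth JSON for a simulated trace set."""
    payload = {
        "emission_means": model.emission_means.tolist(),
        "noise_sd": model.noise_sd,
        "rate_matrix": model.rate_matrix.tolist(),
        "bleach_frames": [t.bleach_frame for t in truths],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def export_hdf5(path, traces) -> None:
    """Write a trace set into one hierarchical HDF5 container."""
    import h5py

    with h5py.File(path, "w") as fh:
        for i, trace in enumerate(traces):
            grp = fh.create_group(trace.meta.get("trace_id", f"trace-{i:05d}"))
            grp.create_dataset("donor", data=trace.donor)
            grp.create_dataset("acceptor", data=trace.acceptor)
            grp.attrs["frame_period_s"] = trace.frame_period
            grp.attrs["condition"] = trace.meta.get("condition", "")


def import_hdf5(path) -> list:
    import h5py

    traces = []
    with h5py.File(path, "r") as fh:
        for key in sorted(fh):
            grp = fh[key]
            traces.append(FretTrace(
                float(grp.attrs["frame_period_s"]),
                grp["donor"][...], grp["acceptor"][...],
                meta={"trace_id": key,
                      "condition": str(grp.attrs.get("condition", ""))}))
    return traces
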