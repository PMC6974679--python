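"""Reading and writing the pipeline's containers.

HDF5 is the canonical tensor container (signals and connectivity tensors);
JSON holds codebooks, symbolic sequences and ground truth; CSV holds tidy
per-subject metric tables. Every writer/reader pair round-trips exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from nmstate.connectivity import ROITimeseries
from nmstate.microstates import Codebook, SymbolicTimeSeries

__all__ = [
    "write_signals",
    "read_signals",
    "read_signals_csv",
    "write_dfcg",
    "read_dfcg",
    "write_codebook",
    "read_codebook",
    "write_sts",
    "read_sts",
    "write_ground_truth",
    "read_ground_truth",
    "profiles_to_frame",
    "read_subnetwork_map",
]


class FormatError(ValueError):
    """Raised when a file does not match the expected layout."""


def write_signals(path, ts: ROITimeseries, group: str | None = None) -> None:
    """Write one subject's signal matrix to HDF5 (dataset ``signals``)."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("signals", data=ts.signals)
        d.attrs["fs"] = ts.fs
        d.attrs["band"] = list(ts.band)
        d.attrs["node_labels"] = [str(s) for s in ts.node_labels]
        if group is not None:
            d.attrs["group"] = group


def read_signals(path) -> tuple[ROITimeseries, str | None]:
    """Read a subject's HDF5 signal file; returns (timeseries, group)."""
    try:
        with h5py.File(path, "r") as f:
            if "signals" not in f:
                raise FormatError(f"{path}: missing 'signals' dataset")
            d = f["signals"]
            if "fs" not in d.attrs or "band" not in d.attrs:
                raise FormatError(f"{path}: missing fs/band attributes")
            ts = ROITimeseries(
                signals=d[()],
                fs=float(d.attrs["fs"]),
                band=tuple(float(v) for v in d.attrs["band"]),
                node_labels=[str(s) for s in d.attrs.get("node_labels", [])],
            )
            group = d.attrs.get("group")
            return ts, (str(group) if group is not None else None)
    except OSError as e:
        raise FormatError(f"{path}: not a readable HDF5 file ({e})") from e


def read_signals_csv(path, fs: float, band: tuple[float, float]) -> ROITimeseries:
    """Read a delimited signal matrix (rows = nodes, header = node labels)."""
    df = pd.read_csv(path)
    return ROITimeseries(
        signals=df.to_numpy(dtype=float).T,
        fs=fs,
        band=band,
        node_labels=list(df.columns),
    )


def write_dfcg(path, tensor: np.ndarray, window_len: int, step: int) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("dfcg", data=tensor)
        d.attrs["window_len"] = window_len
        d.attrs["step"] = step


def read_dfcg(path) -> tuple[np.ndarray, int, int]:
    with h5py.File(path, "r") as f:
        if "dfcg" not in f:
            raise FormatError(f"{path}: missing 'dfcg' dataset")
        d = f["dfcg"]
        return d[()], int(d.attrs["window_len"]), int(d.attrs["step"])


def write_codebook(path, codebook: Codebook) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "prototypes": codebook.prototypes.tolist(),
                "assignments": codebook.assignments.tolist(),
                "distortion": codebook.distortion,
            }
        )
    )


def read_codebook(path) -> Codebook:
    d = json.loads(Path(path).read_text())
    return Codebook(
        prototypes=np.asarray(d["prototypes"], dtype=float),
        assignments=np.asarray(d["assignments"], dtype=int),
        distortion=float(d["distortion"]),
    )


def write_sts(path, sts: SymbolicTimeSeries) -> None:
    Path(path).write_text(
        json.dumps({"labels": sts.labels.tolist(), "k": sts.k, "meta": sts.meta})
    )


def read_sts(path) -> SymbolicTimeSeries:
    d = json.loads(Path(path).read_text())
    return SymbolicTimeSeries(
        labels=np.asarray(d["labels"], dtype=int), k=int(d["k"]), meta=d.get("meta", {})
    )


def write_ground_truth(path, gt) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "state_sequences": {
                    s: seq.tolist() for s, seq in gt.state_sequences.items()
                },
                "groups": gt.groups,
                "coupling_graphs": {
                    str(k): v.tolist() for k, v in gt.coupling_graphs.items()
                },
            }
        )
    )


def read_ground_truth(path) -> dict:
    d = json.loads(Path(path).read_text())
    d["state_sequences"] = {
        s: np.asarray(seq, dtype=int) for s, seq in d["state_sequences"].items()
    }
    d["coupling_graphs"] = {
        int(k): np.asarray(v, dtype=float) for k, v in d["coupling_graphs"].items()
    }
    return d


def profiles_to_frame(profiles: dict, groups: dict, band: str = "") -> pd.DataFrame:
    """Tidy per-subject chronnectomic table.

    One row per (subject, metric, state): FI and CI have state "", OT/DT
    one row per state, PT one row per ordered state pair.
    """
    rows = []
    for sid, prof in profiles.items():
        g = groups.get(sid, "")
        p = prof.pvalues or {}

        def row(metric, state, value, pval):
            rows.append(
                {
                    "subject": sid,
                    "group": g,
                    "band": band,
                    "metric": metric,
                    "state": state,
                    "value": float(value),
                    "p": float(pval) if pval is not None else np.nan,
                }
            )

        row("FI", "", prof.fi, p.get("fi"))
        row("CI", "", prof.ci, p.get("ci"))
        for s in range(prof.k):
            row("OT", str(s + 1), prof.ot[s], p["ot"][s] if "ot" in p else None)
            row("DT", str(s + 1), prof.dt[s], p["dt"][s] if "dt" in p else None)
            for s2 in range(prof.k):
                row(
                    "PT",
                    f"{s + 1}->{s2 + 1}",
                    prof.pt[s, s2],
                    p["pt_fdr"][s, s2] if "pt_fdr" in p else None,
                )
    return pd.DataFrame(rows)


def read_subnetwork_map(path) -> dict:
    """Two-column CSV (node index or label, subnetwork) → mapping dict."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError("subnetwork map needs two columns: node, label")
    nodes = df.iloc[:, 0]
    try:
        nodes = nodes.astype(int)
    except (TypeError, ValueError):
        pass
    return dict(zip(nodes, df.iloc[:, 1].astype(str)))
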