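"""Readers and writers for datasets, TVC series and benchmark reports.

All on-disk formats are plain text: long-format CSV for data and tables,
JSON for reports and state schedules.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bench import BenchmarkReport
from .simgen import SimulatedDataset

__all__ = [
    "write_dataset_csv",
    "read_dataset_csv",
    "write_tvc_csv",
    "read_roi_matrix",
    "write_report",
    "write_report_tables",
]


def write_dataset_csv(ds: SimulatedDataset, path) -> None:
    """Long-format CSV (t, x, y, r_true, mu_t, sim_id); the state schedule,
    if any, goes to a ``<stem>.schedule.json`` sidecar."""
    path = Path(path)
    T = ds.T
    df = pd.DataFrame({
        "t": np.arange(T),
        "x": ds.pair.x,
        "y": ds.pair.y,
        "r_true": ds.truth.r if ds.truth is not None else np.full(T, np.nan),
        "mu_t": ds.mean_track if ds.mean_track is not None else np.zeros(T),
        "sim_id": ds.pair.meta.get("sim", -1),
    })
    df.to_csv(path, index=False)
    if ds.schedule is not None:
        sidecar = path.with_suffix(".schedule.json")
        sidecar.write_text(json.dumps({
            "segments": [list(s) for s in ds.schedule.segments],
            "state_means": list(ds.schedule.state_means),
            "duration_set": list(ds.schedule.duration_set),
        }, indent=1))


def read_dataset_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_tvc_csv(series_dict, path) -> None:
    """Long-format CSV (t, method, estimate, valid) for a dict of TVCSeries."""
    frames = []
    for name, s in series_dict.items():
        frames.append(pd.DataFrame({
            "t": np.arange(s.T),
            "method": name,
            "estimate": s.estimate,
            "valid": s.valid,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_roi_matrix(path) -> np.ndarray:
    """Read a rows-x-ROIs plain-text matrix (CSV or TSV, header row of labels)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    values = df.to_numpy(dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("expected at least two ROI columns")
    return values


def write_report(report: BenchmarkReport, out_dir) -> Path:
    """Write report.json (+ CSV tables) into ``out_dir``; returns the JSON path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(report.to_dict(), indent=1))
    write_report_tables(report.to_dict(), out_dir / "tables")
    return json_path


def _condition_tag(entry: dict) -> str:
    bits = [f"sim{entry['sim']}"]
    for k, v in sorted(entry["params"].items()):
        bits.append(f"{k}-{v}")
    return "_".join(bits)


def write_report_tables(report_dict: dict, tables_dir) -> None:
    """Render the per-condition WAIC/posterior tables and the similarity
    matrix as CSV files (one file per condition)."""
    tables_dir = Path(tables_dir)
    tables_dir.mkdir(parents=True, exist_ok=True)
    for entry in report_dict["conditions"]:
        tag = _condition_tag(entry)
        if entry["similarity"] is not None:
            sim = entry["similarity"]
            pd.DataFrame(sim["matrix"], index=sim["methods"],
                         columns=sim["methods"]).to_csv(
                tables_dir / f"{tag}_similarity.csv")
        if entry["waic_table"] is not None:
            waic = pd.DataFrame(entry["waic_table"]).set_index("method")
            post = pd.DataFrame(entry["posterior"]).set_index("method")
            waic.join(post).to_csv(tables_dir / f"{tag}_model_comparison.csv")
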