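"""Tabular I/O and run manifests shared by the pipeline stages."""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("dataset_id", "time_hr", "dose_equiv_gy")


def read_repair_curves(path, dataset_specs: dict) -> list:
    """Read observed repair curves and join them onto configured datasets.

    ``path`` is a CSV file with columns ``dataset_id, time_hr,
    dose_equiv_gy`` (several datasets may share one file) or a directory of
    such CSVs.  ``dataset_specs`` maps id to the configured skeleton
    :class:`~dsbrepair.hierarchy.DatasetSpec`; the returned specs carry the
    observations on the file's time grid.
    """
    path = Path(path)
    files = sorted(path.glob("*.csv")) if path.is_dir() else [path]
    if not files:
        raise FileNotFoundError(f"no CSV files under {path}")
    frames = []
    for f in files:
        df = pd.read_csv(f)
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"{f}: missing required column {col!r}")
        frames.append(df[list(REQUIRED_COLUMNS)])
    table = pd.concat(frames, ignore_index=True)
    if np.any(table["time_hr"] < 0) or np.any(table["dose_equiv_gy"] < 0):
        raise ValueError("negative time or dose-equivalent values in input")
    out = []
    for did, group in table.groupby("dataset_id", sort=True):
        if did not in dataset_specs:
            raise ValueError(f"unknown dataset id {did!r} (not in configuration)")
        t = group["time_hr"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{did}: time points must be strictly increasing")
        skeleton = dataset_specs[did]
        spec = skeleton.with_observed(group["dose_equiv_gy"].to_numpy(dtype=float))
        spec.timepoints = t
        out.append(spec.validate())
    return out


def write_repair_curves(datasets, path) -> Path:
    """Write datasets to a single tidy CSV (inverse of read on values)."""
    rows = [
        pd.DataFrame(
            {"dataset_id": d.id, "time_hr": d.timepoints, "dose_equiv_gy": d.observed}
        )
        for d in datasets
    ]
    path = Path(path)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    return path


@dataclass
class RunManifest:
    """Record of one pipeline invocation: inputs, seed, timings, outputs.

    Written as JSON next to the outputs, even when the run fails (with the
    error recorded), so every artifact can be traced to its inputs.
    """

    command: str
    seed: int = None
    config: str = None
    started: float = field(default_factory=time.time)
    outputs: list = field(default_factory=list)
    status: str = "running"
    error: str = None
    timings: dict = field(default_factory=dict)

    def add_output(self, path):
        self.outputs.append(str(path))

    def finish(self, status: str = "ok", error: str = None):
        self.status = status
        self.error = error
        self.timings["wall_seconds"] = round(time.time() - self.started, 3)

    def write(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        doc = {
            "command": self.command,
            "seed": self.seed,
            "config": self.config,
            "status": self.status,
            "error": self.error,
            "outputs": self.outputs,
            "timings": self.timings,
        }
        path.write_text(json.dumps(doc, indent=2))
        return path
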