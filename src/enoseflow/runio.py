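"""On-disk formats: per-run CSV files and dataset directories.

A run file carries its metadata in ``# key: value`` header lines followed
by a ``time_s,no_voltage_v,flow_sccm`` table.  A dataset is a directory of
run files plus a ``manifest.csv`` listing them with their conditions,
mirroring the per-run acquisition of the bench system.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .preprocess import CalibrationSample, frame_to_samples, samples_to_frame
from .simulate import Condition, RunSeries

__all__ = [
    "write_run",
    "read_run",
    "write_dataset",
    "read_dataset",
    "write_features",
    "read_features",
]

_META_KEYS = ("concentration_ppb", "flow_sccm", "replicate", "split", "sample_rate_hz")


def write_run(run: RunSeries, path) -> None:
    """Write one run to CSV with metadata header lines."""
    path = Path(path)
    cond = run.condition
    with open(path, "w", newline="") as fh:
        fh.write(f"# concentration_ppb: {cond.concentration_ppb:.9g}\n")
        fh.write(f"# flow_sccm: {cond.flow_sccm:.9g}\n")
        fh.write(f"# replicate: {cond.replicate}\n")
        fh.write(f"# split: {cond.split}\n")
        fh.write(f"# sample_rate_hz: {run.sample_rate_hz:.9g}\n")
        writer = csv.writer(fh)
        writer.writerow(["time_s", "no_voltage_v", "flow_sccm"])
        for t, v, f in zip(run.time_s, run.no_voltage, run.flow_sccm):
            writer.writerow([f"{t:.6g}", f"{v:.10g}", f"{f:.10g}"])


def read_run(path) -> RunSeries:
    """Read a run file; duration is reconstructed as rows / sample_rate."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            try:
                key, value = line[1:].split(":", 1)
            except ValueError as exc:
                raise ValueError(f"format error in {path}: malformed metadata line {line!r}") from exc
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        table = pd.read_csv(fh)

    missing = set(_META_KEYS) - set(meta)
    if missing:
        raise ValueError(f"format error in {path}: missing metadata keys {sorted(missing)}")
    for col in ("time_s", "no_voltage_v", "flow_sccm"):
        if col not in table.columns:
            raise ValueError(f"format error in {path}: missing column {col!r}")
        if not np.issubdtype(table[col].dtype, np.number):
            raise ValueError(f"parse error in {path}: non-numeric values in column {col!r}")

    rate = float(meta["sample_rate_hz"])
    n = len(table)
    cond = Condition(
        float(meta["concentration_ppb"]), float(meta["flow_sccm"]), int(meta["replicate"]), meta["split"]
    )
    return RunSeries(cond, rate, n / rate, table["no_voltage_v"].to_numpy(), table["flow_sccm"].to_numpy())


def _run_filename(cond: Condition) -> str:
    return f"run_c{cond.concentration_ppb:07.2f}_f{cond.flow_sccm:06.1f}_r{cond.replicate}.csv"


def write_dataset(runs: Iterable[RunSeries], out_dir) -> Path:
    """Write one CSV per run plus a manifest; returns the directory path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for run in runs:
        name = _run_filename(run.condition)
        write_run(run, out_dir / name)
        cond = run.condition
        rows.append(
            {
                "file": name,
                "concentration_ppb": cond.concentration_ppb,
                "flow_sccm": cond.flow_sccm,
                "replicate": cond.replicate,
                "split": cond.split,
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    return out_dir


def read_dataset(in_dir) -> list[RunSeries]:
    """Read every run listed in a dataset directory's manifest."""
    in_dir = Path(in_dir)
    manifest = in_dir / "manifest.csv"
    if not manifest.exists():
        raise ValueError(f"format error: no manifest.csv in {in_dir}")
    table = pd.read_csv(manifest)
    return [read_run(in_dir / name) for name in table["file"]]


def write_features(samples, path) -> None:
    samples_to_frame(samples).to_csv(path, index=False)


def read_features(path) -> list[CalibrationSample]:
    return frame_to_samples(pd.read_csv(path))
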