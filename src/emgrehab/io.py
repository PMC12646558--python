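"""File formats: EMG CSV + JSON sidecar, clinical tables, manifests.

All formats are plain text and diff-able. The EMG file is a CSV with header
``time_s,ch1,...,chK`` (seconds as floats, one row per sample); the sidecar
is a JSON object with the sampling frequency, identifying metadata, and the
0-based half-open contraction boundaries. The clinical table is a CSV with
header ``patient_id,group,week,fma_ue,arat,bbt``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import DataError, EMGRecording

_TIME_TOL_PPM = 1.0


def write_emg(rec: EMGRecording, csv_path: str | Path,
              sidecar_path: str | Path) -> None:
    """Write one recording as CSV + JSON sidecar (deterministic formatting)."""
    n_ch = rec.n_channels
    header = "time_s," + ",".join(f"ch{c + 1}" for c in range(n_ch))
    t = np.arange(rec.n_samples) / rec.fs
    table = np.column_stack([t, rec.data.T])
    np.savetxt(csv_path, table, delimiter=",", header=header, comments="",
               fmt="%.6f")
    sidecar = {"fs_hz": rec.fs, "n_channels": n_ch, "n_samples": rec.n_samples}
    for key in ("patient_id", "group", "week", "movement", "repetitions",
                "separability", "filters"):
        if key in rec.meta:
            sidecar[key] = rec.meta[key]
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)


def read_emg(csv_path: str | Path, sidecar_path: str | Path) -> EMGRecording:
    """Read an EMG CSV + sidecar back into an :class:`EMGRecording`.

    Validates the header, time-column monotonicity and spacing (must match
    the sidecar ``fs_hz`` within 1 ppm), and the row count.
    """
    csv_path = Path(csv_path)
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    fs = float(sidecar["fs_hz"])
    n_ch = int(sidecar["n_channels"])
    expected_header = "time_s," + ",".join(f"ch{c + 1}" for c in range(n_ch))
    with open(csv_path) as fh:
        header = fh.readline().strip()
    if header != expected_header:
        raise DataError(f"{csv_path}: header {header!r} does not match "
                        f"expected {expected_header!r}")
    try:
        table = np.loadtxt(csv_path, delimiter=",", skiprows=1, ndmin=2)
    except ValueError as exc:
        raise DataError(f"{csv_path}: malformed row ({exc})") from exc
    if table.shape[1] != n_ch + 1:
        raise DataError(f"{csv_path}: expected {n_ch + 1} columns, "
                        f"found {table.shape[1]}")
    if "n_samples" in sidecar and table.shape[0] != int(sidecar["n_samples"]):
        raise DataError(f"{csv_path}: truncated at row {table.shape[0]} "
                        f"(sidecar promises {sidecar['n_samples']} samples)")
    t = table[:, 0]
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 1
        raise DataError(f"{csv_path}: non-monotone time at row {bad}")
    step = float(np.median(dt))
    # times are written at microsecond resolution, so tolerate that
    # quantization on top of the 1 ppm spacing contract
    tol = max(_TIME_TOL_PPM * 1e-6 / fs, 1.0e-6)
    if abs(step - 1.0 / fs) > tol:
        raise DataError(f"{csv_path}: time step {step:.8f}s disagrees with "
                        f"sidecar fs {fs} Hz")
    meta = {k: sidecar[k] for k in sidecar if k not in ("fs_hz",)}
    return EMGRecording(data=np.ascontiguousarray(table[:, 1:].T), fs=fs, meta=meta)


def write_clinical(rows: Iterable[Mapping], path: str | Path) -> None:
    df = pd.DataFrame(list(rows))
    df = df[["patient_id", "group", "week", "fma_ue", "arat", "bbt"]]
    df.to_csv(path, index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = ["patient_id", "group", "week", "fma_ue", "arat", "bbt"]
    if list(df.columns) != expected:
        raise DataError(f"{path}: clinical table columns {list(df.columns)} "
                        f"do not match {expected}")
    return df


def read_manifest(path: str | Path, verify: bool = True) -> dict:
    """Load a dataset manifest, optionally validating every checksum."""
    path = Path(path)
    with open(path) as fh:
        manifest = json.load(fh)
    base = path.parent
    for entry in manifest["files"]:
        fpath = base / entry["path"]
        if not fpath.exists():
            raise DataError(f"manifest references missing file {fpath}")
        if verify:
            digest = hashlib.sha256(fpath.read_bytes()).hexdigest()
            if digest != entry["sha256"]:
                raise DataError(f"checksum mismatch for {fpath}")
    return manifest
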