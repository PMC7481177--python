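"""Dataset container I/O.

A dataset lives in an HDF5 container of 2-D float arrays (e.g. ``clean`` /
``corrupted`` record matrices, or ``windows``) plus a CSV manifest sidecar
with one row per array row.  Writes are byte-deterministic: datasets are
created with ``track_times=False`` so regenerating with the same seed gives
bit-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import ValidationError

SCHEMA_VERSION = 1

#: Manifest columns and the default used when a column is absent on read.
MANIFEST_DEFAULTS = {
    "id": None,
    "subject_id": None,
    "window_index": 0,
    "rhythm": "UNKNOWN",
    "qa_true": "UNKNOWN",
    "noise_factor": np.nan,
    "seed": -1,
}


def manifest_path(container: Path | str) -> Path:
    p = Path(container)
    return p.with_name(p.stem + ".manifest.csv")


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable config block."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_container(path: Path | str, arrays: dict[str, np.ndarray],
                    manifest: pd.DataFrame, attrs: dict | None = None) -> Path:
    """Write arrays + manifest; returns the container path.

    Every array must have as many rows as the manifest.
    """
    path = Path(path)
    n = len(manifest)
    for name, arr in arrays.items():
        if arr.shape[0] != n:
            raise ValidationError(
                f"array '{name}' has {arr.shape[0]} rows but manifest has {n}")
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w", libver="earliest") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        for key, val in (attrs or {}).items():
            fh.attrs[key] = val
        for name, arr in arrays.items():
            fh.create_dataset(name, data=np.asarray(arr, dtype=np.float64),
                              track_times=False)
    manifest.to_csv(manifest_path(path), index=False)
    return path


def read_container(path: Path | str) -> tuple[dict[str, np.ndarray], pd.DataFrame, dict]:
    """Read a container back; missing manifest columns get schema defaults."""
    path = Path(path)
    with h5py.File(path, "r") as fh:
        version = int(fh.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValidationError(
                f"container schema version {version} != supported "
                f"{SCHEMA_VERSION}; regenerate or migrate the container")
        arrays = {name: np.array(fh[name]) for name in fh.keys()}
        attrs = {k: fh.attrs[k] for k in fh.attrs.keys()}
    manifest = pd.read_csv(manifest_path(path))
    for col, default in MANIFEST_DEFAULTS.items():
        if col not in manifest.columns and default is not None:
            manifest[col] = default
    return arrays, manifest, attrs


def read_delimited_signal(path: Path | str) -> np.ndarray:
    """Read a single-channel PPG trace stored one sample per row."""
    arr = np.loadtxt(path, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    return arr
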