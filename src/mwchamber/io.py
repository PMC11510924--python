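"""Persistence: Touchstone S-matrices, HDF5 datasets, YAML configs, JSON reports."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .em_forward import SMatrix
from .scenarios import Dataset

__all__ = [
    "write_touchstone",
    "read_touchstone",
    "save_dataset",
    "load_dataset",
    "config_hash",
    "save_report",
]


def write_touchstone(path, s: SMatrix, *, z0: float = 50.0) -> None:
    """Write an N-port S-matrix as a Touchstone .sNp file (RI format, GHz).

    For N > 2 Touchstone expects network data in rows of at most four
    entry pairs, row-major over (i, j).
    """
    n = s.n_ports
    path = Path(path)
    if path.suffix.lower() != f".s{n}p":
        path = path.with_suffix(f".s{n}p")
    lines = [
        f"! mwchamber {s.kind} S-matrix, {n} ports",
        f"# GHz S RI R {z0:g}",
    ]
    freq_ghz = s.frequency / 1e9
    vals = []
    for i in range(n):
        for j in range(n):
            e = s.entries[i, j]
            vals.append(f"{e.real:.12e} {e.imag:.12e}")
    row_len = 4
    chunks = [vals[k : k + row_len] for k in range(0, len(vals), row_len)]
    lines.append(f"{freq_ghz:.9g} " + " ".join(chunks[0]))
    for ch in chunks[1:]:
        lines.append("  " + " ".join(ch))
    path.write_text("\n".join(lines) + "\n")


def read_touchstone(path) -> SMatrix:
    """Read a single-frequency Touchstone file written by :func:`write_touchstone`."""
    path = Path(path)
    n = int(path.suffix[2:-1])
    unit_scale = 1e9
    numbers: list[float] = []
    for line in path.read_text().splitlines():
        line = line.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("#"):
            toks = line[1:].split()
            unit = toks[0].lower() if toks else "ghz"
            unit_scale = {"hz": 1.0, "khz": 1e3, "mhz": 1e6, "ghz": 1e9}[unit]
            if "ri" not in [t.lower() for t in toks]:
                raise ValueError("only RI-format Touchstone files are supported")
            continue
        numbers.extend(float(t) for t in line.split())
    if len(numbers) != 1 + 2 * n * n:
        raise ValueError(f"expected {1 + 2 * n * n} values, got {len(numbers)}")
    freq = numbers[0] * unit_scale
    ri = np.asarray(numbers[1:]).reshape(n * n, 2)
    entries = (ri[:, 0] + 1j * ri[:, 1]).reshape(n, n)
    return SMatrix(entries, freq, "full")


def save_dataset(path, dataset: Dataset, *, config: dict | None = None) -> None:
    """Persist a dataset as HDF5 (features, labels, split, meta, config hash)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=dataset.features)
        f.create_dataset("labels", data=dataset.labels)
        f.create_dataset(
            "split", data=np.asarray(dataset.split, dtype="S12")
        )
        g = f.create_group("meta")
        for col in dataset.meta.columns:
            vals = dataset.meta[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S32")
            g.create_dataset(col, data=vals)
        if config is not None:
            f.attrs["config_hash"] = config_hash(config)
            f.attrs["config_yaml"] = yaml.safe_dump(_plain(config))


def load_dataset(path) -> Dataset:
    with h5py.File(path, "r") as f:
        feats = f["features"][...]
        labels = f["labels"][...]
        split = f["split"][...].astype(str)
        meta = {}
        for col in f["meta"]:
            v = f["meta"][col][...]
            if v.dtype.kind == "S":
                v = v.astype(str)
            meta[col] = v
    return Dataset(feats, labels, np.asarray(split, dtype=object), pd.DataFrame(meta))


def _plain(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _plain(asdict(obj))
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_hash(config) -> str:
    """Content hash of a configuration (dataclass/dict), stable across runs."""
    blob = json.dumps(_plain(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_report(path, report, *, dataset_hash: str | None = None) -> None:
    d = report.to_dict()
    if dataset_hash:
        d["dataset_hash"] = dataset_hash
    Path(path).write_text(json.dumps(d, indent=2) + "\n")
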