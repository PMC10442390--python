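"""On-disk formats: columnar sweep files with JSON metadata sidecars, fit
JSONs with provenance, and YAML/JSON run configuration."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .simulate import SweepSet

__all__ = ["write_sweepset", "read_sweepset", "write_fit_json", "load_config",
           "RunConfigError"]

SCHEMA_VERSION = 1
HDF5_THRESHOLD = 100  # sweeps; larger families go to HDF5


class RunConfigError(ValueError):
    """Configuration validation failure with a path-precise message."""


def _metadata_sidecar(sweepset: SweepSet) -> dict:
    md = dict(sweepset.metadata)
    md.setdefault("schema_version", SCHEMA_VERSION)
    md["kind"] = sweepset.kind
    md["sweep_values"] = sweepset.sweep_values
    payload = json.dumps(md, sort_keys=True, default=float)
    md["config_hash"] = hashlib.sha256(payload.encode()).hexdigest()[:16]
    return md


def write_sweepset(sweepset: SweepSet, basepath: str | Path,
                   fmt: str | None = None) -> Path:
    """Write a sweep family as ``<base>.csv`` (or ``.h5`` beyond 100 sweeps)
    plus a ``<base>.json`` metadata sidecar.  Round-trips losslessly."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    if fmt is None:
        fmt = "h5" if len(sweepset.sweeps) > HDF5_THRESHOLD else "csv"
    md = _metadata_sidecar(sweepset)
    md["format"] = fmt
    if fmt == "csv":
        df = pd.DataFrame({"time_ms": sweepset.time})
        for sv in sweepset.sweep_values:
            df[f"sweep_{sv:g}"] = sweepset.sweeps[sv]
        data_path = base.with_suffix(".csv")
        df.to_csv(data_path, index=False, float_format="%.17g")
    elif fmt == "h5":
        data_path = base.with_suffix(".h5")
        with h5py.File(data_path, "w") as f:
            f.create_dataset("time_ms", data=sweepset.time)
            g = f.create_group("sweeps")
            for sv in sweepset.sweep_values:
                g.create_dataset(f"{sv:g}", data=sweepset.sweeps[sv])
    else:
        raise ValueError("fmt must be 'csv' or 'h5'")
    base.with_suffix(".json").write_text(
        json.dumps(md, indent=2, sort_keys=True, default=float))
    return data_path


def read_sweepset(basepath: str | Path) -> SweepSet:
    base = Path(basepath)
    md = json.loads(base.with_suffix(".json").read_text())
    fmt = md.get("format", "csv")
    sweep_values = md.pop("sweep_values")
    if fmt == "csv":
        df = pd.read_csv(base.with_suffix(".csv"), float_precision="round_trip")
        time = df["time_ms"].to_numpy()
        sweeps = {float(sv): df[f"sweep_{sv:g}"].to_numpy() for sv in sweep_values}
    else:
        with h5py.File(base.with_suffix(".h5"), "r") as f:
            time = f["time_ms"][()]
            sweeps = {float(sv): f["sweeps"][f"{sv:g}"][()] for sv in sweep_values}
    kind = md.get("kind", "ionic")
    return SweepSet(time=time, sweeps=sweeps, kind=kind, metadata=md)


def write_fit_json(path: str | Path, fit, provenance: dict) -> Path:
    """Serialize any fit object exposing ``to_dict`` with its provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {"fit": fit.to_dict(), "provenance": provenance,
           "schema_version": SCHEMA_VERSION}
    path.write_text(json.dumps(doc, indent=2, sort_keys=True, default=float))
    return path


_REQUIRED_CONFIG = ("variant", "protocol")


def load_config(path: str | Path) -> dict:
    """Load and validate a YAML/JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise RunConfigError(f"config file not found: {path}")
    text = path.read_text()
    cfg = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    if not isinstance(cfg, dict):
        raise RunConfigError(f"{path}: top level must be a mapping")
    for key in _REQUIRED_CONFIG:
        if key not in cfg:
            raise RunConfigError(f"{path}: missing required key '{key}'")
    acq = cfg.get("acquisition", {})
    if acq.get("noise_sigma", 0.0) > 0 and cfg.get("seed") is None:
        raise RunConfigError(f"{path}: acquisition.noise_sigma > 0 requires 'seed'")
    return cfg
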