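"""Serialization and configuration glue for the pipeline.

Formats:

* thermal traces: a two-column CSV (``time_s,temperature_C``) with a JSON
  sidecar (same stem, ``.json``) holding ambient temperature, the
  laser-off time and the calorimetric constants;
* fluence maps: HDF5 with a ``rel`` dataset and a JSON metadata attribute;
* efficiency and ramp-time tables: plain CSV via pandas.

Every writer embeds provenance (package version, seed, config hash).  A
single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence([global_seed, stage_index])`` with fixed stage
indices, so stages are individually reproducible and statistically
decoupled.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .mc import BeamModel, FluenceMap, TissueModel
from .traces import ThermalTrace

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_fluence_h5",
    "read_fluence_h5",
    "load_config",
    "config_hash",
    "provenance",
    "stage_seed",
    "STAGE_INDICES",
]

STAGE_INDICES = {"traces": 0, "efficiency": 1, "mc": 2, "heating": 3}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed in [0, 2^31)."""
    idx = STAGE_INDICES[stage]
    ss = np.random.SeedSequence([int(global_seed), idx])
    return int(ss.generate_state(1)[0] % (2**31))


def config_hash(config: dict) -> str:
    """Short stable hash of a JSON-serializable config dict."""
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:12]


def provenance(config: dict, seed: int) -> dict:
    return {"package": "photherm", "version": __version__, "seed": int(seed),
            "config_hash": config_hash(config)}


def write_trace_csv(trace: ThermalTrace, path: str | Path) -> Path:
    """Write a trace as CSV plus a JSON sidecar with the scalar metadata."""
    path = Path(path)
    pd.DataFrame(
        {"time_s": trace.times_s, "temperature_C": trace.temperatures_C}
    ).to_csv(path, index=False, float_format="%.10g")
    sidecar = {
        "laser_off_time_s": trace.laser_off_time_s,
        "t_ambient_C": trace.t_ambient_C,
        "sample_mass_g": trace.sample_mass_g,
        "heat_capacity_J_per_gK": trace.heat_capacity_J_per_gK,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")
    return path


def read_trace_csv(path: str | Path) -> ThermalTrace:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty trace file: {path} (no header line)") from None
    for col in ("time_s", "temperature_C"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    bad = df[df.isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: unparseable values at CSV line {bad.index[0] + 2}")
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"trace sidecar not found: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    return ThermalTrace(
        times_s=df["time_s"].to_numpy(),
        temperatures_C=df["temperature_C"].to_numpy(),
        laser_off_time_s=meta["laser_off_time_s"],
        t_ambient_C=meta["t_ambient_C"],
        sample_mass_g=meta["sample_mass_g"],
        heat_capacity_J_per_gK=meta["heat_capacity_J_per_gK"],
    )


def write_fluence_h5(fmap: FluenceMap, path: str | Path) -> Path:
    path = Path(path)
    meta = {
        "voxel_size_cm": fmap.voxel_size_cm,
        "dims_cm": list(fmap.dims_cm),
        "n_packets": fmap.n_packets,
        "seed": fmap.seed,
        "launched_weight": fmap.launched_weight,
        "absorbed_weight": fmap.absorbed_weight,
        "escaped_weight": fmap.escaped_weight,
        "surface_unit_raw": fmap.surface_unit_raw,
        "normalization": "mean fluence in first voxel layer inside the beam disc = 1",
        "beam": dataclasses.asdict(fmap.beam),
        "tissue": dataclasses.asdict(fmap.tissue),
        "version": __version__,
    }
    with h5py.File(path, "w") as f:
        f.create_dataset("rel", data=fmap.rel, compression="gzip")
        f.attrs["metadata"] = json.dumps(meta)
    return path


def read_fluence_h5(path: str | Path) -> FluenceMap:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"fluence map not found: {path}")
    with h5py.File(path, "r") as f:
        rel = f["rel"][...]
        meta = json.loads(f.attrs["metadata"])
    return FluenceMap(
        rel=rel,
        voxel_size_cm=meta["voxel_size_cm"],
        dims_cm=tuple(meta["dims_cm"]),
        beam=BeamModel(**meta["beam"]),
        tissue=TissueModel(
            **{**meta["tissue"], "dims_cm": tuple(meta["tissue"]["dims_cm"])}
        ),
        n_packets=meta["n_packets"],
        seed=meta["seed"],
        launched_weight=meta["launched_weight"],
        absorbed_weight=meta["absorbed_weight"],
        escaped_weight=meta["escaped_weight"],
        surface_unit_raw=meta["surface_unit_raw"],
    )


def load_config(path: str | Path | None) -> dict:
    """Load a YAML or JSON config file; None yields an empty dict."""
    if path is None:
        return {}
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    data = yaml.safe_load(text)
    return data or {}
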