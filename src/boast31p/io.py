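"""File formats: per-voxel CSV records, map grids with JSON headers, FIDs.

All tabular data moves as plain CSV through pandas; maps are CSV grids with
a JSON sidecar describing geometry; FIDs are raw complex64 arrays with a
JSON sidecar (dwell time, points, reference frequency, voxel and step).
Parameter objects serialize to JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exchange_model import DantePulseTrain, FermiPulse, PoolSystem, SequenceParams
from .spectral_fitting import FidData

__all__ = [
    "write_amplitudes_csv",
    "read_amplitudes_csv",
    "write_map_csv",
    "read_map_csv",
    "write_fid",
    "read_fid",
    "params_to_json",
    "params_from_json",
]

AMPLITUDE_COLUMNS = [
    "voxel_id",
    "scan_step",
    "metabolite",
    "amplitude",
    "amplitude_sd",
    "flip_deg",
    "tr_s",
    "saturation_mode",
]


def write_amplitudes_csv(df: pd.DataFrame, path) -> None:
    cols = [c for c in AMPLITUDE_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in AMPLITUDE_COLUMNS
    ]
    df[cols].to_csv(path, index=False)


def read_amplitudes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in AMPLITUDE_COLUMNS if c not in df.columns and c != "metabolite"]
    if missing:
        raise ValueError(f"amplitude CSV missing columns: {missing}")
    return df


def write_map_csv(values: np.ndarray, path, header: dict | None = None) -> None:
    """A 1D/2D map as CSV plus a `<path>.json` geometry sidecar."""
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    np.savetxt(path, arr, delimiter=",")
    meta = {"shape": list(np.shape(values))}
    meta.update(header or {})
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def read_map_csv(path) -> tuple[np.ndarray, dict]:
    arr = np.loadtxt(path, delimiter=",")
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if "shape" in meta:
        arr = arr.reshape(meta["shape"])
    return arr, meta


def write_fid(fid: FidData, path, **extra) -> None:
    """Raw complex64 samples to `<path>` plus a JSON sidecar `<path>.json`."""
    fid.samples.astype(np.complex64).tofile(path)
    meta = {
        "dwell_s": fid.dwell,
        "n_points": fid.n_points,
        "acquisition_delay_s": fid.acquisition_delay,
        "dtype": "complex64",
    }
    meta.update(extra)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def read_fid(path) -> FidData:
    meta = json.loads(Path(str(path) + ".json").read_text())
    samples = np.fromfile(path, dtype=np.complex64)
    return FidData(
        samples,
        dwell=meta["dwell_s"],
        acquisition_delay=meta.get("acquisition_delay_s", 0.0),
    )


_PARAM_TYPES = {
    "PoolSystem": PoolSystem,
    "SequenceParams": SequenceParams,
    "DantePulseTrain": DantePulseTrain,
    "FermiPulse": FermiPulse,
}


def params_to_json(obj) -> str:
    """Serialize a parameter dataclass with a type tag."""
    name = type(obj).__name__
    if name not in _PARAM_TYPES:
        raise TypeError(f"unsupported parameter type: {name}")
    return json.dumps({"type": name, **dataclasses.asdict(obj)}, indent=2)


def params_from_json(text: str):
    data = json.loads(text)
    cls = _PARAM_TYPES[data.pop("type")]
    return cls(**data)
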