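"""Configuration files, trace serialization and run manifests.

Configs are YAML with two optional sections, ``model`` (ModelParams keys)
and ``solver`` (SolverConfig keys), plus free-form experiment options under
``experiment``.  Traces are CSV (one row per snapshot, units in the column
headers); field snapshots go to HDF5, one group per snapshot time.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, fields
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .params import ModelParams
from .solver import SolverConfig, SimulationTrace, CellState

TRACE_COLUMNS = ["t_s", "max_u_per_um2", "total_u", "total_f",
                 "mt_pN_per_um", "polarity_angle_deg", "polarized_flag"]


# ---------------------------------------------------------------------------
# config

def load_config(path) -> tuple[ModelParams, SolverConfig, dict]:
    """Parse and validate a YAML config; unknown keys are rejected.

    Returns (ModelParams, SolverConfig, experiment-options dict).  An empty
    file yields the full default parameter set.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(data) - {"model", "solver", "experiment"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    try:
        params = ModelParams.from_dict(data.get("model") or {})
    except (TypeError, ValueError) as e:
        raise ValueError(f"invalid model section: {e}") from e
    solver_keys = {f.name for f in fields(SolverConfig)}
    sv = data.get("solver") or {}
    bad = set(sv) - solver_keys
    if bad:
        raise ValueError(f"unknown solver keys: {sorted(bad)}")
    solver = SolverConfig(**sv)
    return params, solver, data.get("experiment") or {}


def dump_config(params: ModelParams, solver: SolverConfig | None = None,
                experiment: dict | None = None, path=None) -> str:
    doc: dict[str, Any] = {"model": params.to_dict()}
    if solver is not None:
        doc["solver"] = asdict(solver)
    if experiment:
        doc["experiment"] = experiment
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_hash(params: ModelParams, solver: SolverConfig | None = None) -> str:
    return hashlib.sha256(
        dump_config(params, solver).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# traces

def trace_frame(trace: SimulationTrace,
                polarized_threshold: float | None = None) -> pd.DataFrame:
    arr = trace.asarrays()
    flag = (arr["max_u"] >= polarized_threshold).astype(int) \
        if polarized_threshold is not None else np.zeros(len(arr["times"]), int)
    return pd.DataFrame({
        "t_s": arr["times"],
        "max_u_per_um2": arr["max_u"],
        "total_u": arr["total_u"],
        "total_f": arr["total_f"],
        "mt_pN_per_um": arr["mt_series"],
        "polarity_angle_deg": arr["polarity_angle"],
        "polarized_flag": flag,
    })


def write_trace(trace: SimulationTrace, path,
                polarized_threshold: float | None = None) -> None:
    """Scalar series to CSV; holds the documented column schema."""
    trace_frame(trace, polarized_threshold).to_csv(path, index=False)


def read_trace(path) -> SimulationTrace:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace file {path} missing columns: {sorted(missing)}")
    tr = SimulationTrace()
    tr.times = df["t_s"].tolist()
    tr.max_u = df["max_u_per_um2"].tolist()
    tr.total_u = df["total_u"].tolist()
    tr.total_f = df["total_f"].tolist()
    tr.mt_series = df["mt_pN_per_um"].tolist()
    tr.polarity_angle = df["polarity_angle_deg"].tolist()
    return tr


def write_snapshots(trace: SimulationTrace, path, geometry=None) -> None:
    """Full-field snapshots to HDF5, one group per stored time."""
    import h5py
    with h5py.File(path, "w") as h5:
        if geometry is not None:
            gg = h5.create_group("geometry")
            gg.create_dataset("phi", data=geometry.phi)
            gg.create_dataset("Bphi", data=geometry.Bphi)
            gg.create_dataset("grad_phi_mag", data=geometry.grad_phi_mag)
            gg.attrs["L"] = geometry.L
            gg.attrs["N"] = geometry.N
            gg.attrs["eps"] = geometry.eps
        for t, st in trace.snapshots:
            grp = h5.create_group(f"t{t:012.4f}")
            grp.attrs["t"] = t
            grp.attrs["mt"] = st.mt
            for name in ("u", "v", "f"):
                grp.create_dataset(name, data=getattr(st, name),
                                   compression="gzip")


def read_snapshots(path) -> list[tuple[float, CellState]]:
    import h5py
    out = []
    with h5py.File(path, "r") as h5:
        for key in sorted(k for k in h5 if k.startswith("t")):
            grp = h5[key]
            st = CellState(u=grp["u"][...], v=grp["v"][...], f=grp["f"][...],
                           t=float(grp.attrs["t"]), mt=float(grp.attrs["mt"]))
            out.append((st.t, st))
    return out


# ---------------------------------------------------------------------------
# run manifest

def write_manifest(path, *, params: ModelParams,
                   solver: SolverConfig | None = None, seed: int | None = None,
                   outputs: list | None = None, diagnostics: dict | None = None
                   ) -> dict:
    manifest = {
        "code_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config_hash": config_hash(params, solver),
        "model": params.to_dict(),
        "solver": asdict(solver) if solver is not None else None,
        "seed": seed,
        "outputs": outputs or [],
        "diagnostics": diagnostics or {},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
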