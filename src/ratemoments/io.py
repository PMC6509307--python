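"""Structured configuration and trajectory table readers/writers.

Network specifications round-trip through plain nested key-value documents
(YAML); matrices may be given inline or as plain headerless CSV files.
Trajectories are written as delimiter-separated tables with a versioned
header comment and a sidecar JSON metadata document, using 17 significant
digits so float64 values round-trip exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from .network import FICurveParams, InputSignal, NetworkSpec
from .trajectory import StatTrajectory, pair_indices

__all__ = [
    "SchemaError",
    "spec_to_dict",
    "spec_from_dict",
    "save_network",
    "load_network",
    "write_trajectory",
    "read_trajectory",
    "load_matrix_csv",
]

TRAJECTORY_SCHEMA = "ratemoments-trajectory v1"


class SchemaError(ValueError):
    """Raised on file-format version or column-layout mismatches."""


def load_matrix_csv(path) -> np.ndarray:
    """Headerless row-major CSV matrix."""
    mat = np.loadtxt(path, delimiter=",", ndmin=2)
    return mat


def _signal_to_dict(sig: InputSignal) -> Dict:
    d = {"kind": sig.kind, "mode": sig.mode, "baseline": sig.baseline}
    if sig.kind == "pulse":
        d.update(amplitude=sig.amplitude, t_on=sig.t_on, t_off=sig.t_off, ramp=sig.ramp)
    elif sig.kind == "sinusoid":
        d.update(amplitude=sig.amplitude, frequency=sig.frequency, phase=sig.phase)
    return d


def _signal_from_dict(d: Dict) -> InputSignal:
    known = {f.name for f in dataclasses.fields(InputSignal)}
    extra = set(d) - known
    if extra:
        raise SchemaError(f"unknown input-signal fields: {sorted(extra)}")
    return InputSignal(**d)


def spec_to_dict(spec: NetworkSpec) -> Dict:
    return {
        "n_cells": spec.n_cells,
        "tau": spec.tau.tolist(),
        "mu_bg": spec.mu_bg.tolist(),
        "sigma_bg": spec.sigma_bg.tolist(),
        "corr": spec.corr.tolist(),
        "coupling": spec.coupling.tolist(),
        "fi": [{"x_rev": p.x_rev, "x_sp": p.x_sp} for p in spec.fi],
        "inputs": {key: _signal_to_dict(sig) for key, sig in spec.inputs.items()},
    }


def _resolve_matrix(value, base_dir: Optional[Path]) -> np.ndarray:
    if isinstance(value, str):
        path = Path(value)
        if base_dir is not None and not path.is_absolute():
            path = base_dir / path
        return load_matrix_csv(path)
    return np.asarray(value, dtype=float)


def spec_from_dict(d: Dict, base_dir=None) -> NetworkSpec:
    base_dir = Path(base_dir) if base_dir is not None else None
    try:
        return NetworkSpec(
            n_cells=int(d["n_cells"]),
            tau=np.asarray(d["tau"], dtype=float),
            mu_bg=np.asarray(d["mu_bg"], dtype=float),
            sigma_bg=np.asarray(d["sigma_bg"], dtype=float),
            corr=_resolve_matrix(d["corr"], base_dir),
            coupling=_resolve_matrix(d["coupling"], base_dir),
            fi=tuple(FICurveParams(float(p["x_rev"]), float(p["x_sp"])) for p in d["fi"]),
            inputs={key: _signal_from_dict(sd) for key, sd in d.get("inputs", {}).items()},
        )
    except KeyError as exc:
        raise SchemaError(f"network config missing field {exc.args[0]!r}") from None


def save_network(spec: NetworkSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def load_network(path) -> NetworkSpec:
    path = Path(path)
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise SchemaError(f"{path} does not contain a network configuration mapping")
    return spec_from_dict(d, base_dir=path.parent)


def _columns(n_cells: int):
    jj, kk = pair_indices(n_cells)
    cols = {"mean_activity": [f"mean_x_{j + 1}" for j in range(n_cells)]}
    cols["var_activity"] = [f"var_x_{j + 1}" for j in range(n_cells)]
    cols["cov_activity"] = [f"cov_x_{j + 1}_{k + 1}" for j, k in zip(jj, kk)]
    cols["mean_firing"] = [f"mean_nu_{j + 1}" for j in range(n_cells)]
    cols["var_firing"] = [f"var_nu_{j + 1}" for j in range(n_cells)]
    cols["cov_firing"] = [f"cov_nu_{j + 1}_{k + 1}" for j, k in zip(jj, kk)]
    return cols


def write_trajectory(traj: StatTrajectory, path, metadata: Optional[Dict] = None) -> None:
    """Write a trajectory table (with schema header) and a JSON metadata sidecar."""
    if not traj.has_firing:
        raise ValueError("trajectory is missing firing statistics; complete it first")
    path = Path(path)
    cols = _columns(traj.n_cells)
    data = {"time": traj.times}
    for fam, names in cols.items():
        arr = traj.family(fam)
        for i, name in enumerate(names):
            data[name] = arr[:, i]
    frame = pd.DataFrame(data)
    with open(path, "w") as fh:
        fh.write(f"# {TRAJECTORY_SCHEMA}\n")
        fh.write(f"# provenance: {traj.provenance}\n")
        frame.to_csv(fh, index=False, float_format="%.17g")
    meta = {"schema": TRAJECTORY_SCHEMA, "provenance": traj.provenance, "n_cells": traj.n_cells}
    meta.update(metadata or {})
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_trajectory(path) -> StatTrajectory:
    """Read a trajectory table, mapping columns by name (layout-independent)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#") or TRAJECTORY_SCHEMA not in first:
            found = first.lstrip("# ").strip() or "<empty>"
            raise SchemaError(
                f"expected schema header '{TRAJECTORY_SCHEMA}', found '{found}'"
            )
        provenance = "closure"
        second = fh.readline().strip()
        if second.startswith("# provenance:"):
            provenance = second.split(":", 1)[1].strip()
    frame = pd.read_csv(path, comment="#", skip_blank_lines=True, float_precision="round_trip")
    if "time" not in frame.columns:
        raise SchemaError("trajectory table has no 'time' column")
    mean_cols = [c for c in frame.columns if c.startswith("mean_x_")]
    n_cells = len(mean_cols)
    if n_cells == 0:
        raise SchemaError("trajectory table has no mean_x_* columns")
    cols = _columns(n_cells)
    arrays = {}
    for fam, names in cols.items():
        missing = [c for c in names if c not in frame.columns]
        if missing:
            raise SchemaError(f"trajectory table missing columns {missing}")
        arrays[fam] = frame[names].to_numpy(dtype=float)
    if frame[["time"] + sum(cols.values(), [])].isna().any().any():
        raise SchemaError("trajectory table contains missing values (truncated file?)")
    return StatTrajectory(
        times=frame["time"].to_numpy(dtype=float),
        provenance=provenance,
        **arrays,
    )
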