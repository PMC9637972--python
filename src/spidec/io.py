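"""File formats: extended XYZ trajectories, pressure CSV, metadata JSON.

The extended-XYZ dialect written here carries the orthorhombic box in the
``Lattice`` comment field and the global step number in ``step=``; patchy
orientations are stored as three per-atom vector columns (the body axes in
the lab frame). Everything round-trips through :func:`read_extxyz`.
"""

from __future__ import annotations

import json
import shlex
from pathlib import Path

import numpy as np
import pandas as pd

from .configuration import Box
from .trajectory import Trajectory

__all__ = [
    "write_extxyz",
    "read_extxyz",
    "write_pressure_csv",
    "read_pressure_csv",
    "write_metadata",
    "read_metadata",
]


def _frame_header(n: int, box: Box, step: int, with_orient: bool) -> str:
    lat = f"{box.Lx:.10g} 0 0 0 {box.Ly:.10g} 0 0 0 {box.Lz:.10g}"
    props = "species:S:1:pos:R:3:mol:I:1"
    if with_orient:
        props += ":axis_a:R:3:axis_b:R:3:axis_c:R:3"
    return f'Lattice="{lat}" Properties={props} step={step} pbc="T T T"'


def write_extxyz(path, traj: Trajectory, mode: str = "w") -> None:
    """Write all frames of ``traj`` to an extended-XYZ file."""
    path = Path(path)
    with_orient = traj.orientations is not None
    with open(path, mode) as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_particles}\n")
            fh.write(
                _frame_header(traj.n_particles, traj.box, int(traj.steps[f]), with_orient)
                + "\n"
            )
            for i in range(traj.n_particles):
                x, y, z = traj.positions[f, i]
                line = (
                    f"{traj.species[i]} {x:.10g} {y:.10g} {z:.10g} "
                    f"{int(traj.molecule_index[i])}"
                )
                if with_orient:
                    m = traj.orientations[f, i]
                    # columns are body axes; store them column by column
                    for c in range(3):
                        line += f" {m[0, c]:.10g} {m[1, c]:.10g} {m[2, c]:.10g}"
                fh.write(line + "\n")


def _parse_comment(comment: str) -> dict:
    out = {}
    for tok in shlex.split(comment):
        if "=" in tok:
            k, v = tok.split("=", 1)
            out[k] = v
    return out


def read_extxyz(path, time_per_step: float = 1.0) -> Trajectory:
    """Read an extended-XYZ trajectory written by :func:`write_extxyz`."""
    path = Path(path)
    frames, steps, orients = [], [], []
    species: list[str] = []
    mol: list[int] = []
    box = None
    with_orient = False
    with open(path) as fh:
        while True:
            line = fh.readline()
            if not line.strip():
                break
            n = int(line)
            meta = _parse_comment(fh.readline())
            lat = np.array([float(v) for v in meta["Lattice"].split()]).reshape(3, 3)
            box = Box(lat[0, 0], lat[1, 1], lat[2, 2])
            steps.append(int(meta.get("step", len(frames))))
            with_orient = "axis_a" in meta.get("Properties", "")
            pos = np.empty((n, 3))
            ori = np.empty((n, 3, 3)) if with_orient else None
            first_frame = not frames
            for i in range(n):
                parts = fh.readline().split()
                if first_frame:
                    species.append(parts[0])
                    mol.append(int(parts[4]))
                pos[i] = [float(v) for v in parts[1:4]]
                if with_orient:
                    vals = [float(v) for v in parts[5:14]]
                    ori[i] = np.array(vals).reshape(3, 3).T  # stored column-major
            frames.append(pos)
            if with_orient:
                orients.append(ori)
    if not frames:
        raise ValueError(f"no frames found in {path}")
    return Trajectory(
        np.array(frames),
        np.array(steps),
        box,
        species,
        np.array(mol),
        np.array(orients) if orients else None,
        time_per_step,
    )


def write_pressure_csv(path, pressure: pd.DataFrame) -> None:
    """Pressure-tensor time series: columns step,pxx,pyy,pzz."""
    pressure.to_csv(path, index=False)


def read_pressure_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"step", "pxx", "pyy", "pzz"} - set(df.columns)
    if missing:
        raise ValueError(f"pressure CSV missing columns: {sorted(missing)}")
    return df


def write_metadata(path, meta: dict) -> None:
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, default=_json_default)
        fh.write("\n")


def read_metadata(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
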