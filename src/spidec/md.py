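"""Constant-NVT Langevin dynamics in reduced units.

The integrator is velocity Verlet with the BAOAB splitting of the Langevin
thermostat (friction default 0.1 m/tau); with friction zero and noise off it
reduces to plain velocity Verlet. Masses are all 1. Neighbor search uses a
linked-cell pair list with a 0.3-sigma skin, rebuilt on half-skin
displacement; boxes too small for a 3x3x3 cell grid fall back to an all-pairs
list.

Random insertions can contain severe overlaps; instead of rejection sampling,
the first ``limit_steps`` steps clip each half-drift displacement component,
letting the thermostat relax the configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .configuration import Box, Configuration, ModelSpec
from .potentials import lj_energy, lj_force
from .trajectory import Trajectory

__all__ = [
    "MDParams",
    "MDResult",
    "IntegrationError",
    "PressureTensorSample",
    "run_md",
    "compute_pressure_tensor",
    "build_cell_list",
    "default_timestep",
]


class IntegrationError(RuntimeError):
    """Raised when the trajectory develops non-finite coordinates."""


def default_timestep(model: ModelSpec) -> float:
    """0.005 tau for particle systems, 0.001 tau for chain systems."""
    return 0.001 if model.beads_per_molecule > 1 else 0.005


@dataclass
class MDParams:
    """Langevin MD run parameters (reduced units).

    ``limit_steps`` displacement-limits the start of the run to relax random
    insertions; set it to 0 when starting from an equilibrated state.
    """

    n_steps: int
    temperature: float
    dt: float = 0.005
    friction: float = 0.1
    save_interval: int = 1000
    pressure_interval: int = 10
    seed: int = 0
    limit_steps: int = 1000
    max_disp: float = 0.05
    skin: float = 0.3
    noise: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")


@dataclass(frozen=True)
class PressureTensorSample:
    step: int
    pxx: float
    pyy: float
    pzz: float


@dataclass
class MDResult:
    final: Configuration
    trajectory: Trajectory
    pressure: pd.DataFrame
    potential_energy: np.ndarray  # at each saved frame
    kinetic_energy: np.ndarray  # at each saved frame
    metadata: dict


def _build_tables(model: ModelSpec):
    nt = len(model.type_names)
    eps = np.zeros((nt, nt))
    sig = np.ones((nt, nt))
    rc = np.zeros((nt, nt))
    mode = np.zeros((nt, nt), dtype=np.int64)
    ush = np.zeros((nt, nt))
    fsh = np.zeros((nt, nt))
    mode_codes = {
        "plain": _kernels.MODE_PLAIN,
        "cut_shifted": _kernels.MODE_CUT_SHIFTED,
        "force_shifted": _kernels.MODE_FORCE_SHIFTED,
        "wca": _kernels.MODE_WCA,
    }
    for (i, j), p in model.pair_params.items():
        for a, b in ((i, j), (j, i)):
            eps[a, b] = p.epsilon
            sig[a, b] = p.sigma
            rc[a, b] = p.r_cut
            mode[a, b] = mode_codes[p.mode]
            if p.mode in ("cut_shifted", "force_shifted"):
                ush[a, b] = lj_energy(p.r_cut, p)
            if p.mode == "force_shifted":
                fsh[a, b] = lj_force(p.r_cut, p)
    return eps, sig, rc, mode, ush, fsh


def _pair_capacity(n: int, rho: float, cut: float) -> int:
    # generous estimate: half the neighbors within the cutoff sphere at a
    # local density capped well above the densest liquid states seen here
    dense = max(2.0 * rho, 1.3)
    per = 0.5 * dense * 4.19 * cut**3
    cap = int(n * max(per * 2.0, 100.0))
    return min(cap, n * (n - 1) // 2 + 1)


def _maxwell_velocities(n: int, temperature: float, rng: np.random.Generator):
    v = rng.standard_normal((n, 3)) * math.sqrt(max(temperature, 0.0))
    v -= v.mean(axis=0)
    return v


def run_md(
    config: Configuration,
    model: ModelSpec,
    params: MDParams,
    sinks=None,
) -> MDResult:
    """Run Langevin MD and return the trajectory, pressure series and state.

    ``sinks`` may be a dict with keys ``trajectory``, ``pressure``,
    ``metadata`` mapping to file paths; outputs are then also written to disk
    (extended-XYZ, CSV, JSON).
    """
    if model.kind == "patchy":
        raise ValueError("patchy particles are simulated with the MC engine")
    pos = np.ascontiguousarray(config.positions.copy())
    n = pos.shape[0]
    box = config.box.lengths
    n_mol = config.n_molecules
    types = model.bead_type_indices(n_mol)
    if len(types) != n:
        raise ValueError("configuration size does not match the model topology")
    eps, sig, rc, mode, ush, fsh = _build_tables(model)
    bonds = model.bond_list(n_mol)
    bk = model.bond_params.k_spring if model.bond_params else 0.0
    br0 = model.bond_params.r0 if model.bond_params else 1.0
    mol = np.ascontiguousarray(config.molecule_index)
    excl = model.beads_per_molecule > 1

    rng = np.random.default_rng(params.seed)
    if config.velocities is not None:
        vel = np.ascontiguousarray(config.velocities.copy())
    else:
        vel = _maxwell_velocities(n, params.temperature, rng)

    max_cut = model.max_cutoff
    if max_cut + params.skin > min(box) / 2:
        raise ValueError(
            f"cutoff+skin {max_cut + params.skin:.3g} exceeds half the "
            f"smallest box side {min(box) / 2:.3g}"
        )
    cap = _pair_capacity(n, n / config.box.volume, max_cut + params.skin)
    pairs = np.empty((cap, 2), dtype=np.int32)
    pos_ref = np.empty_like(pos)
    forces = np.empty_like(pos)

    n_psamples = (
        params.n_steps // params.pressure_interval + 2
        if params.pressure_interval > 0
        else 1
    )
    psteps = np.zeros(n_psamples, dtype=np.int64)
    pxx = np.zeros(n_psamples)
    pyy = np.zeros(n_psamples)
    pzz = np.zeros(n_psamples)

    save = max(1, params.save_interval)
    n_chunks = params.n_steps // save
    rem = params.n_steps - n_chunks * save
    frames = [pos.copy()]
    steps = [0]
    pes = [
        _kernels.total_energy(
            pos, box, types, eps, sig, rc, mode, ush, fsh, bonds, bk, br0, mol, excl
        )
        if n <= 2000
        else np.nan
    ]
    kes = [0.5 * float(np.sum(vel**2))]
    pcount = 0
    step0 = 0
    use_noise = params.noise and params.friction > 0
    dummy = np.zeros((1, 1, 1))
    # cap the per-call noise block at ~10^6 gaussians to bound memory
    sub_max = max(1, int(1_000_000 / (3 * n)))
    chunk_sizes = [save] * n_chunks + ([rem] if rem else [])
    for csize in chunk_sizes:
        done = 0
        while done < csize:
            sub = min(csize - done, sub_max) if use_noise else csize - done
            noise = rng.standard_normal((sub, n, 3)) if use_noise else dummy
            status, pe, pcount = _kernels.md_chunk(
                pos, vel, box, types, eps, sig, rc, mode, ush, fsh,
                bonds, bk, br0, mol, excl,
                params.dt, params.friction, params.temperature, noise,
                sub, step0, params.limit_steps, params.max_disp,
                pairs, pos_ref, forces, max_cut, params.skin,
                params.pressure_interval, psteps, pxx, pyy, pzz, pcount,
            )
            if status == -1:
                raise RuntimeError("neighbor pair list overflow (internal error)")
            if status > 0:
                raise IntegrationError(
                    f"non-finite energy at step {status}; the system blew up"
                )
            step0 += sub
            done += sub
            vmax2 = float(np.max(np.sum(vel * vel, axis=1)))
            if not np.isfinite(vmax2) or vmax2 > 1e12:
                raise IntegrationError(
                    f"runaway velocities by step {step0} "
                    f"(max speed {math.sqrt(vmax2):.3g}); the system blew up"
                )
        frames.append(pos.copy())
        steps.append(step0)
        pes.append(pe)
        kes.append(0.5 * float(np.sum(vel**2)))

    traj = Trajectory(
        np.array(frames),
        np.array(steps),
        config.box,
        model.bead_type_names(n_mol),
        mol,
        time_per_step=params.dt,
    )
    pressure = pd.DataFrame(
        {
            "step": psteps[:pcount],
            "pxx": pxx[:pcount],
            "pyy": pyy[:pcount],
            "pzz": pzz[:pcount],
        }
    )
    final = Configuration(pos, config.box, mol, velocities=vel)
    metadata = {
        "engine": "md",
        "model": model.kind,
        "n_particles": n,
        "n_molecules": int(n_mol),
        "realized_density": n / config.box.volume,
        "box": list(box),
        "dt": params.dt,
        "friction": params.friction,
        "temperature": params.temperature,
        "n_steps": params.n_steps,
        "save_interval": params.save_interval,
        "pressure_interval": params.pressure_interval,
        "seed": params.seed,
    }
    result = MDResult(final, traj, pressure, np.array(pes), np.array(kes), metadata)
    if sinks:
        from . import io

        if "trajectory" in sinks:
            io.write_extxyz(sinks["trajectory"], traj)
        if "pressure" in sinks:
            io.write_pressure_csv(sinks["pressure"], pressure)
        if "metadata" in sinks:
            io.write_metadata(sinks["metadata"], metadata)
    return result


def compute_pressure_tensor(config: Configuration, model: ModelSpec) -> PressureTensorSample:
    """Instantaneous diagonal pressure tensor, kinetic + virial parts.

    p_aa = (sum_i m v_ia^2 + sum_pairs r_a f_a) / V with minimum-image pair
    displacements; bond contributions are included for chains. Velocities
    must be present on the configuration.
    """
    if config.velocities is None:
        raise ValueError("velocities are required for the kinetic part")
    pos = np.ascontiguousarray(config.positions)
    box = config.box.lengths
    n_mol = config.n_molecules
    types = model.bead_type_indices(n_mol)
    eps, sig, rc, mode, ush, fsh = _build_tables(model)
    bonds = model.bond_list(n_mol)
    bk = model.bond_params.k_spring if model.bond_params else 0.0
    br0 = model.bond_params.r0 if model.bond_params else 1.0
    mol = np.ascontiguousarray(config.molecule_index)
    excl = model.beads_per_molecule > 1
    cut = model.max_cutoff
    cap = _pair_capacity(len(pos), config.density, cut)
    pairs = np.empty((cap, 2), dtype=np.int32)
    _, vxx, vyy, vzz = _kernels.virial_tensor(
        pos, box, types, eps, sig, rc, mode, ush, fsh,
        bonds, bk, br0, mol, excl, pairs, cut,
    )
    v = config.velocities
    vol = config.box.volume
    return PressureTensorSample(
        step=0,
        pxx=(np.sum(v[:, 0] ** 2) + vxx) / vol,
        pyy=(np.sum(v[:, 1] ** 2) + vyy) / vol,
        pzz=(np.sum(v[:, 2] ** 2) + vzz) / vol,
    )


def build_cell_list(config: Configuration, r_cut: float) -> np.ndarray:
    """All pairs within ``r_cut`` (each exactly once), as an (n_pairs, 2) array."""
    box = config.box.lengths
    if r_cut > min(box) / 2:
        raise ValueError("r_cut must not exceed half the smallest box side")
    n = config.n_particles
    cap = _pair_capacity(n, config.density, r_cut)
    pos = np.ascontiguousarray(config.positions)
    while True:
        pairs = np.empty((cap, 2), dtype=np.int32)
        got = _kernels.build_pairs(pos, box, r_cut, pairs)
        if got >= 0:
            return pairs[:got].copy()
        cap *= 2
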