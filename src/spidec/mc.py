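"""Metropolis Monte Carlo for patchy particles and LJ particles.

One MC step is a sweep: one attempted move per particle. For patchy
particles each attempt is a displacement or a rotation with equal
probability (displacements uniform in a cube of side 0.09 sigma, rotations
bounded by 0.05 rad); hard-core overlaps are always rejected. For LJ
particles only displacements are attempted.

The total potential energy is tracked incrementally from accepted-move
deltas; :func:`recompute_energy` provides the full reference sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .configuration import Box, Configuration, ModelSpec
from .md import PressureTensorSample, _build_tables, _pair_capacity
from .trajectory import Trajectory

__all__ = [
    "MCParams",
    "MCResult",
    "UnsupportedModelError",
    "run_mc",
    "rotate_move",
    "mc_pressure_tensor",
    "recompute_energy",
]


class UnsupportedModelError(ValueError):
    """Raised for model/operation combinations that are not defined."""


@dataclass
class MCParams:
    """Metropolis MC parameters (one step = one attempted move per particle)."""

    n_steps: int
    temperature: float
    displacement_side: float = 0.09  # cube side length, sigma units
    rotation_halfwidth: float = 0.05  # radians
    save_interval: int = 2000
    pressure_interval: int = 0  # sweeps; LJ particles only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.displacement_side <= 0 or self.rotation_halfwidth <= 0:
            raise ValueError("move halfwidths must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class MCResult:
    final: Configuration
    trajectory: Trajectory
    energy: float
    acceptance: dict
    pressure: pd.DataFrame
    metadata: dict


def _cell_grid(box: np.ndarray, cut: float, n: int = 0):
    # cells no smaller than the cutoff; cap the grid so it stays O(n) memory
    max_dim = max(3, int(np.cbrt(8.0 * max(n, 1))) + 1)
    ncx = min(int(box[0] / cut), max_dim)
    ncy = min(int(box[1] / cut), max_dim)
    ncz = min(int(box[2] / cut), max_dim)
    use = ncx >= 3 and ncy >= 3 and ncz >= 3
    if not use:
        ncx = ncy = ncz = 1
    return ncx, ncy, ncz, use


def rotate_move(orient: np.ndarray, halfwidth: float = 0.05, seed: int | None = None):
    """One bounded rotation proposal applied to a 3x3 orientation matrix.

    The body z axis moves uniformly within a spherical cap of half-angle
    ``halfwidth``; the frame then spins about the new z axis by an angle
    uniform in (-halfwidth, halfwidth). The proposal is symmetric, so it
    preserves detailed balance without a proposal-ratio correction.
    """
    if seed is not None:
        _kernels.seed_rng(int(seed) % 2**31)
    return _kernels.propose_rotation(np.ascontiguousarray(orient, dtype=float), halfwidth)


def run_mc(
    config: Configuration,
    model: ModelSpec,
    params: MCParams,
    sinks=None,
) -> MCResult:
    """Run Metropolis MC and return trajectory plus acceptance statistics."""
    if model.kind == "patchy":
        return _run_mc_patchy(config, model, params, sinks)
    if model.kind == "lj_particle":
        return _run_mc_lj(config, model, params, sinks)
    raise UnsupportedModelError(
        f"MC engine supports patchy and lj_particle systems, not {model.kind}"
    )


def _chunks(total: int, size: int) -> list[int]:
    n = total // size
    out = [size] * n
    if total - n * size:
        out.append(total - n * size)
    return out


def _run_mc_patchy(config, model, params, sinks) -> MCResult:
    pp = model.patch_params
    pos = np.ascontiguousarray(config.positions.copy())
    if config.orientations is None:
        raise ValueError("patchy configurations require orientations")
    axes = np.ascontiguousarray(config.orientations.copy())
    n = pos.shape[0]
    box = config.box.lengths
    patch_body = np.ascontiguousarray(pp.patch_directions)
    patches = np.einsum("nij,pj->npi", axes, patch_body)
    cut = pp.sigma + pp.lambda_range
    ncx, ncy, ncz, use_cells = _cell_grid(box, cut, n)
    head = np.full(ncx * ncy * ncz, -1, dtype=np.int32)
    nxt = np.full(n, -1, dtype=np.int32)

    energy = _kernels.patchy_total_energy(
        pos, patches, box, pp.sigma, pp.lambda_range, pp.epsilon, pp.cos_theta_s
    )
    if energy >= 0.5 * _kernels.OVERLAP:
        raise ValueError("initial patchy configuration has hard-core overlaps")

    _kernels.seed_rng(int(params.seed) % 2**31)
    disp_half = params.displacement_side / 2.0

    frames = [pos.copy()]
    orient_frames = [axes.copy()]
    steps = [0]
    nd = ad = nr = ar = 0
    step0 = 0
    for csize in _chunks(params.n_steps, max(1, params.save_interval)):
        energy, d, a, r, b = _kernels.mc_sweeps_patchy(
            pos, axes, patches, patch_body, box,
            pp.sigma, pp.lambda_range, pp.epsilon, pp.cos_theta_s,
            params.temperature, disp_half, params.rotation_halfwidth, csize,
            head, nxt, ncx, ncy, ncz, use_cells, energy,
        )
        nd += d
        ad += a
        nr += r
        ar += b
        step0 += csize
        frames.append(pos.copy())
        orient_frames.append(axes.copy())
        steps.append(step0)

    traj = Trajectory(
        np.array(frames), np.array(steps), config.box,
        model.bead_type_names(n), config.molecule_index,
        orientations=np.array(orient_frames), time_per_step=1.0,
    )
    acceptance = {
        "displacement": {"attempted": int(nd), "accepted": int(ad)},
        "rotation": {"attempted": int(nr), "accepted": int(ar)},
    }
    final = Configuration(pos, config.box, config.molecule_index, orientations=axes)
    metadata = _mc_metadata(model, config, params, acceptance)
    result = MCResult(final, traj, float(energy), acceptance, pd.DataFrame(), metadata)
    _write_sinks(result, sinks)
    return result


def _run_mc_lj(config, model, params, sinks) -> MCResult:
    pos = np.ascontiguousarray(config.positions.copy())
    n = pos.shape[0]
    box = config.box.lengths
    types = model.bead_type_indices(config.n_molecules)
    eps, sig, rc, mode, ush, fsh = _build_tables(model)
    cut = model.max_cutoff
    ncx, ncy, ncz, use_cells = _cell_grid(box, cut, n)
    head = np.full(ncx * ncy * ncz, -1, dtype=np.int32)
    nxt = np.full(n, -1, dtype=np.int32)
    nobonds = np.zeros((0, 2), dtype=np.int64)
    mol = np.ascontiguousarray(config.molecule_index)

    energy = _kernels.total_energy(
        pos, box, types, eps, sig, rc, mode, ush, fsh, nobonds, 0.0, 1.0, mol, False
    )
    _kernels.seed_rng(int(params.seed) % 2**31)
    disp_half = params.displacement_side / 2.0

    frames = [pos.copy()]
    steps = [0]
    na = aa = 0
    psamples = []
    step0 = 0
    chunk = max(1, params.save_interval)
    if params.pressure_interval > 0:
        chunk = min(chunk, params.pressure_interval)
    for csize in _chunks(params.n_steps, chunk):
        energy, att, acc = _kernels.mc_sweeps_lj(
            pos, box, types, eps, sig, rc, mode, ush, fsh,
            params.temperature, disp_half, csize,
            head, nxt, ncx, ncy, ncz, use_cells, energy,
        )
        na += att
        aa += acc
        step0 += csize
        if params.pressure_interval > 0 and step0 % params.pressure_interval == 0:
            snap = Configuration(pos.copy(), config.box, mol)
            ps = mc_pressure_tensor(snap, model, params.temperature)
            psamples.append((step0, ps.pxx, ps.pyy, ps.pzz))
        if step0 % max(1, params.save_interval) == 0 or step0 == params.n_steps:
            frames.append(pos.copy())
            steps.append(step0)

    traj = Trajectory(
        np.array(frames), np.array(steps), config.box,
        model.bead_type_names(config.n_molecules), mol, time_per_step=1.0,
    )
    acceptance = {"displacement": {"attempted": int(na), "accepted": int(aa)}}
    pressure = pd.DataFrame(psamples, columns=["step", "pxx", "pyy", "pzz"])
    final = Configuration(pos, config.box, mol)
    metadata = _mc_metadata(model, config, params, acceptance)
    result = MCResult(final, traj, float(energy), acceptance, pressure, metadata)
    _write_sinks(result, sinks)
    return result


def _mc_metadata(model, config, params, acceptance) -> dict:
    return {
        "engine": "mc",
        "model": model.kind,
        "n_particles": config.n_particles,
        "realized_density": config.density,
        "box": list(config.box.lengths),
        "temperature": params.temperature,
        "n_steps": params.n_steps,
        "displacement_side": params.displacement_side,
        "rotation_halfwidth": params.rotation_halfwidth,
        "save_interval": params.save_interval,
        "seed": params.seed,
        "acceptance": acceptance,
    }


def _write_sinks(result: MCResult, sinks) -> None:
    if not sinks:
        return
    from . import io

    if "trajectory" in sinks:
        io.write_extxyz(sinks["trajectory"], result.trajectory)
    if "pressure" in sinks and len(result.pressure):
        io.write_pressure_csv(sinks["pressure"], result.pressure)
    if "metadata" in sinks:
        io.write_metadata(sinks["metadata"], result.metadata)


def recompute_energy(config: Configuration, model: ModelSpec) -> float:
    """Full potential-energy sum, the reference for incremental bookkeeping."""
    pos = np.ascontiguousarray(config.positions)
    box = config.box.lengths
    if model.kind == "patchy":
        pp = model.patch_params
        patches = np.einsum("nij,pj->npi", config.orientations, pp.patch_directions)
        return float(
            _kernels.patchy_total_energy(
                pos, patches, box, pp.sigma, pp.lambda_range, pp.epsilon, pp.cos_theta_s
            )
        )
    types = model.bead_type_indices(config.n_molecules)
    eps, sig, rc, mode, ush, fsh = _build_tables(model)
    bonds = model.bond_list(config.n_molecules)
    bk = model.bond_params.k_spring if model.bond_params else 0.0
    br0 = model.bond_params.r0 if model.bond_params else 1.0
    return float(
        _kernels.total_energy(
            pos, box, types, eps, sig, rc, mode, ush, fsh,
            bonds, bk, br0, np.ascontiguousarray(config.molecule_index),
            model.beads_per_molecule > 1,
        )
    )


def mc_pressure_tensor(
    config: Configuration, model: ModelSpec, temperature: float
) -> PressureTensorSample:
    """Pressure tensor for MC snapshots of continuous-potential models.

    The kinetic part is replaced by the ideal term rho*T on each diagonal;
    the virial part is the usual pair sum. Patchy particles are rejected:
    the discontinuous square-well/hard-core potential has no proper virial.
    """
    if model.kind == "patchy":
        raise UnsupportedModelError(
            "pressure tensor is not defined for the discontinuous patchy potential"
        )
    pos = np.ascontiguousarray(config.positions)
    box = config.box.lengths
    types = model.bead_type_indices(config.n_molecules)
    eps, sig, rc, mode, ush, fsh = _build_tables(model)
    bonds = model.bond_list(config.n_molecules)
    bk = model.bond_params.k_spring if model.bond_params else 0.0
    br0 = model.bond_params.r0 if model.bond_params else 1.0
    cut = model.max_cutoff
    cap = _pair_capacity(len(pos), config.density, cut)
    pairs = np.empty((cap, 2), dtype=np.int32)
    _, vxx, vyy, vzz = _kernels.virial_tensor(
        pos, box, types, eps, sig, rc, mode, ush, fsh,
        bonds, bk, br0, np.ascontiguousarray(config.molecule_index),
        model.beads_per_molecule > 1, pairs, cut,
    )
    vol = config.box.volume
    rho_t = config.density * temperature
    return PressureTensorSample(
        step=0,
        pxx=rho_t + vxx / vol,
        pyy=rho_t + vyy / vol,
        pzz=rho_t + vzz / vol,
    )
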