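"""Synthetic data generators and independent brute-force oracles.

Everything here is seed-deterministic and cheap, so the analysis operations
can be exercised without long simulations: forward-generated tanh profiles,
ideal two-phase particle configurations, freely jointed chains, voxel masks
of known morphology, patch-coverage quadrature and a two-particle
Boltzmann-quadrature oracle for the patchy Monte Carlo engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .configuration import Box, Configuration
from .potentials import PatchParams
from .slab import DensityProfile
from .trajectory import Trajectory

__all__ = [
    "SyntheticProfileSpec",
    "make_tanh_profile",
    "make_two_phase_configuration",
    "make_two_phase_trajectory",
    "preformed_slab_configuration",
    "sample_fjc",
    "fjc_rg2_exact",
    "fibonacci_sphere",
    "patch_coverage",
    "make_voxel_morphology",
    "BoltzmannPairOracle",
    "patchy_pair_oracle",
]


@dataclass(frozen=True)
class SyntheticProfileSpec:
    """Parameters for a forward-generated symmetric double-interface profile."""

    rho_d: float = 0.7
    rho_b: float = 0.05
    z0: float = 10.0
    w: float = 2.0
    noise_sd: float = 0.0
    n_slices: int = 400
    box_length: float = 40.0


def make_tanh_profile(spec: SyntheticProfileSpec, seed: int = 0) -> DensityProfile:
    """Generate the tanh interface model run forward: a slab centered at the
    box middle with interfaces at +-z0, plus additive Gaussian noise."""
    rng = np.random.default_rng(seed)
    L = spec.box_length
    thickness = L / spec.n_slices
    centers = (np.arange(spec.n_slices) + 0.5) * thickness
    zeta = np.abs(centers - L / 2.0)
    rho = 0.5 * (spec.rho_d + spec.rho_b) - 0.5 * (spec.rho_d - spec.rho_b) * np.tanh(
        (zeta - spec.z0) / spec.w
    )
    if spec.noise_sd > 0:
        rho = rho + rng.normal(0.0, spec.noise_sd, size=rho.shape)
    return DensityProfile("z", centers, rho, thickness, L, 1)


def _two_phase_positions(box: Box, n_d: int, n_b: int, hw: float, rng) -> np.ndarray:
    L = box.lengths
    dense = rng.random((n_d, 3)) * [L[0], L[1], 2.0 * hw]
    dense[:, 2] += L[2] / 2.0 - hw
    dilute = rng.random((n_b, 3)) * L
    # compress dilute z into the complement of the slab interval
    gap = 2.0 * hw
    z = dilute[:, 2] * (L[2] - gap) / L[2]
    z = np.where(z < L[2] / 2.0 - hw, z, z + gap)
    dilute[:, 2] = z
    return np.vstack([dense, dilute])


def make_two_phase_configuration(
    box: Box,
    rho_d: float,
    rho_b: float,
    slab_halfwidth: float,
    seed: int = 0,
) -> Configuration:
    """Ideal-gas two-phase fixture: uniform density ``rho_d`` inside the slab
    |z - Lz/2| < slab_halfwidth and ``rho_b`` outside, no interactions."""
    rng = np.random.default_rng(seed)
    L = box.lengths
    v_slab = L[0] * L[1] * 2.0 * slab_halfwidth
    v_out = box.volume - v_slab
    n_d = rng.poisson(rho_d * v_slab)
    n_b = rng.poisson(rho_b * v_out)
    pos = _two_phase_positions(box, n_d, n_b, slab_halfwidth, rng)
    return Configuration(pos, box, np.arange(len(pos)))


def make_two_phase_trajectory(
    box: Box,
    rho_d: float = 0.7,
    rho_b: float = 0.05,
    slab_halfwidth: float | None = None,
    n_frames: int = 10,
    seed: int = 0,
) -> Trajectory:
    """Stack of independent two-phase frames (fixed particle counts) as a
    mock trajectory."""
    if slab_halfwidth is None:
        slab_halfwidth = box.Lz / 6.0
    rng = np.random.default_rng(seed)
    L = box.lengths
    v_slab = L[0] * L[1] * 2.0 * slab_halfwidth
    n_d = int(round(rho_d * v_slab))
    n_b = int(round(rho_b * (box.volume - v_slab)))
    frames = [
        _two_phase_positions(box, n_d, n_b, slab_halfwidth, rng)
        for _ in range(n_frames)
    ]
    n = n_d + n_b
    return Trajectory(
        np.array(frames),
        np.arange(n_frames) * 1000,
        box,
        ["LJ"] * n,
        np.arange(n),
    )


def preformed_slab_configuration(
    model,
    box: Box,
    rho0: float,
    seed: int = 0,
    dense_density: float = 0.7,
) -> Configuration:
    """All molecules packed into a central slab at ``dense_density``.

    The classical-slab style start: the overall density is ``rho0`` but the
    material begins as a dense slab spanning x and y at the box middle, so
    equilibrium two-phase sampling starts immediately instead of waiting for
    spinodal decomposition. Chains are unwrapped before embedding so no bond
    straddles the slab edge.
    """
    from .configuration import lattice_init, random_insert

    L = box.lengths
    n_beads = rho0 * box.volume
    h = min(n_beads / dense_density / (L[0] * L[1]), 0.9 * L[2])
    sub = Box(L[0], L[1], h)
    if model.kind == "patchy":
        cfg = lattice_init(model, sub, dense_density, seed)
    else:
        cfg = random_insert(model, sub, dense_density, seed)
    pos = cfg.positions.copy()
    if model.beads_per_molecule > 1:
        # unwrap each chain inside the sub-box so embedding keeps bonds short
        nb = model.beads_per_molecule
        subL = sub.lengths
        for m in range(cfg.n_molecules):
            sl = slice(m * nb, (m + 1) * nb)
            bonds = np.diff(pos[sl], axis=0)
            bonds -= subL * np.round(bonds / subL)
            pos[sl][1:] = pos[sl][0] + np.cumsum(bonds, axis=0)
    pos[:, 2] += (L[2] - h) / 2.0
    pos -= L * np.floor(pos / L)
    return Configuration(
        pos, box, cfg.molecule_index, orientations=cfg.orientations
    )


# ---------------------------------------------------------------------------
# freely jointed chains


def sample_fjc(
    n_beads: int, bond: float = 1.0, n_chains: int = 1, seed: int = 0
) -> np.ndarray:
    """Freely jointed chains: fixed bond length, uniformly random directions,
    no excluded volume. Returns an (n_chains, n_beads, 3) array."""
    if n_beads < 2:
        raise ValueError("a chain needs at least 2 beads")
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n_chains, n_beads - 1, 3))
    v *= bond / np.linalg.norm(v, axis=2, keepdims=True)
    coords = np.zeros((n_chains, n_beads, 3))
    coords[:, 1:] = np.cumsum(v, axis=1)
    return coords


def fjc_rg2_exact(n_beads: int, bond: float = 1.0) -> float:
    """Closed-form mean-square radius of gyration b^2 (n^2 - 1) / (6 n)."""
    return bond * bond * (n_beads * n_beads - 1) / (6.0 * n_beads)


# ---------------------------------------------------------------------------
# patch coverage


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform directions on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def patch_coverage(p: PatchParams, n_points: int = 200_000) -> float:
    """Fraction of the particle surface covered by the union of the patches.

    Deterministic spherical quadrature (Fibonacci lattice): a direction is
    covered if it lies within angular distance arccos(cos_theta_s) of ANY
    patch center — the union is handled by a point-in-any-cap test, never by
    adding cap areas (the caps overlap at wide half-angles).
    """
    dirs = fibonacci_sphere(n_points)
    dots = dirs @ np.asarray(p.patch_directions).T
    covered = np.any(dots > p.cos_theta_s, axis=1)
    return float(covered.mean())


# ---------------------------------------------------------------------------
# voxel morphologies


def make_voxel_morphology(label: str, shape=(16, 16, 16), radius: float | None = None):
    """Ground-truth periodic voxel mask for the morphology classifier.

    Shapes: centered ball (sphere), z-spanning rod (cylinder), z-slab (slab),
    dense block with a z-spanning dilute core (hollow_cylinder), dense shell
    enclosing a dilute ball (hollow_sphere), plus the two homogeneous masks.
    """
    shape = tuple(int(s) for s in shape)
    nx, ny, nz = shape
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    X, Y, Z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    r_xy = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2)
    r_xyz = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2)
    if radius is None:
        radius = min(shape) / 4.0
    if radius > min(shape) / 2.0:
        raise ValueError("shape radius exceeds half the grid: not realizable")
    if label == "homogeneous_dilute":
        return np.zeros(shape, dtype=bool)
    if label == "homogeneous_dense":
        return np.ones(shape, dtype=bool)
    if label == "sphere":
        return r_xyz <= radius
    if label == "cylinder":
        return r_xy <= radius
    if label == "slab":
        return np.abs(Z - cz) <= radius
    if label == "hollow_cylinder":
        return ~(r_xy <= radius)
    if label == "hollow_sphere":
        return ~(r_xyz <= radius)
    if label == "shell":
        return (r_xyz <= 2.0 * radius) & ~(r_xyz <= radius)
    raise ValueError(f"unknown morphology label {label!r}")


# ---------------------------------------------------------------------------
# two-particle Boltzmann oracle


@dataclass
class BoltzmannPairOracle:
    """Quadrature expectations for two patchy particles in a periodic box."""

    bonded_fraction: float
    well_fraction: float  # probability the pair separation is in the well
    mean_energy: float
    count_distribution: np.ndarray  # P(k patches cover a uniform direction)


def _cap_count_distribution(p: PatchParams, n_dirs: int) -> np.ndarray:
    dirs = fibonacci_sphere(n_dirs)
    dots = dirs @ np.asarray(p.patch_directions).T
    counts = np.sum(dots > p.cos_theta_s, axis=1)
    kmax = p.patch_directions.shape[0]
    return np.bincount(counts, minlength=kmax + 1) / n_dirs


def patchy_pair_oracle(
    p: PatchParams,
    temperature: float,
    box: Box,
    n_dirs: int = 100_000,
    tol: float = 1e-3,
) -> BoltzmannPairOracle:
    """Exact (quadrature) equilibrium statistics of two patchy particles.

    Factorization: with one particle fixed, the relative position is uniform
    over the box and each particle's patch frame is an independent uniform
    rotation, so the number of patches covering the inter-particle direction
    on each particle is i.i.d. with distribution p_k (computed by spherical
    quadrature). For box sides >= 2(sigma + lambda) the square-well region is
    a full spherical shell, giving a closed-form partition sum:

        Z = V_out + V_shell * sum_jk p_j p_k exp(eps * j * k / T)

    The quadrature is refined once (2x directions); a drift above ``tol`` in
    the bonded fraction raises a resolution error.
    """
    L = box.lengths
    rng_out = p.sigma + p.lambda_range
    if np.min(L) < 2.0 * rng_out:
        raise ValueError("box too small: the interaction shell must be spherical")

    def compute(nd):
        pk = _cap_count_distribution(p, nd)
        v_core = 4.0 / 3.0 * math.pi * p.sigma**3
        v_shell = 4.0 / 3.0 * math.pi * (rng_out**3) - v_core
        v_out = box.volume - v_core - v_shell
        jk = np.outer(np.arange(len(pk)), np.arange(len(pk)))
        weights = np.outer(pk, pk) * np.exp(p.epsilon * jk / temperature)
        z_shell = v_shell * weights.sum()
        z = v_out + z_shell
        bonded = v_shell * weights[jk >= 1].sum() / z
        mean_e = -p.epsilon * v_shell * (weights * jk).sum() / z
        return pk, bonded, v_shell * weights.sum() / z, mean_e

    pk, bonded, well, mean_e = compute(n_dirs)
    _, bonded2, _, _ = compute(2 * n_dirs)
    if abs(bonded2 - bonded) > tol:
        raise RuntimeError(
            f"quadrature not converged: bonded fraction moved by "
            f"{abs(bonded2 - bonded):.2e} on refinement"
        )
    return BoltzmannPairOracle(bonded2, well, mean_e, pk)
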