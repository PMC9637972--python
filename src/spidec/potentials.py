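"""Pairwise and bonded interaction potentials for the coarse-grained model systems.

All quantities are in reduced units: lengths in units of the bead diameter
sigma, energies in units of the well depth epsilon. Four nonbonded forms are
supported:

``plain``
    The bare 12-6 Lennard-Jones potential.
``cut_shifted``
    LJ truncated at ``r_cut`` and shifted so the energy is zero at the cutoff
    (the force is the bare LJ force inside the cutoff).
``force_shifted``
    LJ with both the energy and the force brought continuously to zero at
    ``r_cut`` (linear term added to the energy).
``wca``
    The purely repulsive Weeks-Chandler-Andersen potential: LJ truncated and
    shifted at its minimum, 2^(1/6) sigma.

Patchy (Kern-Frenkel) particles are hard spheres of diameter sigma decorated
with four attractive circular patches at tetrahedron vertices; two particles
gain -epsilon per bonded patch pair when their separation lies in the square
well [sigma, sigma + lambda) and the inter-particle direction falls inside a
patch on each particle.

All functions here are scalar, pure and validated; the simulation engines use
equivalent vectorized kernels (see ``spidec._kernels``), which are tested
against these reference implementations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PairParams",
    "BondParams",
    "PatchParams",
    "TETRAHEDRAL_DIRECTIONS",
    "WCA_CUTOFF",
    "lj_energy",
    "lj_force",
    "lj_cut_shifted_energy",
    "lj_force_shifted_energy_force",
    "wca_energy",
    "pair_energy_force",
    "bond_energy",
    "bond_force",
    "patchy_pair_energy",
]

#: Cutoff of the WCA potential in units of sigma (the LJ minimum).
WCA_CUTOFF = 2.0 ** (1.0 / 6.0)

#: Unit vectors toward the vertices of a regular tetrahedron, the canonical
#: patch-center geometry. Pairwise angles are all arccos(-1/3).
TETRAHEDRAL_DIRECTIONS = np.array(
    [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
) / math.sqrt(3.0)
TETRAHEDRAL_DIRECTIONS.setflags(write=False)

_MODES = ("plain", "cut_shifted", "force_shifted", "wca")


@dataclass(frozen=True)
class PairParams:
    """Parameters of one nonbonded type pair.

    Parameters
    ----------
    epsilon : float
        Well depth (energy units).
    sigma : float
        Bead diameter (length units).
    r_cut : float
        Cutoff radius. Ignored for ``wca`` (implied cutoff 2^(1/6) sigma).
    mode : {"plain", "cut_shifted", "force_shifted", "wca"}
    """

    epsilon: float = 1.0
    sigma: float = 1.0
    r_cut: float = 3.0
    mode: str = "cut_shifted"

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.mode in ("cut_shifted", "force_shifted") and self.r_cut <= self.sigma:
            raise ValueError("r_cut must exceed sigma for truncated modes")

    @property
    def effective_cutoff(self) -> float:
        """Radius beyond which the interaction is exactly zero (inf for plain)."""
        if self.mode == "wca":
            return WCA_CUTOFF * self.sigma
        if self.mode == "plain":
            return math.inf
        return self.r_cut


@dataclass(frozen=True)
class BondParams:
    """Harmonic bond, U(r) = (k/2)(r - r0)^2.

    The 1/2 convention matches common MD packages, so a quoted spring constant
    of 75,000 epsilon/sigma^2 means k_spring = 75,000 here.
    """

    k_spring: float = 75000.0
    r0: float = 1.0

    def __post_init__(self) -> None:
        if self.k_spring <= 0:
            raise ValueError("k_spring must be positive")
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")


def _unit_rows(m: np.ndarray) -> np.ndarray:
    return m / np.linalg.norm(m, axis=1, keepdims=True)


@dataclass(frozen=True)
class PatchParams:
    """Kern-Frenkel patch geometry and square-well range.

    ``cos_theta_s`` is the cosine of the patch half-angle. The default 0.65
    (half-angle 49.46 degrees) makes the four tetrahedral caps exactly
    disjoint and cover a 0.7 fraction of the particle surface
    (4 * (1 - cos_theta_s)/2 = 0.7), so a pair of particles can form at most
    one patch-patch bond — the tetravalent limited-valence model.
    ``lambda_range`` is the width of the attractive square well beyond the
    hard core.
    """

    epsilon: float = 1.0
    sigma: float = 1.0
    cos_theta_s: float = 0.65
    lambda_range: float = 0.5
    patch_directions: np.ndarray = field(
        default_factory=lambda: TETRAHEDRAL_DIRECTIONS.copy()
    )

    def __post_init__(self) -> None:
        if not (-1.0 < self.cos_theta_s < 1.0):
            raise ValueError("cos_theta_s must lie strictly inside (-1, 1)")
        if self.lambda_range <= 0:
            raise ValueError("lambda_range must be positive")
        dirs = np.asarray(self.patch_directions, dtype=float)
        if dirs.ndim != 2 or dirs.shape[1] != 3:
            raise ValueError("patch_directions must be an (n, 3) array")
        object.__setattr__(self, "patch_directions", _unit_rows(dirs))


# ---------------------------------------------------------------------------
# scalar reference implementations


def _check_r(r: float) -> None:
    if r <= 0:
        raise ValueError(f"pair distance must be positive, got {r}")


def lj_energy(r: float, p: PairParams) -> float:
    """Bare 12-6 Lennard-Jones energy 4*eps*[(sigma/r)^12 - (sigma/r)^6]."""
    _check_r(r)
    sr6 = (p.sigma / r) ** 6
    return 4.0 * p.epsilon * (sr6 * sr6 - sr6)


def lj_force(r: float, p: PairParams) -> float:
    """Bare LJ force magnitude, -dU/dr (positive = repulsive)."""
    _check_r(r)
    sr6 = (p.sigma / r) ** 6
    return 24.0 * p.epsilon * (2.0 * sr6 * sr6 - sr6) / r


def lj_cut_shifted_energy(r: float, p: PairParams) -> float:
    """LJ truncated at r_cut and shifted to zero there."""
    _check_r(r)
    if r >= p.r_cut:
        return 0.0
    return lj_energy(r, p) - lj_energy(p.r_cut, p)


def lj_force_shifted_energy_force(r: float, p: PairParams) -> tuple[float, float]:
    """Force-shifted LJ: energy and force both vanish continuously at r_cut.

    Returns ``(energy, force magnitude)`` with force = -dU/dr.
    """
    _check_r(r)
    if r >= p.r_cut:
        return 0.0, 0.0
    fc = lj_force(p.r_cut, p)
    e = lj_energy(r, p) - lj_energy(p.r_cut, p) + fc * (r - p.r_cut)
    f = lj_force(r, p) - fc
    return e, f


def wca_energy(r: float, p: PairParams) -> float:
    """Purely repulsive WCA energy: LJ + eps below 2^(1/6) sigma, else 0."""
    _check_r(r)
    if r >= WCA_CUTOFF * p.sigma:
        return 0.0
    return lj_energy(r, p) + p.epsilon


def pair_energy_force(r: float, p: PairParams) -> tuple[float, float]:
    """Energy and force magnitude for any nonbonded mode of ``p``."""
    _check_r(r)
    if p.mode == "plain":
        return lj_energy(r, p), lj_force(r, p)
    if p.mode == "cut_shifted":
        if r >= p.r_cut:
            return 0.0, 0.0
        return lj_cut_shifted_energy(r, p), lj_force(r, p)
    if p.mode == "force_shifted":
        return lj_force_shifted_energy_force(r, p)
    # wca
    if r >= WCA_CUTOFF * p.sigma:
        return 0.0, 0.0
    return wca_energy(r, p), lj_force(r, p)


def bond_energy(r: float, b: BondParams) -> float:
    """Harmonic bond energy (k/2)(r - r0)^2."""
    _check_r(r)
    return 0.5 * b.k_spring * (r - b.r0) ** 2


def bond_force(r: float, b: BondParams) -> float:
    """Harmonic bond force magnitude -dU/dr = -k(r - r0)."""
    _check_r(r)
    return -b.k_spring * (r - b.r0)


def _validate_rotation(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        raise ValueError(f"{name} must be a 3x3 rotation matrix")
    if not np.allclose(m.T @ m, np.eye(3), atol=1e-8):
        raise ValueError(f"{name} is not orthonormal")
    if np.linalg.det(m) < 0:
        raise ValueError(f"{name} is an improper rotation (det < 0)")
    return m


def patchy_pair_energy(
    r_vec: np.ndarray,
    orient1: np.ndarray,
    orient2: np.ndarray,
    p: PatchParams,
) -> float:
    """Kern-Frenkel pair energy for two patchy particles.

    Parameters
    ----------
    r_vec : (3,) array
        Displacement from particle 1 to particle 2 (minimum image already
        applied by the caller).
    orient1, orient2 : (3, 3) arrays
        Rotation matrices whose columns are the body axes of each particle in
        the lab frame; patch centers in the lab frame are ``orient @ n_body``.

    Returns
    -------
    float
        ``inf`` on hard-core overlap (|r| < sigma); ``-eps * n_bonds`` in the
        square well, where ``n_bonds`` sums over all patch pairs satisfying
        the double cone condition; 0 beyond sigma + lambda.
    """
    orient1 = _validate_rotation(orient1, "orient1")
    orient2 = _validate_rotation(orient2, "orient2")
    r_vec = np.asarray(r_vec, dtype=float)
    r = float(np.linalg.norm(r_vec))
    if r < p.sigma:
        return math.inf
    if r >= p.sigma + p.lambda_range:
        return 0.0
    rhat = r_vec / r
    n1 = orient1 @ p.patch_directions.T  # (3, n_patch), columns are lab patch axes
    n2 = orient2 @ p.patch_directions.T
    a1 = int(np.sum(rhat @ n1 > p.cos_theta_s))
    a2 = int(np.sum(-rhat @ n2 > p.cos_theta_s))
    # the double sum over (alpha, beta) factorizes into a product of counts
    return -p.epsilon * a1 * a2
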