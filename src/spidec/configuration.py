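"""System construction: boxes, model definitions, and initial configurations.

Two initialization schemes are provided, matching how each engine is driven:
random insertion at a target density (MD; severe overlaps are relaxed by the
engine's displacement-limited first steps) and cubic-lattice placement (MC,
required for hard-core patchy particles).

Coordinates are origin-at-corner and wrapped to [0, L); all analysis uses
half-open slice intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .potentials import BondParams, PairParams, PatchParams

__all__ = [
    "Box",
    "ModelSpec",
    "Configuration",
    "PackingError",
    "minimum_image",
    "wrap_positions",
    "random_insert",
    "lattice_init",
    "HP_SEQUENCE_DEFAULT",
    "HP_SEQUENCE_ADJACENT",
]

#: Default HP decamer: P beads at positions 1 and 5 (1-based), H elsewhere.
HP_SEQUENCE_DEFAULT = "PHHHPHHHHH"
#: Variant with the two P beads adjacent, at positions 5 and 6.
HP_SEQUENCE_ADJACENT = "HHHHPPHHHH"


class PackingError(RuntimeError):
    """Raised when random insertion cannot place particles without overlap."""


@dataclass(frozen=True)
class Box:
    """Periodic rectangular box with square cross-section (Ly = Lx)."""

    Lx: float
    Ly: float
    Lz: float

    def __post_init__(self) -> None:
        if min(self.Lx, self.Ly, self.Lz) <= 0:
            raise ValueError("box sides must be positive")

    @classmethod
    def rectangular(cls, Lx: float, aspect: float = 1.0) -> "Box":
        """Box with side Lx in x and y and Lz = aspect * Lx, aspect >= 1."""
        if aspect < 1.0:
            raise ValueError("Lz/Lx aspect ratio must be >= 1")
        return cls(Lx, Lx, aspect * Lx)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.Lx, self.Ly, self.Lz])

    @property
    def volume(self) -> float:
        return self.Lx * self.Ly * self.Lz


def minimum_image(dr: np.ndarray, box: Box) -> np.ndarray:
    """Map displacement components into (-L/2, L/2] per axis."""
    dr = np.asarray(dr, dtype=float)
    L = box.lengths
    out = dr - L * np.floor(dr / L + 0.5)
    # floor maps the upper edge to -L/2; fold it back to +L/2
    upper = np.isclose(out, -L / 2)
    return np.where(upper, out + L, out)


def wrap_positions(pos: np.ndarray, box: Box) -> np.ndarray:
    """Wrap coordinates into [0, L) per axis."""
    L = box.lengths
    out = pos - L * np.floor(pos / L)
    # tiny negative inputs can round to exactly L; keep the interval half-open
    return np.where(out >= L, out - L, out)


@dataclass(frozen=True)
class ModelSpec:
    """Definition of one of the four model systems.

    ``pair_params`` maps (type_i, type_j) index pairs to :class:`PairParams`;
    types are indices into ``type_names``. Chains carry ``bond_params`` and a
    ``chain_length``; patchy particles carry ``patch_params``.
    """

    kind: str  # lj_particle | lj_chain | hp_chain | patchy
    type_names: tuple[str, ...] = ("LJ",)
    pair_params: dict = field(default_factory=dict)
    bond_params: BondParams | None = None
    patch_params: PatchParams | None = None
    chain_length: int = 1
    hp_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("lj_particle", "lj_chain", "hp_chain", "patchy"):
            raise ValueError(f"unknown system kind {self.kind!r}")
        if self.kind in ("lj_chain", "hp_chain"):
            if self.bond_params is None:
                raise ValueError("chain systems require bond_params")
            if self.chain_length < 2:
                raise ValueError("chain systems require chain_length >= 2")
        if self.kind == "hp_chain":
            if self.hp_sequence is None or len(self.hp_sequence) != self.chain_length:
                raise ValueError("hp_sequence length must equal chain_length")
        if self.kind == "patchy" and self.patch_params is None:
            raise ValueError("patchy systems require patch_params")

    # -- canonical constructors -------------------------------------------

    @classmethod
    def lj_particle(cls, epsilon: float = 1.0, sigma: float = 1.0, r_cut: float = 3.0):
        """Cut-shifted LJ particles (cutoff 3 sigma)."""
        p = PairParams(epsilon, sigma, r_cut, "cut_shifted")
        return cls(kind="lj_particle", type_names=("LJ",), pair_params={(0, 0): p})

    @classmethod
    def lj_chain(
        cls,
        k_spring: float = 75000.0,
        chain_length: int = 10,
        epsilon: float = 1.0,
        sigma: float = 1.0,
        r_cut: float = 6.0,
    ):
        """10-bead homopolymer with force-shifted LJ (cutoff 6 sigma) and
        harmonic bonds; the nonbonded term is excluded between adjacent beads."""
        p = PairParams(epsilon, sigma, r_cut, "force_shifted")
        return cls(
            kind="lj_chain",
            type_names=("C",),
            pair_params={(0, 0): p},
            bond_params=BondParams(k_spring, sigma),
            chain_length=chain_length,
        )

    @classmethod
    def hp_chain(
        cls,
        sequence: str = HP_SEQUENCE_DEFAULT,
        k_spring: float = 75000.0,
        epsilon: float = 1.0,
        sigma: float = 1.0,
        r_cut: float = 6.0,
    ):
        """Two-letter (H/P) decamer: H-H attract via force-shifted LJ, while
        H-P and P-P are purely repulsive WCA. The interaction matrix is a
        per-type-pair lookup, so other matrices are configurable."""
        att = PairParams(epsilon, sigma, r_cut, "force_shifted")
        rep = PairParams(epsilon, sigma, r_cut, "wca")
        return cls(
            kind="hp_chain",
            type_names=("H", "P"),
            pair_params={(0, 0): att, (0, 1): rep, (1, 1): rep},
            bond_params=BondParams(k_spring, sigma),
            chain_length=len(sequence),
            hp_sequence=sequence.upper(),
        )

    @classmethod
    def patchy(
        cls,
        epsilon: float = 1.0,
        sigma: float = 1.0,
        cos_theta_s: float = 0.65,
        lambda_range: float = 0.5,
    ):
        """Kern-Frenkel particles with four tetrahedral patches covering a
        0.7 fraction of the surface (disjoint caps, at most one bond/pair)."""
        return cls(
            kind="patchy",
            type_names=("PATCH",),
            patch_params=PatchParams(epsilon, sigma, cos_theta_s, lambda_range),
        )

    # -- derived quantities ------------------------------------------------

    @property
    def beads_per_molecule(self) -> int:
        return self.chain_length if self.kind.endswith("chain") else 1

    def bead_type_indices(self, n_molecules: int) -> np.ndarray:
        """Per-bead type index array for ``n_molecules`` molecules."""
        if self.kind == "hp_chain":
            per = np.array([0 if c == "H" else 1 for c in self.hp_sequence])
        else:
            per = np.zeros(self.beads_per_molecule, dtype=int)
        return np.tile(per, n_molecules).astype(np.int64)

    def bead_type_names(self, n_molecules: int) -> list[str]:
        idx = self.bead_type_indices(n_molecules)
        return [self.type_names[i] for i in idx]

    def bond_list(self, n_molecules: int) -> np.ndarray:
        """(n_bonds, 2) bead-index array; empty for particle systems."""
        L = self.beads_per_molecule
        if L < 2:
            return np.zeros((0, 2), dtype=np.int64)
        base = np.column_stack([np.arange(L - 1), np.arange(1, L)])
        bonds = [base + m * L for m in range(n_molecules)]
        return np.concatenate(bonds).astype(np.int64)

    @property
    def max_cutoff(self) -> float:
        if self.kind == "patchy":
            pp = self.patch_params
            return pp.sigma + pp.lambda_range
        return max(p.effective_cutoff for p in self.pair_params.values())


@dataclass
class Configuration:
    """Instantaneous system state advanced by the engines.

    ``molecule_index`` assigns each bead to its chain (identity map for
    particle systems); ``orientations`` holds per-particle rotation matrices
    for patchy particles; ``velocities`` is populated by the MD engine.
    """

    positions: np.ndarray
    box: Box
    molecule_index: np.ndarray
    orientations: np.ndarray | None = None
    velocities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        self.molecule_index = np.asarray(self.molecule_index, dtype=np.int64)
        if self.molecule_index.shape != (self.n_particles,):
            raise ValueError("molecule_index must have one entry per particle")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def n_molecules(self) -> int:
        return int(self.molecule_index.max()) + 1 if self.n_particles else 0

    @property
    def density(self) -> float:
        return self.n_particles / self.box.volume

    def copy(self) -> "Configuration":
        return Configuration(
            self.positions.copy(),
            self.box,
            self.molecule_index.copy(),
            None if self.orientations is None else self.orientations.copy(),
            None if self.velocities is None else self.velocities.copy(),
        )


def _molecule_count(model: ModelSpec, box: Box, rho0: float) -> int:
    n_beads = rho0 * box.volume
    n_mol = int(round(n_beads / model.beads_per_molecule))
    if n_mol < 1:
        raise ValueError(
            f"rho0={rho0} in box of volume {box.volume:.3g} yields no molecules"
        )
    return n_mol


def _grid_neighbors(grid: dict, cell: tuple) -> list:
    out = []
    cx, cy, cz = cell
    for ox in (-1, 0, 1):
        for oy in (-1, 0, 1):
            for oz in (-1, 0, 1):
                out.extend(grid.get((cx + ox, cy + oy, cz + oz), ()))
    return out


class _OverlapGrid:
    """Coarse periodic cell grid for overlap checks during insertion."""

    def __init__(self, box: Box, cell_size: float = 1.0):
        self.box = box
        self.n = np.maximum(1, (box.lengths // cell_size).astype(int))
        self.grid: dict[tuple, list[np.ndarray]] = {}

    def _cell(self, p: np.ndarray) -> tuple:
        idx = (p / self.box.lengths * self.n).astype(int) % self.n
        return tuple(idx)

    def min_dist2(self, p: np.ndarray) -> float:
        cx, cy, cz = self._cell(p)
        best = np.inf
        for ox in (-1, 0, 1):
            for oy in (-1, 0, 1):
                for oz in (-1, 0, 1):
                    key = (
                        (cx + ox) % self.n[0],
                        (cy + oy) % self.n[1],
                        (cz + oz) % self.n[2],
                    )
                    for q in self.grid.get(key, ()):
                        d = minimum_image(p - q, self.box)
                        best = min(best, float(d @ d))
        return best

    def add(self, p: np.ndarray) -> None:
        self.grid.setdefault(self._cell(p), []).append(p)


def random_insert(
    model: ModelSpec,
    box: Box,
    rho0: float,
    seed: int,
    min_separation: float | None = None,
    max_retries: int = 200,
) -> Configuration:
    """Randomly insert molecules at bead density ``rho0``.

    Particles go in uniformly at random (hard-core models reject overlaps
    closer than ``min_separation`` and raise :class:`PackingError` after
    bounded retries). Chains grow as random walks with fixed bond length
    r0 and uniformly random bond directions, retrying a bead placement when
    it falls within ``min_separation`` of an already placed bead.
    """
    if rho0 <= 0:
        raise ValueError("rho0 must be positive")
    if min_separation is None:
        # hard cores need a full diameter; soft beads only need enough
        # clearance that the capped first MD steps can relax the rest
        if model.kind == "patchy":
            min_separation = 1.0
        elif model.beads_per_molecule > 1:
            min_separation = 0.9
        else:
            min_separation = 0.7
    rng = np.random.default_rng(seed)
    n_mol = _molecule_count(model, box, rho0)
    L = box.lengths

    if model.beads_per_molecule == 1:
        hard_core = min_separation > 0
        if not hard_core:
            pos = rng.random((n_mol, 3)) * L
        else:
            grid = _OverlapGrid(box, cell_size=max(1.0, min_separation))
            placed = []
            for _ in range(n_mol):
                for attempt in range(max_retries):
                    p = rng.random(3) * L
                    if grid.min_dist2(p) >= min_separation**2:
                        grid.add(p)
                        placed.append(p)
                        break
                else:
                    raise PackingError(
                        f"could not insert particle {len(placed) + 1}/{n_mol} "
                        f"at rho0={rho0} after {max_retries} attempts"
                    )
            pos = np.array(placed)
        mol = np.arange(n_mol)
        orient = None
        if model.kind == "patchy":
            orient = Rotation.random(n_mol, random_state=rng).as_matrix()
        return Configuration(wrap_positions(pos, box), box, mol, orientations=orient)

    # chains: self-avoiding-ish random walks
    nb = model.beads_per_molecule
    r0 = model.bond_params.r0
    grid = _OverlapGrid(box, cell_size=max(1.0, min_separation))
    positions = np.empty((n_mol * nb, 3))
    k = 0
    for m in range(n_mol):
        for attempt in range(max_retries):
            start = None
            for _ in range(max_retries):
                cand = rng.random(3) * L
                if grid.min_dist2(cand) >= min_separation**2:
                    start = cand
                    break
            if start is None:
                break
            chain = [start]
            ok = True
            for _ in range(nb - 1):
                for bead_try in range(max_retries):
                    v = rng.standard_normal(3)
                    v *= r0 / np.linalg.norm(v)
                    cand = wrap_positions(chain[-1] + v, box)
                    near2 = grid.min_dist2(cand)
                    prev2 = min(
                        float(np.min(np.sum(minimum_image(cand - np.array(chain[:-1]), box) ** 2, axis=1)))
                        if len(chain) > 1
                        else np.inf,
                        np.inf,
                    )
                    if min(near2, prev2) >= min_separation**2:
                        chain.append(cand)
                        break
                else:
                    ok = False
                    break
            if ok:
                for p in chain:
                    grid.add(p)
                positions[k : k + nb] = chain
                k += nb
                break
        else:
            raise PackingError(
                f"could not grow chain {m + 1}/{n_mol} at rho0={rho0}"
            )
    mol = np.repeat(np.arange(n_mol), nb)
    return Configuration(wrap_positions(positions, box), box, mol)


def lattice_init(model: ModelSpec, box: Box, rho0: float, seed: int) -> Configuration:
    """Place particles on a cubic lattice spanning the box at density ``rho0``.

    For patchy particles the orientations are drawn uniformly over rotations.
    Only single-bead models are supported (the lattice scheme is the MC
    initialization; chains are simulated with MD here).
    """
    if rho0 <= 0:
        raise ValueError("rho0 must be positive")
    if model.beads_per_molecule != 1:
        raise ValueError("lattice_init supports single-bead models only")
    rng = np.random.default_rng(seed)
    n = _molecule_count(model, box, rho0)
    L = box.lengths
    a = (box.volume / n) ** (1.0 / 3.0)
    dims = np.maximum(1, np.round(L / a).astype(int))
    while np.prod(dims) < n:
        # grow the axis whose spacing is currently largest
        spacing = L / dims
        dims[np.argmax(spacing)] += 1
    xs = [(np.arange(d) + 0.5) * L[i] / d for i, d in enumerate(dims)]
    gx, gy, gz = np.meshgrid(*xs, indexing="ij")
    sites = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    if len(sites) > n:
        keep = rng.choice(len(sites), size=n, replace=False)
        sites = sites[np.sort(keep)]
    orient = None
    if model.kind == "patchy":
        orient = Rotation.random(n, random_state=rng).as_matrix()
    return Configuration(sites, box, np.arange(n), orientations=orient)
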