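"""Per-trajectory analyses: density profiles, interface fits, slab counting,
phase-separation times, morphology classification, interfacial tension and
chain radius of gyration.

The central object is the 1-D density profile along the slab normal. Frames
are recentered so the center of mass sits at the box middle; under periodic
boundaries the center of mass is computed as a circular (angular) mean per
axis, which is translation invariant where the naive mean is not. The
profile is fit over the positive half of the recentered axis to

    rho(z) = (rho_d + rho_b)/2 - (rho_d - rho_b)/2 * tanh((z - z0)/w)

yielding the dense- and bulk-phase densities, the interface position z0 and
width w.

Interfacial tension uses the Kirkwood-Buff route,
gamma = (Lz/2) <pzz - (pxx + pyy)/2>, valid for a single slab with two flat
interfaces normal to z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .configuration import Box
from .trajectory import Trajectory

__all__ = [
    "DensityProfile",
    "InterfaceFit",
    "InterfaceFitError",
    "NotConvergedError",
    "MorphologyResult",
    "GammaEstimate",
    "RgResult",
    "PhasePoint",
    "RHO_H_DEFAULT",
    "RHO_L_DEFAULT",
    "AXES",
    "density_profile",
    "fit_interface",
    "count_slabs",
    "label_slices",
    "max_density_series",
    "detect_tau_ps",
    "detect_tau_ss",
    "classify_morphology",
    "classify_voxel_mask",
    "interfacial_tension",
    "chain_rg",
    "to_weight_fraction",
    "best_profile_axis",
    "phase_point",
]

AXES = {"x": 0, "y": 1, "z": 2}

#: Default slice cutoffs for H/L labeling: centers of the working ranges
#: 0.5-0.6 (high) and 0.1-0.4 (low); override per system.
RHO_H_DEFAULT = 0.55
RHO_L_DEFAULT = 0.25

MORPHOLOGY_ORDER = [
    "homogeneous_dilute",
    "sphere",
    "cylinder",
    "slab",
    "hollow_cylinder",
    "hollow_sphere",
    "homogeneous_dense",
]


class InterfaceFitError(RuntimeError):
    """Interface fit failed or produced unphysical parameters."""


class NotConvergedError(RuntimeError):
    """A timeline has not reached the state the estimator requires."""


@dataclass
class DensityProfile:
    """Per-slice density along one box axis, averaged over frames."""

    axis: str
    bin_centers: np.ndarray
    densities: np.ndarray
    slice_thickness: float
    box_length: float
    n_frames_averaged: int
    units: str = "sigma^-3"

    @property
    def slice_volume_factor(self) -> float:
        """Cross-section area such that density * thickness * area = count."""
        return float("nan")  # informational; set by density_profile

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.axis: self.bin_centers, "rho": self.densities})


def _circular_com(coords: np.ndarray, L: float) -> float:
    """Center of mass of periodic scalar coordinates via the angular mean."""
    theta = coords * (2.0 * math.pi / L)
    s = np.sin(theta).mean()
    c = np.cos(theta).mean()
    ang = math.atan2(s, c)
    return (ang % (2.0 * math.pi)) * L / (2.0 * math.pi)


def _recentered(coords: np.ndarray, L: float) -> np.ndarray:
    shift = L / 2.0 - _circular_com(coords, L)
    return (coords + shift) % L


def density_profile(
    traj: Trajectory,
    axis: str = "z",
    slice_thickness: float = 0.1,
    recenter: bool = True,
) -> DensityProfile:
    """Histogram particle counts into slices along ``axis`` and average.

    Each frame is recentered (circular center of mass to box middle) before
    binning, so an averaged two-phase profile keeps its dense phase at the
    box center. The default 0.1-sigma slices suit interface fitting; use
    ~1-sigma slices for slab counting.
    """
    if traj.n_frames < 1:
        raise ValueError("empty trajectory window")
    a = AXES[axis]
    L = traj.box.lengths[a]
    nbins = max(1, int(round(L / slice_thickness)))
    thickness = L / nbins
    area = traj.box.volume / L
    edges = np.linspace(0.0, L, nbins + 1)
    acc = np.zeros(nbins)
    for f in range(traj.n_frames):
        coords = traj.positions[f, :, a] % L
        if recenter:
            coords = _recentered(coords, L)
        counts, _ = np.histogram(coords, bins=edges)
        acc += counts
    dens = acc / traj.n_frames / (thickness * area)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(axis, centers, dens, thickness, L, traj.n_frames)


@dataclass
class InterfaceFit:
    """Result of the hyperbolic-tangent interface fit."""

    rho_d: float
    rho_b: float
    z0: float
    w: float
    rho_d_se: float
    rho_b_se: float
    z0_se: float
    w_se: float
    residual: float

    def summary(self) -> str:
        return (
            f"tanh interface fit: rho_d={self.rho_d:.4f}(±{self.rho_d_se:.4f}) "
            f"rho_b={self.rho_b:.4f}(±{self.rho_b_se:.4f}) "
            f"z0={self.z0:.3f} w={self.w:.3f} rss={self.residual:.3g}"
        )


def _tanh_model(z, rho_d, rho_b, z0, w):
    return 0.5 * (rho_d + rho_b) - 0.5 * (rho_d - rho_b) * np.tanh((z - z0) / w)


def fit_interface(profile: DensityProfile) -> InterfaceFit:
    """Least-squares tanh fit over the positive half of a recentered profile.

    The dense phase must sit at the box center (which ``density_profile``
    arranges); the fit then sees a single falling interface. Degenerate
    (single-phase) profiles raise :class:`InterfaceFitError`.
    """
    L = profile.box_length
    half = profile.bin_centers >= L / 2.0
    z = profile.bin_centers[half] - L / 2.0
    rho = profile.densities[half]
    if len(z) < 5:
        raise InterfaceFitError("too few slices in the positive half")
    lo, hi = float(rho.min()), float(rho.max())
    if hi - lo < 1e-4:
        raise InterfaceFitError("flat profile: no interface to fit")
    mid = 0.5 * (lo + hi)
    below = np.nonzero(rho < mid)[0]
    z0_guess = z[below[0]] if len(below) else L / 4.0
    p0 = [hi, lo, float(z0_guess), 1.0]
    try:
        popt, pcov = optimize.curve_fit(
            _tanh_model, z, rho, p0=p0,
            bounds=([0.0, 0.0, 0.0, 1e-6], [np.inf, np.inf, L / 2.0, L]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise InterfaceFitError(f"tanh fit did not converge: {exc}") from exc
    rho_d, rho_b, z0, w = popt
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    if rho_d < rho_b:
        raise InterfaceFitError("fitted dense density below bulk density")
    if w > L / 2.0:
        raise InterfaceFitError(
            f"fitted interface width {w:.2f} exceeds the half box {L / 2:.2f}"
        )
    rss = float(np.sum((_tanh_model(z, *popt) - rho) ** 2))
    return InterfaceFit(rho_d, rho_b, z0, w, *se, rss)


def label_slices(
    densities: np.ndarray, rho_H: float = RHO_H_DEFAULT, rho_L: float = RHO_L_DEFAULT
) -> list[str]:
    """Label slices H (> rho_H) or L (< rho_L); intermediate slices drop out."""
    if rho_H <= rho_L:
        raise ValueError("rho_H must exceed rho_L")
    out = []
    for d in densities:
        if d > rho_H:
            out.append("H")
        elif d < rho_L:
            out.append("L")
    return out


def count_slabs(
    profile: DensityProfile,
    rho_H: float = RHO_H_DEFAULT,
    rho_L: float = RHO_L_DEFAULT,
) -> int | None:
    """Number of slabs = half the number of H/L interfaces on the circular
    filtered slice sequence. Returns None when every slice is filtered out
    (indeterminate), 0 for an all-H or all-L (homogeneous) profile."""
    seq = label_slices(profile.densities, rho_H, rho_L)
    if not seq:
        return None
    transitions = sum(
        1 for i in range(len(seq)) if seq[i] != seq[(i + 1) % len(seq)]
    )
    return transitions // 2


def max_density_series(
    traj: Trajectory, slice_thickness: float = 1.0, axis: str = "z"
) -> pd.DataFrame:
    """Per-frame maximum slice density along ``axis`` (no recentering)."""
    a = AXES[axis]
    L = traj.box.lengths[a]
    nbins = max(1, int(round(L / slice_thickness)))
    edges = np.linspace(0.0, L, nbins + 1)
    vol = traj.box.volume / nbins
    rows = []
    for f in range(traj.n_frames):
        counts, _ = np.histogram(traj.positions[f, :, a] % L, bins=edges)
        rows.append((int(traj.steps[f]), counts.max() / vol))
    return pd.DataFrame(rows, columns=["step", "max_density"])


def detect_tau_ps(
    traj: Trajectory, slice_thickness: float = 1.0, axis: str = "z",
    plateau_fraction: float = 0.25,
) -> int:
    """First step at which the maximum slice density reaches its plateau.

    The plateau is the median of the final ``plateau_fraction`` of the
    max-density series. If the first crossing falls inside that final
    stretch the system is still coarsening and NotConvergedError is raised.

    ``traj`` may also be a precomputed (step, max_density) DataFrame.
    """
    if isinstance(traj, pd.DataFrame):
        series = traj
    else:
        series = max_density_series(traj, slice_thickness, axis)
    n = len(series)
    if n < 4:
        raise NotConvergedError("too few frames to locate a plateau")
    tail_start = int(math.floor(n * (1.0 - plateau_fraction)))
    plateau = float(series["max_density"].iloc[tail_start:].median())
    crossing = np.nonzero(series["max_density"].to_numpy() >= plateau)[0]
    first = int(crossing[0])
    if first >= tail_start:
        raise NotConvergedError(
            "maximum density is still rising: no plateau before the final "
            f"{plateau_fraction:.0%} of the trajectory"
        )
    return int(series["step"].iloc[first])


def slab_count_series(
    traj: Trajectory,
    rho_H: float = RHO_H_DEFAULT,
    rho_L: float = RHO_L_DEFAULT,
    slice_thickness: float = 1.0,
    axis: str = "z",
) -> pd.DataFrame:
    rows = []
    for f in range(traj.n_frames):
        prof = density_profile(
            traj.window(f, f + 1), axis, slice_thickness, recenter=False
        )
        rows.append((int(traj.steps[f]), count_slabs(prof, rho_H, rho_L)))
    return pd.DataFrame(rows, columns=["step", "n_slabs"])


def detect_tau_ss(
    traj: Trajectory,
    rho_H: float = RHO_H_DEFAULT,
    rho_L: float = RHO_L_DEFAULT,
    slice_thickness: float = 1.0,
    axis: str = "z",
    persistence: int = 5,
) -> int | None:
    """First step at which the slab count reaches 1 and stays there.

    The count must remain 1 for at least ``persistence`` consecutive saved
    frames (or to the trajectory end if fewer remain) — a guard against
    single-frame flicker. Returns None if a single slab is never reached.

    ``traj`` may also be a precomputed (step, n_slabs) DataFrame.
    """
    if isinstance(traj, pd.DataFrame):
        series = traj
    else:
        series = slab_count_series(traj, rho_H, rho_L, slice_thickness, axis)
    counts = series["n_slabs"].tolist()
    n = len(counts)
    for i in range(n):
        if counts[i] == 1:
            need = min(persistence, n - i)
            if all(counts[i + k] == 1 for k in range(need)):
                return int(series["step"].iloc[i])
    return None


# ---------------------------------------------------------------------------
# morphology


@dataclass
class MorphologyResult:
    label: str
    dense_span: int | None = None
    dilute_span: int | None = None
    n_dense_components: int = 0
    ambiguous: bool = False

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def _periodic_components(mask: np.ndarray):
    """Connected components (6-neighbor) of a periodic boolean grid.

    Returns a list of (voxel index array, spanned-axis count). A component
    spans an axis if a BFS that tracks unwrapped cell offsets revisits a cell
    with a different offset along that axis (non-zero winding).
    """
    shape = mask.shape
    labels = np.full(shape, -1, dtype=np.int64)
    comps = []
    offsets = {}
    idx = np.argwhere(mask)
    for seed_cell in idx:
        seed = tuple(seed_cell)
        if labels[seed] != -1:
            continue
        cid = len(comps)
        stack = [seed]
        labels[seed] = cid
        offsets[seed] = (0, 0, 0)
        members = [seed]
        spans = [False, False, False]
        while stack:
            cell = stack.pop()
            off = offsets[cell]
            for a in range(3):
                for step in (-1, 1):
                    nxt = list(cell)
                    nxt[a] = (nxt[a] + step) % shape[a]
                    nxt_t = tuple(nxt)
                    if not mask[nxt_t]:
                        continue
                    noff = list(off)
                    noff[a] = off[a] + step  # unwrapped cell offset
                    noff = tuple(noff)
                    if labels[nxt_t] == -1:
                        labels[nxt_t] = cid
                        offsets[nxt_t] = noff
                        members.append(nxt_t)
                        stack.append(nxt_t)
                    else:
                        old = offsets[nxt_t]
                        for b in range(3):
                            if old[b] != noff[b]:
                                spans[b] = True
        comps.append((members, sum(spans)))
    return comps


def classify_voxel_mask(mask: np.ndarray, min_voxels: int = 3) -> MorphologyResult:
    """Label a periodic dense-voxel mask by spanning dimensionality.

    Dense component spanning 0/1/2 box directions -> sphere/cylinder/slab; a
    dense phase percolating in all 3 directions is hollow, labeled by the
    largest dilute component (0 -> hollow_sphere, 1 -> hollow_cylinder).
    A lower-dimensional dense shape that encloses a separate dilute pocket
    (shell or tube) is also labeled hollow. Components smaller than
    ``min_voxels`` are treated as noise.
    """
    mask = np.asarray(mask, dtype=bool)
    dense_comps = [c for c in _periodic_components(mask) if len(c[0]) >= min_voxels]
    if not dense_comps:
        return MorphologyResult("homogeneous_dilute", None, None, 0)
    dilute_comps = [
        c for c in _periodic_components(~mask) if len(c[0]) >= min_voxels
    ]
    if not dilute_comps:
        return MorphologyResult(
            "homogeneous_dense", 3, None, len(dense_comps)
        )
    dense_comps.sort(key=lambda c: len(c[0]), reverse=True)
    dilute_comps.sort(key=lambda c: len(c[0]), reverse=True)
    dense_span = dense_comps[0][1]
    dilute_span = dilute_comps[0][1]
    n_dense = len(dense_comps)
    ambiguous = n_dense > 1

    if dense_span == 3:
        if dilute_span == 0:
            label = "hollow_sphere"
        elif dilute_span == 1:
            label = "hollow_cylinder"
        else:
            label = "slab"
            ambiguous = True  # bicontinuous / unresolved structure
    else:
        enclosed = len(dilute_comps) > 1 and any(c[1] < 3 for c in dilute_comps[1:])
        if dense_span == 0:
            label = "hollow_sphere" if enclosed else "sphere"
        elif dense_span == 1:
            label = "hollow_cylinder" if enclosed else "cylinder"
        else:
            label = "slab"
    return MorphologyResult(label, dense_span, dilute_span, n_dense, ambiguous)


def classify_morphology(
    traj: Trajectory,
    cell_size: float = 1.0,
    threshold: float | None = None,
    rho_H: float = RHO_H_DEFAULT,
    rho_L: float = RHO_L_DEFAULT,
    min_voxels: int = 3,
) -> MorphologyResult:
    """Classify the dense-phase shape of a post-separation window.

    A 3-D density grid (cells of about ``cell_size``) is averaged over the
    frames after recentering each frame's center of mass to the box middle,
    then thresholded at the midpoint of the dense/dilute plateau estimates
    (default (rho_H + rho_L)/2) and labeled by periodic connected components.
    """
    if threshold is None:
        threshold = 0.5 * (rho_H + rho_L)
    L = traj.box.lengths
    dims = np.maximum(2, np.round(L / cell_size).astype(int))
    vol = traj.box.volume / np.prod(dims)
    grid = np.zeros(dims)
    for f in range(traj.n_frames):
        pts = traj.positions[f] % L
        rec = np.column_stack([_recentered(pts[:, a], L[a]) for a in range(3)])
        hist, _ = np.histogramdd(
            rec, bins=[np.linspace(0, L[a], dims[a] + 1) for a in range(3)]
        )
        grid += hist
    grid /= traj.n_frames * vol
    return classify_voxel_mask(grid >= threshold, min_voxels=min_voxels)


# ---------------------------------------------------------------------------
# interfacial tension


@dataclass
class GammaEstimate:
    gamma: float
    stderr: float
    n_samples: int

    def summary(self) -> str:
        return f"gamma = {self.gamma:.4f} ± {self.stderr:.4f} ({self.n_samples} samples)"


def interfacial_tension(
    pressure: pd.DataFrame,
    Lz: float,
    start_step: int | None = None,
    n_blocks: int = 5,
) -> GammaEstimate:
    """Kirkwood-Buff tension from a pressure-tensor time series.

    gamma = (Lz/2) <pzz - (pxx + pyy)/2>, averaged over samples with
    step >= start_step (default: the second half of the series). The
    standard error comes from ``n_blocks`` block means.
    """
    if len(pressure) == 0:
        raise ValueError("empty pressure series")
    df = pressure
    if start_step is None:
        start_step = int(df["step"].iloc[len(df) // 2])
    df = df[df["step"] >= start_step]
    if len(df) == 0:
        raise ValueError("empty averaging window")
    aniso = (df["pzz"] - 0.5 * (df["pxx"] + df["pyy"])).to_numpy()
    gamma = 0.5 * Lz * float(aniso.mean())
    nb = min(n_blocks, len(aniso))
    blocks = np.array_split(aniso, nb)
    bmeans = 0.5 * Lz * np.array([b.mean() for b in blocks])
    se = float(bmeans.std(ddof=1) / math.sqrt(nb)) if nb > 1 else float("nan")
    return GammaEstimate(gamma, se, len(aniso))


# ---------------------------------------------------------------------------
# chain radius of gyration


@dataclass
class RgResult:
    values: np.ndarray  # per chain, per frame
    mean: float
    rms: float

    def histogram(self, bins: int = 50):
        return np.histogram(self.values, bins=bins)


def _unwrap_chain(coords: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Unwrap a chain across periodic images by minimum-image bond vectors."""
    bonds = np.diff(coords, axis=0)
    bonds -= L * np.round(bonds / L)
    blen = np.linalg.norm(bonds, axis=1)
    if np.any(blen > np.min(L) / 4.0):
        raise ValueError(
            "chain unwrap ambiguity: bond longer than a quarter box after "
            "minimum imaging"
        )
    out = np.empty_like(coords)
    out[0] = coords[0]
    out[1:] = coords[0] + np.cumsum(bonds, axis=0)
    return out


def chain_rg(
    traj: Trajectory,
    fit: InterfaceFit | None = None,
    axis: str = "z",
) -> RgResult:
    """Per-chain radius of gyration over all frames.

    Chains are unwrapped along their bonds before computing
    Rg^2 = mean_i |r_i - r_cm|^2 (equal masses). When an interface fit is
    supplied, only chains whose unwrapped center lies within the fitted slab
    (|z - Lz/2| < z0 after recentering) enter the statistics.
    """
    mol = traj.molecule_index
    if np.all(np.bincount(mol) == 1):
        raise ValueError("trajectory has no chain topology")
    L = traj.box.lengths
    a = AXES[axis]
    values = []
    chain_ids = np.unique(mol)
    for f in range(traj.n_frames):
        pts = traj.positions[f]
        if fit is not None:
            zc = _recentered(pts[:, a] % L[a], L[a])
        for cid in chain_ids:
            sel = mol == cid
            coords = _unwrap_chain(pts[sel], L)
            if fit is not None:
                z_chain = _circular_com(zc[sel], L[a])
                # after recentering the slab center sits at L/2
                if abs(z_chain - L[a] / 2.0) >= fit.z0:
                    continue
            com = coords.mean(axis=0)
            rg2 = float(np.mean(np.sum((coords - com) ** 2, axis=1)))
            values.append(math.sqrt(rg2))
    values = np.asarray(values)
    if len(values) == 0:
        raise ValueError("no chains selected")
    return RgResult(values, float(values.mean()), float(np.sqrt(np.mean(values**2))))


# ---------------------------------------------------------------------------
# concentration conversion

AVOGADRO = 6.02214076e23


def to_weight_fraction(
    profile: DensityProfile,
    molecular_weight: float,
    water_density_kg_per_L: float = 1.0,
) -> DensityProfile:
    """Convert a molecule-center number-density profile (per Angstrom^3) to
    weight/weight concentration against water.

    wt/wt per slice = (count * MW / N_A) / (slice volume * water density);
    with densities in A^-3, MW in Da and water in kg/L this reduces to
    rho * MW / (0.602214076 * water_density).
    """
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be positive")
    if water_density_kg_per_L <= 0:
        raise ValueError("water density must be positive")
    factor = molecular_weight / (0.602214076 * water_density_kg_per_L)
    return DensityProfile(
        profile.axis,
        profile.bin_centers.copy(),
        profile.densities * factor,
        profile.slice_thickness,
        profile.box_length,
        profile.n_frames_averaged,
        units="wt/wt",
    )


# ---------------------------------------------------------------------------
# windowing and phase-point extraction


def best_profile_axis(traj: Trajectory, slice_thickness: float = 1.0) -> str:
    """Axis with the largest density contrast (slab-normal autodetection)."""
    best, best_axis = -1.0, "z"
    for axis in ("x", "y", "z"):
        prof = density_profile(traj, axis, slice_thickness)
        contrast = float(prof.densities.max() - prof.densities.min())
        if contrast > best:
            best, best_axis = contrast, axis
    return best_axis


@dataclass
class PhasePoint:
    """One binodal point: coexistence densities (and tension) at one T."""

    temperature: float
    rho_b: float
    rho_d: float
    rho_b_se: float = float("nan")
    rho_d_se: float = float("nan")
    gamma: float | None = None
    gamma_se: float | None = None
    width: float = float("nan")
    provenance: str = ""


def equilibrium_window(
    traj: Trajectory,
    rho_H: float = RHO_H_DEFAULT,
    rho_L: float = RHO_L_DEFAULT,
    axis: str = "z",
) -> tuple[Trajectory, int]:
    """Second half of the trajectory, or [tau_SS, end] when the fusion into a
    single slab completes only in the second half. Returns (window, start_step)."""
    half_idx = traj.n_frames // 2
    start_step = int(traj.steps[half_idx])
    tau_ss = detect_tau_ss(traj, rho_H, rho_L, axis=axis)
    if tau_ss is not None and tau_ss > start_step:
        idx = int(np.searchsorted(traj.steps, tau_ss))
        return traj.window(idx), tau_ss
    return traj.window(half_idx), start_step


def phase_point(
    traj: Trajectory,
    temperature: float,
    pressure: pd.DataFrame | None = None,
    rho_H: float = RHO_H_DEFAULT,
    rho_L: float = RHO_L_DEFAULT,
    slice_thickness: float = 0.1,
    axis: str | None = None,
    provenance: str = "",
) -> PhasePoint:
    """Extract a binodal point (and optionally gamma) from a slab trajectory."""
    window, start_step = equilibrium_window(traj, rho_H, rho_L)
    if axis is None:
        axis = best_profile_axis(window)
    coarse = density_profile(window, axis, 1.0)
    if count_slabs(coarse, rho_H, rho_L) != 1:
        raise InterfaceFitError(
            "window is not a single-slab two-phase state "
            f"(slab count {count_slabs(coarse, rho_H, rho_L)!r})"
        )
    prof = density_profile(window, axis, slice_thickness)
    fit = fit_interface(prof)
    gamma = gamma_se = None
    if pressure is not None and len(pressure):
        est = interfacial_tension(
            pressure, traj.box.lengths[AXES[axis]], start_step=start_step
        )
        gamma, gamma_se = est.gamma, est.stderr
    return PhasePoint(
        temperature,
        fit.rho_b,
        fit.rho_d,
        fit.rho_b_se,
        fit.rho_d_se,
        gamma,
        gamma_se,
        fit.w,
        provenance,
    )
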