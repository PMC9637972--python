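"""Cross-temperature and cross-geometry aggregation.

Covers: assembly of binodals from per-temperature phase points and their
critical-point fit; scanning initial density to locate the boundaries
between dense-phase morphologies (the effective spinodal at the extremes);
the 1/(1+xi) scaling of those boundaries with box elongation; and the two
closed-form references (van der Waals fluid, symmetric Flory-Huggins blend)
for binodal/spinodal geometry.

Critical-point fit: with beta fixed at the 3-D Ising value 0.32,

    (rho_b + rho_d)/2 = rho_c + A (T - T_c)        (rectilinear diameter)
    rho_d - rho_b     = B (T_c - T)^beta           (order parameter)

are fit jointly (shared T_c, rho_c) by least squares.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .configuration import Box, ModelSpec, lattice_init, random_insert
from .md import MDParams, default_timestep, run_md
from .mc import MCParams, run_mc
from .slab import (
    MORPHOLOGY_ORDER,
    NotConvergedError,
    PhasePoint,
    classify_morphology,
    detect_tau_ps,
)

__all__ = [
    "CriticalFit",
    "fit_critical_point",
    "MorphologyScan",
    "scan_boundaries",
    "BoundaryScalingFit",
    "fit_boundary_scaling",
    "vdw_theory",
    "flory_huggins_theory",
    "TheoryCurves",
]

ISING_BETA = 0.32


@dataclass
class CriticalFit:
    T_c: float
    rho_c: float
    A: float
    B: float
    T_c_se: float
    rho_c_se: float
    A_se: float
    B_se: float
    beta_exponent: float = ISING_BETA
    n_points: int = 0
    excluded_temperatures: list = field(default_factory=list)

    def diameter(self, T: np.ndarray) -> np.ndarray:
        return self.rho_c + self.A * (np.asarray(T) - self.T_c)

    def width(self, T: np.ndarray) -> np.ndarray:
        dT = np.clip(self.T_c - np.asarray(T), 0.0, None)
        return self.B * dT**self.beta_exponent

    def binodal(self, T: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d, w = self.diameter(T), self.width(T)
        return d - w / 2.0, d + w / 2.0

    def summary(self) -> str:
        return (
            f"critical point fit (beta={self.beta_exponent}): "
            f"T_c={self.T_c:.4f}(±{self.T_c_se:.4f}) "
            f"rho_c={self.rho_c:.4f}(±{self.rho_c_se:.4f}) "
            f"A={self.A:.4f} B={self.B:.4f} on {self.n_points} temperatures"
        )


def fit_critical_point(
    points: list[PhasePoint],
    beta: float = ISING_BETA,
    exclude_near_tc: float = 0.02,
) -> CriticalFit:
    """Joint least-squares fit of the diameter and order-parameter laws.

    Temperatures within ``exclude_near_tc`` (relative) of the running T_c
    estimate are dropped and the fit repeated once: near-critical slabs in
    finite boxes bias both densities.
    """
    pts = sorted(points, key=lambda p: p.temperature)
    if len(pts) < 3:
        raise ValueError("need at least 3 temperatures to fit the critical point")
    T = np.array([p.temperature for p in pts])
    mid = np.array([0.5 * (p.rho_b + p.rho_d) for p in pts])
    width = np.array([p.rho_d - p.rho_b for p in pts])
    if np.any(np.diff(width[np.argsort(T)]) > 0):
        warnings.warn(
            "binodal width is not monotonically decreasing with T", stacklevel=2
        )

    def residuals(x, T, mid, width):
        Tc, rhoc, A, B = x
        dT = Tc - T
        pen = np.where(dT <= 0, 1e3 * (1e-4 - np.minimum(dT, 0.0)), 0.0)
        r1 = mid - rhoc - A * (T - Tc)
        r2 = width - B * np.clip(dT, 1e-12, None) ** beta
        return np.concatenate([r1, r2 + pen])

    def solve(T, mid, width):
        Tmax, Tmin = T.max(), T.min()
        span = max(Tmax - Tmin, 1e-3)
        x0 = [Tmax + 0.3 * span, float(mid.mean()), -0.05, float(width.max())]
        return optimize.least_squares(
            residuals, x0, args=(T, mid, width), max_nfev=20000
        )

    res = solve(T, mid, width)
    Tc = res.x[0]
    keep = T < (1.0 - exclude_near_tc) * Tc
    excluded = [float(t) for t in T[~keep]]
    if keep.sum() >= 3 and excluded:
        res = solve(T[keep], mid[keep], width[keep])
        n_used = int(keep.sum())
    else:
        excluded = []
        n_used = len(T)

    # standard errors from the Jacobian at the solution
    m, k = res.jac.shape[0], 4
    dof = max(m - k, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(4, np.nan)
    Tc, rhoc, A, B = res.x
    return CriticalFit(
        Tc, rhoc, A, B, se[0], se[1], se[2], se[3], beta, n_used, excluded
    )


# ---------------------------------------------------------------------------
# morphology-boundary scans


@dataclass
class MorphologyScan:
    """Rows of (Lz/Lx, rho0, majority label) plus per-seed labels."""

    rows: pd.DataFrame  # columns Lz_over_Lx, rho0, label
    per_seed: pd.DataFrame  # columns Lz_over_Lx, rho0, seed, label

    def boundaries(self, aspect: float | None = None) -> pd.DataFrame:
        """Midpoints between adjacent differing labels along the density grid.

        Ambiguous rows (no majority across seeds) contribute their own rho0
        as the boundary value. Returns columns (Lz_over_Lx, lower_label,
        upper_label, rho0_boundary).
        """
        out = []
        df = self.rows
        aspects = [aspect] if aspect is not None else sorted(df["Lz_over_Lx"].unique())
        for asp in aspects:
            sub = df[df["Lz_over_Lx"] == asp].sort_values("rho0")
            rhos = sub["rho0"].to_numpy()
            labels = sub["label"].tolist()
            ambig = sub["ambiguous"].to_numpy()
            order = {m: i for i, m in enumerate(MORPHOLOGY_ORDER)}
            ranks = [order[l] for l in labels]
            if any(b < a for a, b in zip(ranks, ranks[1:])):
                warnings.warn(
                    f"non-monotone morphology sequence at Lz/Lx={asp}: "
                    + ", ".join(
                        f"{r:g}:{l}" for r, l in zip(rhos, labels)
                    ),
                    stacklevel=2,
                )
            for i in range(len(rhos) - 1):
                if labels[i] != labels[i + 1]:
                    if ambig[i + 1] and labels[i + 1] != labels[i]:
                        b = float(rhos[i + 1])
                    elif ambig[i]:
                        b = float(rhos[i])
                    else:
                        b = 0.5 * float(rhos[i] + rhos[i + 1])
                    out.append((asp, labels[i], labels[i + 1], b))
        return pd.DataFrame(
            out, columns=["Lz_over_Lx", "lower_label", "upper_label", "rho0_boundary"]
        )

    def boundary_between(
        self, lower_label: str, upper_label: str, aspect: float | None = None
    ) -> float:
        """Midpoint between the highest density labeled ``lower_label`` and
        the lowest labeled ``upper_label`` (the scan's tie rule applies)."""
        df = self.rows
        if aspect is not None:
            df = df[df["Lz_over_Lx"] == aspect]
        lo = df[df["label"] == lower_label]["rho0"]
        hi = df[df["label"] == upper_label]["rho0"]
        if lo.empty or hi.empty:
            raise ValueError(
                f"scan contains no {lower_label!r}/{upper_label!r} pair"
            )
        return 0.5 * (float(lo.max()) + float(hi.min()))


def _majority(labels: list[str]) -> tuple[str, bool]:
    vals, counts = np.unique(labels, return_counts=True)
    best = int(np.argmax(counts))
    return str(vals[best]), counts[best] <= len(labels) // 2 and len(vals) > 1


def _run_one_scan_point(
    model: ModelSpec,
    box: Box,
    rho0: float,
    temperature: float,
    seed: int,
    engine: str,
    min_steps: int,
    max_steps: int,
    save_interval: int,
    classify_fraction: float,
    rho_H: float,
    rho_L: float,
):
    if engine == "mc":
        config = lattice_init(model, box, rho0, seed)
        params = MCParams(
            n_steps=min_steps, temperature=temperature,
            save_interval=save_interval, seed=seed,
        )
        result = run_mc(config, model, params)
    else:
        config = random_insert(model, box, rho0, seed)
        params = MDParams(
            n_steps=min_steps, temperature=temperature,
            dt=default_timestep(model), save_interval=save_interval, seed=seed,
        )
        result = run_md(config, model, params)
    traj = result.trajectory
    # adaptive extension: aim for at least 5 * tau_PS of trajectory
    try:
        tau = detect_tau_ps(traj)
        target = min(5 * tau, max_steps)
    except NotConvergedError:
        target = min(2 * min_steps, max_steps)
    total = min_steps
    while total < target:
        extra = min(target - total, min_steps)
        if engine == "mc":
            params = MCParams(
                n_steps=extra, temperature=temperature,
                save_interval=save_interval, seed=seed + 7919,
            )
            result2 = run_mc(result.final, model, params)
        else:
            params = MDParams(
                n_steps=extra, temperature=temperature,
                dt=default_timestep(model), save_interval=save_interval,
                seed=seed + 7919, limit_steps=0,
            )
            result2 = run_md(result.final, model, params)
        t2 = result2.trajectory
        t2.steps = t2.steps + total
        traj = _concat_traj(traj, t2)
        result = result2
        total += extra
    n = traj.n_frames
    start = max(1, int(n * (1.0 - classify_fraction)))
    return classify_morphology(traj.window(start), rho_H=rho_H, rho_L=rho_L)


def _concat_traj(a, b):
    from .trajectory import Trajectory

    return Trajectory(
        np.concatenate([a.positions, b.positions[1:]]),
        np.concatenate([a.steps, b.steps[1:]]),
        a.box,
        a.species,
        a.molecule_index,
        None
        if a.orientations is None
        else np.concatenate([a.orientations, b.orientations[1:]]),
        a.time_per_step,
    )


def scan_boundaries(
    model: ModelSpec,
    Lx: float,
    temperature: float,
    density_grid,
    aspect: float = 1.0,
    seeds=(0, 1, 2),
    engine: str = "md",
    min_steps: int = 100_000,
    max_steps: int = 400_000,
    save_interval: int = 2000,
    classify_fraction: float = 0.25,
    rho_H: float = 0.55,
    rho_L: float = 0.25,
    base_seed: int = 0,
) -> MorphologyScan:
    """Classify the post-separation morphology on a grid of initial densities.

    Each (rho0, seed) gets its own short simulation from a fresh random
    insertion (MD) or lattice (MC); the run is extended adaptively to about
    5x the phase-separation time (bounded by ``max_steps``). The label per
    density is the majority over seeds; rows with no majority are flagged
    ambiguous and contribute their own density as the boundary (tie rule).
    """
    if engine == "mc":
        min_steps = max(min_steps, 1)
    box = Box.rectangular(Lx, aspect)
    rows = []
    per_seed = []
    for rho0 in density_grid:
        labels = []
        for k, s in enumerate(seeds):
            run_seed = int(
                np.random.SeedSequence([base_seed, int(round(rho0 * 1e6)), s])
                .generate_state(1)[0]
                % 2**31
            )
            morph = _run_one_scan_point(
                model, box, rho0, temperature, run_seed, engine,
                min_steps, max_steps, save_interval, classify_fraction,
                rho_H, rho_L,
            )
            labels.append(morph.label)
            per_seed.append((aspect, float(rho0), s, morph.label))
        label, ambiguous = _majority(labels)
        rows.append((aspect, float(rho0), label, ambiguous))
    return MorphologyScan(
        pd.DataFrame(rows, columns=["Lz_over_Lx", "rho0", "label", "ambiguous"]),
        pd.DataFrame(per_seed, columns=["Lz_over_Lx", "rho0", "seed", "label"]),
    )


# ---------------------------------------------------------------------------
# boundary scaling with box elongation


@dataclass
class BoundaryScalingFit:
    """Fit of rho0(xi) = (rho_1 + rho_inf * xi) / (1 + xi), xi = Lz/Lx - 1."""

    rho_1: dict
    rho_inf: float | dict
    shared: bool

    def predict(self, transition, xi: np.ndarray) -> np.ndarray:
        xi = np.asarray(xi, dtype=float)
        r1 = self.rho_1[transition]
        rinf = self.rho_inf if self.shared else self.rho_inf[transition]
        return (r1 + rinf * xi) / (1.0 + xi)


def fit_boundary_scaling(
    data: dict,
    shared_rho_inf: bool = True,
) -> BoundaryScalingFit:
    """Least squares of boundary densities against box elongation.

    ``data`` maps a transition key to (xi, rho0) arrays. The model is linear
    in (rho_1, rho_inf) after multiplying through by (1 + xi). With
    ``shared_rho_inf`` all transitions share a single extrapolated density
    rho_inf (one common spinodal estimate), otherwise each is fit alone.
    """
    keys = list(data)
    for k in keys:
        if len(np.atleast_1d(data[k][0])) < 3:
            raise ValueError(f"transition {k!r}: need at least 3 aspect ratios")
    if not shared_rho_inf:
        rho1, rinf = {}, {}
        for k in keys:
            xi = np.asarray(data[k][0], dtype=float)
            y = np.asarray(data[k][1], dtype=float) * (1.0 + xi)
            A = np.column_stack([np.ones_like(xi), xi])
            sol, *_ = np.linalg.lstsq(A, y, rcond=None)
            rho1[k], rinf[k] = float(sol[0]), float(sol[1])
        return BoundaryScalingFit(rho1, rinf, False)
    # shared rho_inf: block design matrix
    rows_A, rows_y = [], []
    nk = len(keys)
    for i, k in enumerate(keys):
        xi = np.asarray(data[k][0], dtype=float)
        y = np.asarray(data[k][1], dtype=float) * (1.0 + xi)
        A = np.zeros((len(xi), nk + 1))
        A[:, i] = 1.0
        A[:, nk] = xi
        rows_A.append(A)
        rows_y.append(y)
    A = np.vstack(rows_A)
    y = np.concatenate(rows_y)
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    rho1 = {k: float(sol[i]) for i, k in enumerate(keys)}
    return BoundaryScalingFit(rho1, float(sol[nk]), True)


# ---------------------------------------------------------------------------
# closed-form theory curves


@dataclass
class TheoryCurves:
    """Binodal and spinodal branches on a control-parameter grid."""

    parameter: np.ndarray  # T/Tc (vdW) or chi (FH)
    binodal_low: np.ndarray
    binodal_high: np.ndarray
    spinodal_low: np.ndarray
    spinodal_high: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.parameter,
                "binodal_low": self.binodal_low,
                "binodal_high": self.binodal_high,
                "spinodal_low": self.spinodal_low,
                "spinodal_high": self.spinodal_high,
            }
        )


def _vdw_pressure(rho, T):
    # units rho_c = T_c = 1; b = 1/3, a = 9/8
    return rho * T / (1.0 - rho / 3.0) - 1.125 * rho * rho


def _vdw_mu(rho, T):
    b = 1.0 / 3.0
    return -T * np.log((1.0 - b * rho) / rho) + T / (1.0 - b * rho) - 2.25 * rho


def _vdw_spinodal(T):
    # dP/drho = 0  <=>  T = (9/4) rho (1 - rho/3)^2
    f = lambda rho: 2.25 * rho * (1.0 - rho / 3.0) ** 2 - T
    lo = optimize.brentq(f, 1e-9, 1.0)
    hi = optimize.brentq(f, 1.0, 3.0 - 1e-9)
    return lo, hi


def vdw_theory(T_grid) -> TheoryCurves:
    """Binodal (Maxwell construction) and spinodal of the van der Waals fluid.

    Temperatures are in units of T_c and densities in units of rho_c, for the
    equation of state (P + (9/8) T_c rho^2 / rho_c)(1 - rho/(3 rho_c)) = rho T.
    Coexistence requires T < T_c; rows at T >= 1 are NaN.
    """
    T_grid = np.atleast_1d(np.asarray(T_grid, dtype=float))
    out = np.full((len(T_grid), 4), np.nan)
    for i, T in enumerate(T_grid):
        if T >= 1.0 or T <= 0.0:
            continue
        sp_lo, sp_hi = _vdw_spinodal(T)
        p_hi = _vdw_pressure(sp_lo, T)  # local max of P on the dilute side
        p_lo = max(_vdw_pressure(sp_hi, T), 0.0)  # local min, clipped at vacuum

        def rho_v(P):
            return optimize.brentq(lambda r: _vdw_pressure(r, T) - P, 1e-12, sp_lo)

        def rho_l(P):
            return optimize.brentq(
                lambda r: _vdw_pressure(r, T) - P, sp_hi, 3.0 - 1e-9
            )

        def dmu(P):
            return _vdw_mu(rho_l(P), T) - _vdw_mu(rho_v(P), T)

        eps = 1e-10 * max(p_hi, 1.0)
        P_co = optimize.brentq(dmu, p_lo + eps, p_hi - eps, xtol=1e-14)
        out[i] = rho_v(P_co), rho_l(P_co), sp_lo, sp_hi
    return TheoryCurves(T_grid, out[:, 0], out[:, 1], out[:, 2], out[:, 3])


def flory_huggins_theory(L: int, chi_grid) -> TheoryCurves:
    """Binodal and spinodal mole fractions of a symmetric polymer blend.

    Free energy per site f = (phi/L) ln phi + ((1-phi)/L) ln(1-phi)
    + chi phi (1-phi) for two species of equal length L. The critical point
    is phi_c = 1/2, chi_c = 2/L; the binodal uses the exchange-symmetry
    condition df/dphi = 0 at phi != 1/2. Rows at chi <= chi_c are NaN.
    """
    if L < 1:
        raise ValueError("chain length L must be >= 1")
    chi_grid = np.atleast_1d(np.asarray(chi_grid, dtype=float))
    chi_c = 2.0 / L
    out = np.full((len(chi_grid), 4), np.nan)
    for i, chi in enumerate(chi_grid):
        if chi <= chi_c:
            continue
        # spinodal: 1/(phi(1-phi)) = 2 L chi
        disc = 1.0 - 2.0 / (L * chi)
        s = 0.5 * math.sqrt(disc)
        sp_lo, sp_hi = 0.5 - s, 0.5 + s

        def dfdphi(phi):
            return math.log(phi / (1.0 - phi)) / L + chi * (1.0 - 2.0 * phi)

        lo = optimize.brentq(dfdphi, 1e-15, 0.5 - 1e-9)
        out[i] = lo, 1.0 - lo, sp_lo, sp_hi
    return TheoryCurves(chi_grid, out[:, 0], out[:, 1], out[:, 2], out[:, 3])
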