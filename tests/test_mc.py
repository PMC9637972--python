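"""Metropolis MC engine: acceptance rules, detailed balance against
quadrature oracles, rotation moves, bookkeeping and pressure."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from spidec import (
    Box,
    Configuration,
    MCParams,
    ModelSpec,
    compute_pressure_tensor,
    lattice_init,
    mc_pressure_tensor,
    run_mc,
)
from spidec.fixtures import patchy_pair_oracle
from spidec.mc import UnsupportedModelError, recompute_energy, rotate_move
from spidec.potentials import PatchParams, patchy_pair_energy


def test_zero_delta_u_moves_always_accepted():
    """With interactions off every move has dU = 0 and must be accepted."""
    model = ModelSpec.lj_particle(epsilon=1e-10, sigma=1e-3, r_cut=3e-3)
    box = Box.rectangular(6.0)
    cfg = lattice_init(model, box, 0.2, seed=1)
    res = run_mc(cfg, model, MCParams(n_steps=50, temperature=0.5, seed=2,
                                      save_interval=50))
    acc = res.acceptance["displacement"]
    assert acc["accepted"] == acc["attempted"]


def test_patchy_hard_core_never_violated():
    """Overlapping proposals are always rejected: no sampled frame contains a
    pair closer than sigma."""
    model = ModelSpec.patchy()
    box = Box.rectangular(7.0)
    cfg = lattice_init(model, box, 0.4, seed=3)
    res = run_mc(cfg, model, MCParams(n_steps=3_000, temperature=0.5,
                                      save_interval=500, seed=4))
    L = box.lengths
    for f in range(res.trajectory.n_frames):
        pos = res.trajectory.positions[f]
        d = pos[:, None] - pos[None, :]
        d -= L * np.round(d / L)
        dist = np.sqrt((d**2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        assert dist.min() >= 1.0 - 1e-9


def test_incremental_energy_matches_full_recomputation():
    """Accumulated dU agrees with a full O(N^2) recomputation to 1e-8 after
    well over 1e4 attempted moves, for both engines."""
    patchy = ModelSpec.patchy()
    box = Box.rectangular(7.0)
    cfg = lattice_init(patchy, box, 0.4, seed=5)
    res = run_mc(cfg, patchy, MCParams(n_steps=100, temperature=0.55,
                                       save_interval=100, seed=6))
    assert res.energy == pytest.approx(recompute_energy(res.final, patchy), abs=1e-8)

    lj = ModelSpec.lj_particle()
    cfg2 = lattice_init(lj, Box.rectangular(7.0), 0.4, seed=7)
    res2 = run_mc(cfg2, lj, MCParams(n_steps=100, temperature=0.9,
                                     save_interval=100, seed=8))
    assert res2.energy == pytest.approx(recompute_energy(res2.final, lj), abs=1e-8)


def test_mc_deterministic_per_seed():
    model = ModelSpec.patchy()
    box = Box.rectangular(7.0)
    cfg = lattice_init(model, box, 0.3, seed=9)
    p = MCParams(n_steps=200, temperature=0.6, save_interval=200, seed=10)
    r1 = run_mc(cfg, model, p)
    r2 = run_mc(cfg, model, p)
    np.testing.assert_array_equal(r1.final.positions, r2.final.positions)
    np.testing.assert_array_equal(r1.final.orientations, r2.final.orientations)


class TestRotateMove:
    def test_output_stays_orthonormal(self):
        m = np.eye(3)
        for k in range(200):
            m = rotate_move(m, 0.05, seed=k if k == 0 else None)
            assert np.allclose(m.T @ m, np.eye(3), atol=1e-12)
            assert np.linalg.det(m) == pytest.approx(1.0, abs=1e-12)

    def test_z_axis_deviation_bounded(self):
        rng = np.random.default_rng(11)
        for k in range(200):
            m0 = Rotation.random(random_state=rng).as_matrix()
            m1 = rotate_move(m0, 0.05, seed=1000 + k)
            cosdev = float(m0[:, 2] @ m1[:, 2])
            assert cosdev >= np.cos(0.05) - 1e-12

    def test_vanishing_halfwidth_is_identity(self):
        m0 = Rotation.random(random_state=np.random.default_rng(1)).as_matrix()
        m1 = rotate_move(m0, 1e-12, seed=5)
        assert np.allclose(m1, m0, atol=1e-9)

    def test_repeated_application_uniformizes_axes(self):
        """After many bounded rotations the z axis is uniform on the sphere:
        cap-counting against the analytic cap area."""
        rng = np.random.default_rng(12)
        samples = []
        from spidec import _kernels

        _kernels.seed_rng(77)
        for walker in range(60):
            m = Rotation.random(random_state=rng).as_matrix()
            for _ in range(400):
                m = rotate_move(m, 0.5)
            samples.append(m[:, 2])
        samples = np.array(samples)
        for direction in (np.array([0, 0, 1.0]), np.array([1, 1, 0]) / np.sqrt(2)):
            frac = np.mean(samples @ direction > 0.5)  # cap of half-angle 60 deg
            se = np.sqrt(0.25 * 0.75 / len(samples))
            assert abs(frac - 0.25) < 3.5 * se


def test_two_particle_patchy_matches_boltzmann_oracle():
    """Bonded fraction of a patchy pair in a periodic box matches direct
    quadrature over separations and orientations within 3 sigma —
    a detailed-balance check covering both move types."""
    p = PatchParams()
    model = ModelSpec.patchy()
    box = Box.rectangular(3.2)
    T = 0.3
    oracle = patchy_pair_oracle(p, T, box)
    rng = np.random.default_rng(13)
    cfg = Configuration(
        np.array([[0.5, 0.5, 0.5], [2.0, 2.0, 2.0]]),
        box,
        np.arange(2),
        orientations=Rotation.random(2, random_state=rng).as_matrix(),
    )
    res = run_mc(cfg, model, MCParams(
        n_steps=150_000, temperature=T, save_interval=150,
        displacement_side=1.0, rotation_halfwidth=0.5, seed=14,
    ))
    traj = res.trajectory
    bonded = []
    for f in range(20, traj.n_frames):
        d = traj.positions[f, 1] - traj.positions[f, 0]
        d -= box.lengths * np.round(d / box.lengths)
        e = patchy_pair_energy(d, traj.orientations[f, 0], traj.orientations[f, 1], p)
        bonded.append(e <= -1.0)
    frac = np.mean(bonded)
    # block standard error over 5 blocks of correlated samples
    blocks = np.array_split(np.array(bonded, dtype=float), 5)
    se = np.std([b.mean() for b in blocks], ddof=1) / np.sqrt(5)
    assert abs(frac - oracle.bonded_fraction) < 3 * se + 0.01


def test_two_particle_lj_radial_distribution_matches_quadrature():
    """Sampled pair-separation histogram matches r^2 exp(-beta U) quadrature:
    Metropolis detailed balance for the continuous-potential path."""
    model = ModelSpec.lj_particle()
    rc, T = 3.0, 0.9
    box = Box.rectangular(8.0)
    cfg = Configuration(
        np.array([[1.0, 1.0, 1.0], [2.1, 1.0, 1.0]]), box, np.arange(2)
    )
    res = run_mc(cfg, model, MCParams(n_steps=300_000, temperature=T,
                                      save_interval=100, seed=15,
                                      displacement_side=0.6))
    traj = res.trajectory
    d = traj.positions[:, 1] - traj.positions[:, 0]
    d -= box.lengths * np.round(d / box.lengths)
    r = np.linalg.norm(d, axis=1)[50:]
    edges = np.array([1.0, 1.15, 1.4, 1.8, 2.4, 3.0])
    hist, _ = np.histogram(r, bins=edges)
    sel = r < 3.0
    # quadrature with the same cut-shifted potential
    rg = np.linspace(0.7, 3.0, 200_000)
    u = 4 * (rg**-12 - rg**-6) - 4 * (rc**-12.0 - rc**-6.0)
    w = rg**2 * np.exp(-u / T)
    probs = np.array([
        np.trapezoid(w[(rg >= a) & (rg < b)], rg[(rg >= a) & (rg < b)])
        for a, b in zip(edges[:-1], edges[1:])
    ])
    probs /= probs.sum()
    got = hist / hist.sum()
    n_eff = sel.sum() / 10  # generous correlation discount
    for gi, pi in zip(got, probs):
        se = np.sqrt(pi * (1 - pi) / n_eff)
        assert abs(gi - pi) < 4 * se + 0.01


class TestMCPressure:
    def test_ideal_gas_is_rho_T(self):
        model = ModelSpec.lj_particle(epsilon=1e-10, sigma=1e-3, r_cut=3e-3)
        box = Box.rectangular(9.0)
        cfg = lattice_init(model, box, 0.3, seed=16)
        pt = mc_pressure_tensor(cfg, model, temperature=1.1)
        rho_t = cfg.density * 1.1
        assert pt.pxx == pytest.approx(rho_t, rel=1e-9)
        assert pt.pyy == pytest.approx(rho_t, rel=1e-9)
        assert pt.pzz == pytest.approx(rho_t, rel=1e-9)

    def test_virial_agrees_with_md_engine_on_frozen_configuration(self):
        model = ModelSpec.lj_particle()
        box = Box.rectangular(8.0)
        rng = np.random.default_rng(17)
        from spidec.configuration import random_insert

        cfg = random_insert(model, box, 0.4, seed=18)
        cfg.velocities = np.zeros((cfg.n_particles, 3))
        md = compute_pressure_tensor(cfg, model)  # kinetic part zero
        T = 0.8
        mc = mc_pressure_tensor(cfg, model, T)
        rho_t = cfg.density * T
        assert mc.pxx - rho_t == pytest.approx(md.pxx, rel=1e-10)
        assert mc.pzz - rho_t == pytest.approx(md.pzz, rel=1e-10)

    def test_patchy_rejected(self):
        model = ModelSpec.patchy()
        box = Box.rectangular(7.0)
        cfg = lattice_init(model, box, 0.3, seed=19)
        with pytest.raises(UnsupportedModelError):
            mc_pressure_tensor(cfg, model, 0.6)


def test_patchy_spinodal_decomposition_smoke():
    """N=250 patchy particles at rho0=0.36, T=0.61 demix within 5e5 sweeps:
    some 1-sigma slice reaches 1.5x the initial density and the profile fits
    to a dense phase well above the dilute one.

    (The tetravalent network liquid equilibrates near rho_d ~ 0.63, so a
    2x-rho0 slice threshold is above the dense-phase density itself; 1.5x
    plus the two-phase fit is the sharpest test this model admits.)"""
    from spidec.slab import best_profile_axis, density_profile, fit_interface, max_density_series

    from spidec.slab import InterfaceFitError

    model = ModelSpec.patchy()
    box = Box.rectangular((250 / 0.36) ** (1 / 3))
    cfg = lattice_init(model, box, 0.36, seed=20)
    state, total = cfg, 0
    reached = False
    while total < 500_000:
        res = run_mc(state, model, MCParams(n_steps=60_000, temperature=0.61,
                                            save_interval=6_000, seed=21 + total))
        state = res.final
        total += 60_000
        best = max(
            max_density_series(res.trajectory, axis=ax)["max_density"].iloc[-3:].min()
            for ax in "xyz"
        )
        if best <= 1.5 * 0.36:
            continue
        window = res.trajectory.window(res.trajectory.n_frames // 2)
        axis = best_profile_axis(window)
        try:
            fit = fit_interface(density_profile(window, axis, 0.25))
        except InterfaceFitError:
            continue
        if fit.rho_d > 0.5 and fit.rho_b < 0.5 * fit.rho_d:
            reached = True
            break
    assert reached, "no dense domain with a two-phase profile within 5e5 sweeps"
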