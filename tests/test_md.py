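"""Langevin MD engine: integrator correctness, thermostat statistics,
pressure virial, neighbor search, determinism and failure modes."""

import numpy as np
import pytest

from spidec import (
    Box,
    Configuration,
    MDParams,
    ModelSpec,
    compute_pressure_tensor,
    run_md,
)
from spidec.configuration import random_insert
from spidec.md import IntegrationError, build_cell_list
from spidec.potentials import PairParams, pair_energy_force

RMIN = 2.0 ** (1.0 / 6.0)


def test_energy_conservation_zero_friction():
    """With the thermostat off the integrator is symplectic velocity Verlet:
    total energy drifts < 1e-4 over 1e4 steps at dt = 0.005."""
    model = ModelSpec.lj_particle()
    box = Box.rectangular(10.0)
    pos = np.array([[5.0, 5.0, 5.0], [5.0 + RMIN + 0.05, 5.0, 5.0]])
    vel = np.array([[0.02, 0.01, 0.0], [-0.02, -0.01, 0.0]])
    cfg = Configuration(pos, box, np.arange(2), velocities=vel)
    res = run_md(
        cfg,
        model,
        MDParams(n_steps=10_000, temperature=0.0, friction=0.0,
                 save_interval=500, seed=1, limit_steps=0),
    )
    total = res.potential_energy + res.kinetic_energy
    assert total.max() - total.min() < 1e-4


def test_momentum_conserved_without_thermostat():
    model = ModelSpec.lj_particle()
    box = Box.rectangular(8.0)
    cfg = random_insert(model, box, 0.2, seed=3)
    rng = np.random.default_rng(4)
    vel = rng.standard_normal((cfg.n_particles, 3)) * 0.5
    vel -= vel.mean(axis=0)
    cfg.velocities = vel
    res = run_md(
        cfg,
        model,
        MDParams(n_steps=2_000, temperature=0.0, friction=0.0,
                 save_interval=2_000, seed=5, limit_steps=0),
    )
    assert np.abs(res.final.velocities.sum(axis=0)).max() < 1e-10


def test_equipartition_at_equilibrium(lj_fluid_run):
    """Mean kinetic energy per degree of freedom = T/2 within 2%."""
    n = lj_fluid_run.final.n_particles
    kes = lj_fluid_run.kinetic_energy[5:]  # discard approach to equilibrium
    kT = 2.0 * kes.mean() / (3.0 * n)
    assert kT == pytest.approx(1.5, rel=0.02)


def test_configurational_and_kinetic_temperature_agree():
    """Configurational temperature (thermometer by exact-sampler calibration)
    matches the kinetic temperature within 3%, for an LJ system at T=0.9,
    rho=0.5.

    The mean potential energy of the Langevin run is converted to an
    effective configurational temperature against <U>(T) measured with the
    Metropolis MC engine — an exact Boltzmann sampler — at two bracketing
    temperatures; at these conditions dU/dT is steep (~3.9 per particle), so
    the thermometer resolves well below 1%. (Gradient-based configurational
    thermometers carry r^-13..r^-26 tails whose sampling variance is
    impractical for a steep LJ core.)"""
    from spidec import MCParams, run_mc
    from spidec.configuration import lattice_init
    from spidec.mc import recompute_energy

    model = ModelSpec.lj_particle()
    box = Box.rectangular(10.5, 1.0)
    cfg = random_insert(model, box, 0.5, seed=31)
    warm = run_md(cfg, model, MDParams(n_steps=10_000, temperature=0.9,
                                       friction=1.0, save_interval=10_000,
                                       seed=32))
    run = run_md(warm.final, model, MDParams(n_steps=40_000, temperature=0.9,
                                             friction=1.0, save_interval=500,
                                             seed=33, limit_steps=0))
    n = run.final.n_particles

    def mc_mean_u(T, seed):
        c = lattice_init(model, box, n / box.volume, seed=seed)
        eq = run_mc(c, model, MCParams(n_steps=2500, temperature=T,
                                       save_interval=2500, seed=seed + 1,
                                       displacement_side=0.3))
        prod = run_mc(eq.final, model, MCParams(n_steps=6000, temperature=T,
                                                save_interval=100, seed=seed + 2,
                                                displacement_side=0.3))
        es = [
            recompute_energy(
                Configuration(prod.trajectory.positions[f], box, np.arange(n)),
                model,
            )
            for f in range(10, prod.trajectory.n_frames)
        ]
        return float(np.mean(es)) / n

    t_lo, t_hi = 0.85, 0.95
    u_lo, u_hi = mc_mean_u(t_lo, 300), mc_mean_u(t_hi, 400)
    u_md = float(run.potential_energy[20:].mean()) / n
    # linear calibration through the bracket midpoint
    slope = (u_hi - u_lo) / (t_hi - t_lo)
    t_conf = 0.5 * (t_lo + t_hi) + (u_md - 0.5 * (u_lo + u_hi)) / slope
    kes = run.kinetic_energy[20:]
    t_kin = 2.0 * kes.mean() / (3.0 * n)
    assert t_conf == pytest.approx(t_kin, rel=0.03)


def test_free_particle_msd_follows_langevin_law():
    """Mean-square displacement matches the closed-form Ornstein-Uhlenbeck
    result for a thermal free particle within sampling error."""
    model = ModelSpec.lj_particle()
    box = Box.rectangular(10.0)
    T, gamma, dt, nst = 1.0, 0.5, 0.005, 200
    rng = np.random.default_rng(99)
    msds = []
    for s in range(250):
        v0 = rng.standard_normal(3) * np.sqrt(T)
        cfg = Configuration(
            np.array([[5.0, 5.0, 5.0]]), box, np.arange(1), velocities=v0[None, :]
        )
        res = run_md(
            cfg,
            model,
            MDParams(n_steps=nst, temperature=T, friction=gamma, dt=dt,
                     save_interval=nst, seed=s, limit_steps=0, pressure_interval=0),
        )
        d = res.trajectory.positions[-1, 0] - res.trajectory.positions[0, 0]
        d -= box.lengths * np.round(d / box.lengths)
        msds.append(d @ d)
    t = nst * dt
    theory = 6.0 * T / gamma * (t - (1.0 - np.exp(-gamma * t)) / gamma)
    se = np.std(msds) / np.sqrt(len(msds))
    assert abs(np.mean(msds) - theory) < 3.5 * se


def test_trajectory_deterministic_per_seed():
    model = ModelSpec.lj_particle()
    box = Box.rectangular(8.0)
    cfg = random_insert(model, box, 0.3, seed=6)
    p = MDParams(n_steps=2_000, temperature=0.65, save_interval=1_000, seed=77)
    r1 = run_md(cfg, model, p)
    r2 = run_md(cfg, model, p)
    np.testing.assert_array_equal(r1.trajectory.positions, r2.trajectory.positions)
    r3 = run_md(cfg, model, MDParams(n_steps=2_000, temperature=0.65,
                                     save_interval=1_000, seed=78))
    assert not np.array_equal(r1.final.positions, r3.final.positions)


def test_blowup_reports_step():
    model = ModelSpec.lj_particle()
    box = Box.rectangular(8.0)
    cfg = random_insert(model, box, 0.3, seed=8)
    with pytest.raises(IntegrationError, match="step"):
        run_md(
            cfg,
            model,
            MDParams(n_steps=2_000, temperature=0.65, dt=0.5,  # absurd timestep
                     save_interval=1_000, seed=9, limit_steps=0),
        )


class TestPressureTensor:
    def test_ideal_gas_matches_rho_T(self):
        """Interactions off (sub-resolution sigma, tiny epsilon): p = rho T."""
        model = ModelSpec.lj_particle(epsilon=1e-10, sigma=1e-3, r_cut=3e-3)
        box = Box.rectangular(12.0)
        rng = np.random.default_rng(10)
        n = 500
        T = 1.2
        samples = []
        for s in range(40):
            pos = rng.random((n, 3)) * box.lengths
            vel = rng.standard_normal((n, 3)) * np.sqrt(T)
            cfg = Configuration(pos, box, np.arange(n), velocities=vel)
            pt = compute_pressure_tensor(cfg, model)
            samples.append([pt.pxx, pt.pyy, pt.pzz])
        mean = np.mean(samples)
        rho_t = n / box.volume * T
        assert mean == pytest.approx(rho_t, rel=0.02)

    def test_two_fixed_particles_virial_arithmetic(self):
        """pxx V = r f(r) exactly for two particles separated along x."""
        model = ModelSpec.lj_particle()
        box = Box.rectangular(10.0)
        r = 1.5
        pos = np.array([[2.0, 5.0, 5.0], [2.0 + r, 5.0, 5.0]])
        cfg = Configuration(pos, box, np.arange(2), velocities=np.zeros((2, 3)))
        pt = compute_pressure_tensor(cfg, model)
        _, f = pair_energy_force(r, PairParams(1.0, 1.0, 3.0, "cut_shifted"))
        assert pt.pxx * box.volume == pytest.approx(r * f, rel=1e-12)
        assert pt.pyy == 0.0 and pt.pzz == 0.0

    def test_homogeneous_fluid_isotropic(self, lj_fluid_run):
        """<pzz - (pxx+pyy)/2> = 0 within sampling error for a bulk fluid."""
        df = lj_fluid_run.pressure
        half = df[df["step"] > df["step"].max() // 3]
        aniso = (half["pzz"] - 0.5 * (half["pxx"] + half["pyy"])).to_numpy()
        blocks = np.array_split(aniso, 10)
        bm = np.array([b.mean() for b in blocks])
        se = bm.std(ddof=1) / np.sqrt(len(bm))
        assert abs(aniso.mean()) < 4 * se + 1e-4


class TestCellList:
    def test_spaced_line_has_no_pairs(self):
        model = ModelSpec.lj_particle()
        box = Box.rectangular(20.0)
        r_cut = 2.0
        pos = np.array([[1.0, 1, 1], [1 + 2.2, 1, 1], [1 + 4.4, 1, 1]])
        cfg = Configuration(pos, box, np.arange(3))
        assert len(build_cell_list(cfg, r_cut)) == 0

    def test_pair_across_periodic_boundary(self):
        box = Box.rectangular(10.0)
        pos = np.array([[0.2, 5.0, 5.0], [9.9, 5.0, 5.0]])
        cfg = Configuration(pos, box, np.arange(2))
        pairs = build_cell_list(cfg, 1.0)
        assert len(pairs) == 1

    def test_matches_brute_force_on_random_configurations(self):
        rng = np.random.default_rng(12)
        for trial in range(200):
            Lx = rng.uniform(4.0, 12.0)
            aspect = rng.uniform(1.0, 3.0)
            box = Box.rectangular(Lx, aspect)
            n = rng.integers(2, 60)
            pos = rng.random((n, 3)) * box.lengths
            r_cut = rng.uniform(0.5, min(box.lengths) / 2)
            cfg = Configuration(pos, box, np.arange(n))
            pairs = build_cell_list(cfg, r_cut)
            got = {tuple(sorted(p)) for p in pairs.tolist()}
            d = pos[:, None] - pos[None, :]
            d -= box.lengths * np.round(d / box.lengths)
            dist = np.sqrt((d**2).sum(-1))
            expect = {
                (i, j)
                for i in range(n)
                for j in range(i + 1, n)
                if dist[i, j] < r_cut
            }
            assert got == expect

    def test_oversized_cutoff_rejected(self):
        box = Box.rectangular(6.0)
        cfg = Configuration(np.zeros((1, 3)), box, np.arange(1))
        with pytest.raises(ValueError):
            build_cell_list(cfg, 4.0)


def test_phase_separation_smoke(lj_slab_runs):
    """At T=0.65, rho0=0.3 an LJ system develops a dense slab: some 1-sigma
    slice reaches density > 0.6 well before the run ends."""
    res = lj_slab_runs[0.65]
    from spidec.slab import max_density_series

    best = max(
        max_density_series(res.trajectory, axis=ax)["max_density"].iloc[-1]
        for ax in "xyz"
    )
    assert best > 0.6
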