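"""Density profiles, interface fits, slab counting, timescales, morphology,
tension and chain Rg — exercised on synthetic fixtures with known answers."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spidec import Box, Trajectory
from spidec.fixtures import (
    SyntheticProfileSpec,
    fjc_rg2_exact,
    make_tanh_profile,
    make_two_phase_trajectory,
    make_voxel_morphology,
    sample_fjc,
)
from spidec.slab import (
    DensityProfile,
    InterfaceFitError,
    NotConvergedError,
    chain_rg,
    classify_morphology,
    classify_voxel_mask,
    count_slabs,
    density_profile,
    detect_tau_ps,
    detect_tau_ss,
    fit_interface,
    interfacial_tension,
    to_weight_fraction,
)


def _uniform_traj(box, n, n_frames=4, seed=0):
    rng = np.random.default_rng(seed)
    pos = rng.random((n_frames, n, 3)) * box.lengths
    return Trajectory(pos, np.arange(n_frames), box, ["LJ"] * n, np.arange(n))


class TestDensityProfile:
    def test_uniform_configuration_flat_within_poisson(self):
        box = Box.rectangular(10.0, 2.0)
        traj = _uniform_traj(box, 4000, n_frames=8)
        prof = density_profile(traj, "z", 1.0)
        mean = 4000 / box.volume
        # ~200 counts per slice per frame, 8 frames -> ~2.5% noise
        assert np.all(np.abs(prof.densities - mean) < 5 * mean / math.sqrt(200 * 8))

    def test_counts_sum_to_n(self):
        box = Box.rectangular(9.0, 1.5)
        traj = _uniform_traj(box, 777, n_frames=1)
        prof = density_profile(traj, "z", 0.1, recenter=False)
        slice_volume = prof.slice_thickness * box.volume / prof.box_length
        assert prof.densities.sum() * slice_volume == pytest.approx(777)

    def test_two_phase_fixture_recovers_plateaus(self):
        box = Box.rectangular(10.0, 4.0)
        traj = make_two_phase_trajectory(box, 0.7, 0.05, 6.0, n_frames=40, seed=2)
        prof = density_profile(traj, "z", 0.5)
        fit = fit_interface(prof)
        assert fit.rho_d == pytest.approx(0.7, rel=0.02)
        assert fit.rho_b == pytest.approx(0.05, rel=0.2, abs=0.005)

    def test_recentering_translation_invariance(self):
        box = Box.rectangular(10.0, 3.0)
        traj = make_two_phase_trajectory(box, 0.7, 0.05, 5.0, n_frames=6, seed=3)
        prof = density_profile(traj, "z", 0.5)
        for shift in (3.7, 11.0, -8.21):
            shifted = Trajectory(
                (traj.positions + shift) % box.lengths,
                traj.steps, box, traj.species, traj.molecule_index,
            )
            prof2 = density_profile(shifted, "z", 0.5)
            # binning error only: allow one-bin leakage
            assert np.abs(prof.densities - prof2.densities).max() < 0.12

    def test_empty_window_rejected(self):
        box = Box.rectangular(8.0)
        traj = _uniform_traj(box, 10, n_frames=2)
        with pytest.raises(ValueError):
            density_profile(traj.window(2, 2))


class TestInterfaceFit:
    def test_noise_free_roundtrip_exact(self):
        spec = SyntheticProfileSpec(rho_d=0.7, rho_b=0.05, z0=10.0, w=2.0)
        fit = fit_interface(make_tanh_profile(spec))
        assert fit.rho_d == pytest.approx(0.7, abs=1e-6)
        assert fit.rho_b == pytest.approx(0.05, abs=1e-6)
        assert fit.z0 == pytest.approx(10.0, abs=1e-5)
        assert fit.w == pytest.approx(2.0, abs=1e-5)

    def test_noisy_recovery_within_stated_errors(self):
        """Over replicates, true parameters fall within 3 estimated SEs."""
        spec = SyntheticProfileSpec(noise_sd=0.01)
        misses = 0
        n_rep = 60
        for seed in range(n_rep):
            fit = fit_interface(make_tanh_profile(spec, seed=seed))
            ok = (
                abs(fit.rho_d - spec.rho_d) < 3 * fit.rho_d_se
                and abs(fit.rho_b - spec.rho_b) < 3 * fit.rho_b_se
            )
            misses += not ok
        # 3-sigma coverage ~99.7% per parameter; allow a generous few misses
        assert misses <= 3

    def test_flat_profile_raises(self):
        spec = SyntheticProfileSpec(rho_d=0.3, rho_b=0.3)
        with pytest.raises(InterfaceFitError):
            fit_interface(make_tanh_profile(spec))

    def test_width_doubling_doubles_10_90_width(self):
        """10-90% interface width = w*(atanh 0.8 - atanh(-0.8)) = 2w atanh 0.8."""
        for w in (1.0, 2.0):
            spec = SyntheticProfileSpec(w=w, n_slices=4000)
            fit = fit_interface(make_tanh_profile(spec))
            assert 2 * fit.w * math.atanh(0.8) == pytest.approx(
                2 * w * math.atanh(0.8), rel=1e-4
            )


def _profile_from(densities, thickness=1.0):
    d = np.asarray(densities, dtype=float)
    L = thickness * len(d)
    centers = (np.arange(len(d)) + 0.5) * thickness
    return DensityProfile("z", centers, d, thickness, L, 1)


class TestCountSlabs:
    def test_single_slab(self):
        prof = _profile_from([0.8] * 4 + [0.01] * 4)
        assert count_slabs(prof) == 1

    def test_two_slabs_periodic(self):
        prof = _profile_from([0.8, 0.8, 0.01, 0.01, 0.8, 0.8, 0.01, 0.01])
        assert count_slabs(prof) == 2

    def test_all_high_is_homogeneous_dense(self):
        assert count_slabs(_profile_from([0.9] * 8)) == 0

    def test_intermediate_slices_filtered(self):
        # H . L . H L pattern with fillers between rho_L and rho_H
        prof = _profile_from([0.8, 0.4, 0.01, 0.35, 0.8, 0.01])
        assert count_slabs(prof, 0.55, 0.25) == 2

    def test_all_filtered_is_indeterminate(self):
        assert count_slabs(_profile_from([0.4, 0.35, 0.3])) is None

    def test_requires_ordered_cutoffs(self):
        with pytest.raises(ValueError):
            count_slabs(_profile_from([0.1]), rho_H=0.2, rho_L=0.3)


class TestTimescales:
    def test_tau_ps_constructed_series(self):
        steps = np.arange(0, 100) * 100
        dens = np.concatenate([np.linspace(0.3, 0.7, 40), np.full(60, 0.7)])
        dens[40:] += 0.001 * np.sin(np.arange(60))  # small plateau wobble
        series = pd.DataFrame({"step": steps, "max_density": dens})
        tau = detect_tau_ps(series)
        assert tau == pytest.approx(3900, abs=200)

    def test_tau_ps_no_plateau_raises(self):
        steps = np.arange(0, 50) * 100
        series = pd.DataFrame(
            {"step": steps, "max_density": np.linspace(0.3, 1.0, 50)}
        )
        with pytest.raises(NotConvergedError):
            detect_tau_ps(series)

    def test_tau_ss_first_persistent_single_slab(self):
        counts = [3, 2, 2, 1, 1, 1, 1, 1, 1]
        series = pd.DataFrame(
            {"step": np.arange(len(counts)) * 10, "n_slabs": counts}
        )
        assert detect_tau_ss(series) == 30

    def test_tau_ss_never_reached(self):
        series = pd.DataFrame({"step": [0, 10, 20], "n_slabs": [3, 2, 2]})
        assert detect_tau_ss(series) is None

    def test_tau_ss_antiflicker(self):
        counts = [2, 1, 2, 1, 1, 1, 1, 1]
        series = pd.DataFrame(
            {"step": np.arange(len(counts)) * 10, "n_slabs": counts}
        )
        # the isolated 1 at step 10 does not count; persistence starts at 30
        assert detect_tau_ss(series) == 30


class TestMorphology:
    @pytest.mark.parametrize(
        "label",
        [
            "homogeneous_dilute",
            "homogeneous_dense",
            "sphere",
            "cylinder",
            "slab",
            "hollow_cylinder",
            "hollow_sphere",
        ],
    )
    def test_voxel_roundtrip(self, label):
        mask = make_voxel_morphology(label)
        assert classify_voxel_mask(mask).label == label

    def test_shell_counts_as_hollow_sphere(self):
        mask = make_voxel_morphology("shell", radius=3.0)
        assert classify_voxel_mask(mask).label == "hollow_sphere"

    def test_oversized_sphere_rejected(self):
        with pytest.raises(ValueError):
            make_voxel_morphology("sphere", shape=(10, 10, 10), radius=8.0)

    def test_multiple_components_flagged(self):
        mask = np.zeros((16, 16, 16), dtype=bool)
        mask[2:6, 2:6, 2:6] = True
        mask[10:13, 10:13, 10:13] = True
        res = classify_voxel_mask(mask)
        assert res.label == "sphere"  # largest component
        assert res.n_dense_components == 2
        assert res.ambiguous

    def test_two_phase_trajectory_classifies_as_slab(self):
        box = Box.rectangular(10.0, 3.0)
        traj = make_two_phase_trajectory(box, 0.8, 0.02, 5.0, n_frames=8, seed=5)
        assert classify_morphology(traj).label == "slab"


class TestInterfacialTension:
    def test_isotropic_pressure_gives_zero(self):
        df = pd.DataFrame(
            {"step": np.arange(100), "pxx": 1.0, "pyy": 1.0, "pzz": 1.0}
        )
        est = interfacial_tension(df, Lz=20.0)
        assert est.gamma == 0.0

    def test_constructed_anisotropy_arithmetic(self):
        # pzz - (pxx+pyy)/2 = 0.1, Lz = 20 -> gamma = 1.0
        df = pd.DataFrame(
            {"step": np.arange(50), "pxx": 0.5, "pyy": 0.5, "pzz": 0.6}
        )
        est = interfacial_tension(df, Lz=20.0, start_step=0)
        assert est.gamma == pytest.approx(1.0)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            interfacial_tension(pd.DataFrame(columns=["step", "pxx", "pyy", "pzz"]), 10.0)


class TestChainRg:
    def _traj_from_chains(self, coords, box):
        n_chains, n_beads, _ = coords.shape
        pos = coords.reshape(1, n_chains * n_beads, 3) % box.lengths
        mol = np.repeat(np.arange(n_chains), n_beads)
        return Trajectory(pos, [0], box, ["C"] * (n_chains * n_beads), mol)

    def test_rigid_rod_exact(self):
        # 10 collinear beads, bond 1: Rg^2 = sum (i - 4.5)^2 / 10 = 8.25
        box = Box.rectangular(50.0)
        coords = np.zeros((1, 10, 3))
        coords[0, :, 0] = np.arange(10) + 5.0
        res = chain_rg(self._traj_from_chains(coords, box))
        assert res.rms == pytest.approx(math.sqrt(8.25), rel=1e-12)
        assert res.rms == pytest.approx(2.8723, abs=1e-4)

    def test_coincident_beads_zero(self):
        box = Box.rectangular(20.0)
        coords = np.full((1, 5, 3), 3.0)
        res = chain_rg(self._traj_from_chains(coords, box))
        assert res.rms == 0.0

    def test_fjc_ensemble_matches_closed_form(self):
        box = Box.rectangular(1000.0)
        coords = sample_fjc(10, 1.0, 3000, seed=9) + 500.0
        res = chain_rg(self._traj_from_chains(coords, box))
        assert res.rms**2 == pytest.approx(fjc_rg2_exact(10), rel=0.03)
        assert fjc_rg2_exact(10) == pytest.approx(1.65)

    def test_unwrap_across_periodic_boundary(self):
        box = Box.rectangular(10.0)
        coords = np.zeros((1, 3, 3))
        coords[0, :, 0] = [9.5, 0.3, 1.1]  # chain crossing the x boundary
        res = chain_rg(self._traj_from_chains(coords, box))
        straight = np.zeros((1, 3, 3))
        straight[0, :, 0] = [0.0, 0.8, 1.6]
        ref = chain_rg(self._traj_from_chains(straight, box))
        assert res.rms == pytest.approx(ref.rms, rel=1e-12)

    def test_no_chains_rejected(self):
        box = Box.rectangular(5.0)
        traj = _uniform_traj(box, 10)
        with pytest.raises(ValueError):
            chain_rg(traj)


class TestWeightFraction:
    def test_zero_and_linearity(self):
        prof = _profile_from([0.0, 1e-4, 2e-4], thickness=2.0)
        w1 = to_weight_fraction(prof, 741.5)
        assert w1.densities[0] == 0.0
        w2 = to_weight_fraction(prof, 2 * 741.5)
        np.testing.assert_allclose(w2.densities, 2 * w1.densities)
        assert w1.units == "wt/wt"

    def test_single_molecule_dimensional_analysis(self):
        # 1 molecule of 741.5 Da in a 51.47 x 51.47 x 2 A^3 slice, water 1 kg/L:
        # mass = 741.5/6.022e23 g; water mass = V(A^3)*1e-24 g
        vol = 51.47 * 51.47 * 2.0
        rho_number = 1.0 / vol
        expected = (741.5 / 6.02214076e23) / (vol * 1e-24)
        prof = _profile_from([rho_number], thickness=2.0)
        got = to_weight_fraction(prof, 741.5).densities[0]
        assert got == pytest.approx(expected, rel=1e-9)

    def test_invalid_inputs(self):
        prof = _profile_from([0.1])
        with pytest.raises(ValueError):
            to_weight_fraction(prof, -1.0)


def test_fit_and_slab_count_agree_on_clean_two_phase_profile():
    """A profile with well-separated plateaus fits to (rho_d, rho_b) that
    bracket the default H/L cutoffs, and counts exactly one slab."""
    spec = SyntheticProfileSpec(rho_d=0.75, rho_b=0.03, z0=8.0, w=1.0)
    prof = make_tanh_profile(spec)
    fit = fit_interface(prof)
    assert fit.rho_d > 0.55 > 0.25 > fit.rho_b
    coarse = make_tanh_profile(
        SyntheticProfileSpec(rho_d=0.75, rho_b=0.03, z0=8.0, w=1.0, n_slices=40)
    )
    assert count_slabs(coarse) == 1
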