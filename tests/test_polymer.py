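import numpy as np
import pandas as pd
import pytest

from nucmech import synthgen
from nucmech.polymer import (
    DEFAULT_LEVEL_SCALES,
    EpsilonTrack,
    PolymerSystem,
    ShellSpec,
    bend_energy,
    build_shell,
    chain_diagnostics,
    chip_to_epsilon,
    ellipsoid_surface_distance,
    fene_energy,
    init_system,
    lj_energy,
    run_langevin,
    wca_energy,
)
from nucmech.polymer.forcefield import (
    WCA_CUTOFF,
    FeneOverstretchError,
    ForceField,
    equilibrium_bond_length,
)
from nucmech.polymer.langevin import _build_pairs, _forces, potential_energy, pushoff
from nucmech.polymer.shell import WallSpacingError


class TestEpsilon:
    def test_ratios_and_zeros(self):
        track = chip_to_epsilon(np.array([2.0, 4.0, 0.0]), "E2")
        assert track.eps[1] == pytest.approx(2 * track.eps[0])
        assert track.eps[2] == 0.0
        assert list(track.bound_mask) == [True, True, False]

    def test_constant_signal_uniform_scale(self):
        track = chip_to_epsilon(np.full(10, 3.3), "E3")
        np.testing.assert_allclose(track.eps, DEFAULT_LEVEL_SCALES["E3"])

    def test_e4_is_four_times_e1(self):
        sig = np.array([1.0, 5.0, 0.0, 2.0])
        e1 = chip_to_epsilon(sig, "E1").eps
        e4 = chip_to_epsilon(sig, "E4").eps
        np.testing.assert_allclose(e4, 4.0 * e1)

    def test_negative_signal_error(self):
        with pytest.raises(ValueError, match="nonnegative"):
            chip_to_epsilon(np.array([1.0, -0.5]), "E1")

    def test_dataframe_input(self):
        df = synthgen.gen_chip_track(seed=3)
        track = chip_to_epsilon(df, "E2")
        assert len(track) == 258


class TestShell:
    def test_sphere_radius_oracle(self):
        shell = build_shell("sphere", 258, 0.10)
        target_volume = 258 * (np.pi / 6.0) / 0.10
        r = (3.0 * target_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
        assert shell.a == pytest.approx(r)
        assert shell.a == pytest.approx(6.86, abs=0.01)
        assert shell.c == shell.a

    def test_oblate_same_volume(self):
        sph = build_shell("sphere", 258, 0.10)
        obl = build_shell("oblate_0.5", 258, 0.10)
        assert obl.volume == pytest.approx(sph.volume)
        assert obl.a == pytest.approx(8.64, abs=0.01)
        assert obl.c == pytest.approx(4.32, abs=0.01)
        obl3 = build_shell("oblate_0.33", 258, 0.10)
        assert obl3.c / obl3.a == pytest.approx(1.0 / 3.0)

    def test_achieved_phi(self):
        for shape in ("sphere", "oblate_0.5", "oblate_0.33"):
            shell = build_shell(shape, 258, 0.10)
            assert shell.achieved_phi == pytest.approx(0.10, abs=0.01)

    def test_wall_spacing(self):
        from scipy.spatial import cKDTree

        shell = build_shell("oblate_0.33", 258, 0.10)
        d, _ = cKDTree(shell.wall).query(shell.wall, k=2)
        assert d[:, 1].max() <= 1.0

    def test_wall_on_surface(self):
        shell = build_shell("oblate_0.5", 258, 0.10)
        q = shell.normalized_radius(shell.wall)
        np.testing.assert_allclose(q, 1.0, atol=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="shape"):
            build_shell("cube", 100, 0.1)
        with pytest.raises(ValueError, match="phi"):
            build_shell("sphere", 100, 0.5)
        with pytest.raises(WallSpacingError):
            build_shell("sphere", 258, 0.10, n_wall=10, max_gap=1.0)

    def test_json_roundtrip(self, tmp_path):
        shell = build_shell("oblate_0.33", 64, 0.1)
        back = ShellSpec.from_json(shell.to_json(tmp_path / "s.json"))
        assert back.shape == shell.shape
        assert back.a == pytest.approx(shell.a)
        np.testing.assert_allclose(back.wall, shell.wall)


class TestSurfaceDistance:
    def test_sphere_inside_outside(self):
        for r, expect in ((0.0, 5.0), (2.0, 3.0), (8.0, 3.0)):
            d = ellipsoid_surface_distance((r, 0.0, 0.0), 5.0, 5.0)
            assert d == pytest.approx(expect, abs=1e-6)

    def test_oblate_center_is_pole_distance(self):
        assert ellipsoid_surface_distance((0, 0, 0), 9.0, 3.0) == pytest.approx(3.0, abs=1e-6)

    def test_brute_force_oracle(self):
        # dense parametric surface sampling as an independent oracle
        a, c = 7.0, 2.5
        u = np.linspace(0, 2 * np.pi, 600)
        v = np.linspace(-np.pi / 2, np.pi / 2, 600)
        uu, vv = np.meshgrid(u, v)
        surf = np.stack(
            [a * np.cos(vv) * np.cos(uu), a * np.cos(vv) * np.sin(uu), c * np.sin(vv)],
            axis=-1,
        ).reshape(-1, 3)
        rng = np.random.default_rng(0)
        for _ in range(6):
            p = rng.uniform(-1, 1, 3) * [a, a, c]
            brute = np.min(np.linalg.norm(surf - p, axis=1))
            assert ellipsoid_surface_distance(p, a, c) == pytest.approx(brute, abs=5e-3)


class TestForceField:
    def test_fene_at_unit_length(self):
        # direct evaluation: -0.5*30*1.5^2 * ln(1 - (1/1.5)^2)
        expect = -0.5 * 30.0 * 1.5**2 * np.log(1.0 - (1.0 / 1.5) ** 2)
        assert fene_energy(1.0) == pytest.approx(expect)
        assert fene_energy(1.0) == pytest.approx(19.84, abs=0.005)

    def test_fene_overstretch(self):
        with pytest.raises(FeneOverstretchError):
            fene_energy(1.5)

    def test_bend_identities(self):
        assert bend_energy(0.0) == 0.0
        assert bend_energy(np.pi / 2, 1.0) == pytest.approx(1.0)
        assert bend_energy(np.pi, 2.0) == pytest.approx(4.0)

    def test_lj_identities(self):
        assert lj_energy(1.0, 1.5) == pytest.approx(0.0)
        rmin = 2.0 ** (1.0 / 6.0)
        assert lj_energy(rmin, 1.5) == pytest.approx(-1.5)
        assert lj_energy(3.0, 1.5) == 0.0  # beyond cutoff

    def test_wca_cut_and_shift(self):
        assert wca_energy(WCA_CUTOFF + 1e-9) == 0.0
        assert wca_energy(WCA_CUTOFF - 1e-9) == pytest.approx(0.0, abs=1e-6)
        assert wca_energy(0.9) > 0.0

    def test_equilibrium_bond_length(self):
        assert equilibrium_bond_length() == pytest.approx(0.97, abs=0.01)


class TestInitSystem:
    def test_growth_constraints(self):
        shell = build_shell("sphere", 64, 0.10)
        system = init_system([32, 32], np.zeros(64), shell, seed=4)
        bonds = system.bonds
        d = np.linalg.norm(
            system.positions[bonds[:, 0]] - system.positions[bonds[:, 1]], axis=1
        )
        assert np.all((d > 0.8) & (d < 1.2))
        assert np.all(shell.normalized_radius(system.positions) < 1.0)
        assert len(bonds) == 62  # no bond across the chain boundary

    def test_deterministic(self):
        shell = build_shell("sphere", 30, 0.10)
        a = init_system([30], np.zeros(30), shell, seed=9)
        b = init_system([30], np.zeros(30), shell, seed=9)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_eps_length_mismatch(self):
        with pytest.raises(ValueError, match="eps"):
            init_system([10], np.zeros(8), None, seed=0)

    def test_bond_audit_after_pushoff(self):
        shell = build_shell("sphere", 64, 0.10)
        system = init_system([64], np.ones(64), shell, seed=1)
        pushoff(system, n_steps=1500)
        bonds = system.bonds
        d = np.linalg.norm(
            system.positions[bonds[:, 0]] - system.positions[bonds[:, 1]], axis=1
        )
        assert np.all((d > 0.8) & (d < 1.2))


class TestDynamics:
    def test_forces_match_energy_gradient(self):
        # dual route: njit kernel forces vs central differences of the exact
        # all-pairs NumPy potential
        system = init_system(
            [5, 5], np.array([0, 1, 0, 2, 0, 0, 1.5, 0, 1, 0], float), None, seed=7
        )
        pos = system.positions.copy()
        f = system.forcefield
        pm = np.zeros((2000, 2), dtype=np.int64)
        pw = np.zeros((10, 2), dtype=np.int64)
        wall = np.zeros((0, 3))
        n_mm, n_mw = _build_pairs(pos, wall, 100.0, pm, pw)
        force = np.zeros_like(pos)
        _forces(pos, wall, system.bonds, system.angles, system.chain_id,
                system.eps, pm, n_mm, pw, n_mw, f.fene_k, f.fene_r0, f.bend_k,
                f.lj_cutoff, 0.0, 1, f.wall_eps, force)
        h = 1e-6
        for i in range(len(pos)):
            for d in range(3):
                p1, p2 = pos.copy(), pos.copy()
                p1[i, d] += h
                p2[i, d] -= h
                num = -(potential_energy(system, p1) - potential_energy(system, p2)) / (2 * h)
                assert force[i, d] == pytest.approx(num, abs=1e-5)

    def test_seed_determinism(self):
        def run():
            system = init_system([20], np.zeros(20), None, seed=3)
            return run_langevin(system, 500, sample_every=100, seed=11)

        a, b = run(), run()
        for fa, fb in zip(a.frames, b.frames):
            np.testing.assert_array_equal(fa, fb)

    def test_mean_bond_length(self):
        system = init_system([60], np.zeros(60), None, seed=2)
        traj = run_langevin(system, 30_000, sample_every=1_000, seed=5)
        diag = chain_diagnostics(traj, discard_fraction=0.3)
        assert diag["mean_bond"] == pytest.approx(equilibrium_bond_length(), abs=0.02)

    def test_phantom_chain_angle_statistics(self):
        # Boltzmann oracle for U = k(1 - cos t): <cos> = coth(k) - 1/k
        ff = ForceField(excluded_volume=False)
        system = init_system([100], np.zeros(100), None, seed=1, forcefield=ff)
        traj = run_langevin(system, 120_000, sample_every=4_000, seed=3)
        diag = chain_diagnostics(traj, discard_fraction=0.3)
        expect = 1.0 / np.tanh(1.0) - 1.0
        assert diag["mean_cos_theta"] == pytest.approx(expect, abs=0.03)
        assert diag["kuhn_length"] == pytest.approx(2.0, rel=0.10)

    def test_zero_bend_constant_freely_jointed(self):
        ff = ForceField(bend_k=0.0, excluded_volume=False)
        system = init_system([80], np.zeros(80), None, seed=6, forcefield=ff)
        traj = run_langevin(system, 60_000, sample_every=3_000, seed=8)
        diag = chain_diagnostics(traj, discard_fraction=0.3)
        assert diag["mean_cos_theta"] == pytest.approx(0.0, abs=0.04)
        assert diag["kuhn_length"] == pytest.approx(diag["mean_bond"], rel=0.1)

    def test_confinement_holds(self):
        shell = build_shell("oblate_0.5", 64, 0.10)
        system = init_system([64], np.zeros(64), shell, seed=4)
        pushoff(system)
        traj = run_langevin(system, 20_000, sample_every=1_000, seed=9)
        assert traj.energies["max_norm_radius"].max() < 1.0
        for pos in traj.frames:
            assert np.all(shell.normalized_radius(pos) < 1.0)

    def test_attraction_monotonicity(self):
        # at stronger attraction the largest bound-monomer cluster grows
        from scipy.cluster.hierarchy import fcluster, linkage

        def largest_cluster(level):
            sizes = []
            for seed in (0, 1):
                sig = synthgen.gen_chip_track({"a": 40}, seed=40 + seed)
                eps = chip_to_epsilon(sig, level)
                shell = build_shell("sphere", 40, 0.10)
                system = init_system([40], eps, shell, seed=seed)
                pushoff(system)
                traj = run_langevin(system, 30_000, sample_every=30_000,
                                    seed=100 + seed)
                bound = traj.frames[-1][eps.bound_mask]
                if len(bound) < 2:
                    sizes.append(len(bound))
                    continue
                lab = fcluster(linkage(bound, "single"), t=1.3, criterion="distance")
                sizes.append(np.bincount(lab).max())
            return np.mean(sizes)

        assert largest_cluster("E4") >= largest_cluster("E1")

    def test_diagnostics_need_frames(self):
        system = init_system([20], np.zeros(20), None, seed=3)
        traj = run_langevin(system, 500, sample_every=500, seed=1)
        with pytest.raises(ValueError, match="frames"):
            chain_diagnostics(traj)
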