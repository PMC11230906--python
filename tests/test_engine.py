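"""Engine validation: potential forms, force/energy consistency, integrator,
thermostat, pressure tensor, reproducibility."""

import numpy as np
import pytest

from kemix import _kernels
from kemix.engine import EngineInstability, Simulator, Trajectory, pair_energy
from kemix.forcefield import (KB, ForceFieldParams, default_forcefield,
                              desk_forcefield)
from kemix.sequences import ChargeSequence
from kemix.topology import BoxedConfiguration, SystemTopology, build_linear
from conftest import random_neutral


def free_beads_topology(n, bead="K"):
    return SystemTopology(
        bead_types=np.array([bead] * n),
        charges=np.zeros(n) if bead == "CORE" else np.full(
            n, 1.0 if bead == "K" else -1.0),
        bonds=np.empty((0, 2), dtype=np.int64),
        molecule_id=np.arange(n),
        species=np.array(["p"] * n),
        valence=np.ones(n, dtype=int),
    )


def random_config(n, edge, rng, spacing=6.0):
    """Random positions with a minimum spacing (grid + jitter)."""
    per = int(np.ceil(n ** (1 / 3)))
    grid = edge / per
    assert grid > spacing
    idx = np.stack(np.meshgrid(*[np.arange(per)] * 3), -1).reshape(-1, 3)
    pos = (idx[:n] + 0.5) * grid + rng.uniform(-1.0, 1.0, (n, 3))
    return BoxedConfiguration(pos, np.array([edge] * 3, dtype=float))


class TestPairEnergy:
    def test_continuity_at_switch_and_cutoffs(self):
        ff = default_forcefield()
        for ti in range(3):
            for tj in range(3):
                sij = ff.sigma_pair[ti, tj]
                rmin = 2 ** (1 / 6) * sij
                a = pair_energy(ff, ti, tj, rmin - 1e-9)
                b = pair_energy(ff, ti, tj, rmin + 1e-9)
                assert a == pytest.approx(b, abs=1e-6)
                assert pair_energy(ff, ti, tj, ff.rc_elec + 1) == 0.0
                # shifted: value just inside the outermost cutoff is ~0
                assert abs(pair_energy(ff, ti, tj, ff.rc_elec - 1e-6)) < 1e-6

    def test_minimum_value_with_lambda(self):
        # at r = 2^{1/6}σ the AH well depth is -λε (plus shift and DH terms)
        ff = ForceFieldParams(charge=np.zeros(3))  # switch off electrostatics
        for ti, tj in [(0, 0), (0, 1), (1, 1)]:
            sij = ff.sigma_pair[ti, tj]
            lij = ff.lambda_pair[ti, tj]
            shift = float(ff.lj_energy(sij, np.array(ff.rc_pair)))
            expected = -lij * ff.epsilon - lij * shift
            got = pair_energy(ff, ti, tj, 2 ** (1 / 6) * sij)
            assert got == pytest.approx(expected, rel=1e-10)

    def test_lambda_one_is_pure_shifted_lj(self):
        ff = ForceFieldParams(lam=np.ones(3), charge=np.zeros(3))
        sij = ff.sigma_pair[0, 0]
        shift = float(ff.lj_energy(sij, np.array(ff.rc_pair)))
        for r in (0.9 * sij, sij, 1.5 * sij, 2.5 * sij):
            ulj = float(ff.lj_energy(sij, np.array(r)))
            assert pair_energy(ff, 0, 0, r) == pytest.approx(
                ulj - shift, rel=1e-9, abs=1e-12)

    def test_neutral_pair_has_no_electrostatics(self):
        ff = default_forcefield()
        r = 12.0
        with_q = pair_energy(ff, 2, 2, r)       # CORE-CORE, q = 0
        ff2 = ForceFieldParams(charge=np.zeros(3))
        assert with_q == pytest.approx(pair_energy(ff2, 2, 2, r), abs=1e-12)

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            pair_energy(default_forcefield(), 0, 0, 0.0)


class TestForces:
    def test_harmonic_dimer_at_rest_length_has_zero_force(self):
        seq = ChargeSequence("KE")
        top = build_linear(seq)
        ff = default_forcefield()
        pos = np.array([[50.0, 50.0, 50.0], [50.0, 50.0, 53.8]])
        sim = Simulator(top, BoxedConfiguration(pos, np.array([100.] * 3)),
                        ff, seed=0)
        forces, _, _ = sim.forces_energy_virial()
        # bond at rest length: only the K-E non-bonded terms are excluded,
        # so the full force reduces to zero
        assert np.allclose(forces, 0.0, atol=1e-10)

    def test_forces_match_numerical_gradient(self, rng):
        # mixed K/E chains in a periodic box; central finite differences
        seqs = [random_neutral(10, rng) for _ in range(5)]
        from kemix.topology import concat_topologies

        tops = [build_linear(s) for s in seqs]
        top = concat_topologies(tops)
        cfg = random_config(top.n_beads, 60.0, rng)
        sim = Simulator(top, cfg, desk_forcefield(), seed=1)
        forces, e0, _ = sim.forces_energy_virial()

        def energy():
            sim._npairs = -1
            return sim.forces_energy_virial()[1]

        h = 1e-5
        scale = max(1.0, np.abs(forces).max())
        for bead in rng.choice(top.n_beads, size=6, replace=False):
            for ax in range(3):
                orig = sim.pos[bead, ax]
                sim.pos[bead, ax] = orig + h
                ep = energy()
                sim.pos[bead, ax] = orig - h
                em = energy()
                sim.pos[bead, ax] = orig
                num = -(ep - em) / (2 * h)
                assert num == pytest.approx(forces[bead, ax],
                                            abs=2e-5 * scale)

    def test_newtons_third_law_total_force_zero(self, rng):
        top = free_beads_topology(64)
        cfg = random_config(64, 50.0, rng)
        sim = Simulator(top, cfg, desk_forcefield(), seed=2)
        forces, _, _ = sim.forces_energy_virial()
        assert np.allclose(forces.sum(axis=0), 0.0, atol=1e-9)

    def test_pair_list_matches_cell_list_reference(self, rng):
        """The production (Verlet-list) pair sum equals the independent
        cell-list/brute-force kernel."""
        from kemix.topology import concat_topologies

        seqs = [random_neutral(12, rng) for _ in range(8)]
        top = concat_topologies([build_linear(s) for s in seqs])
        cfg = random_config(top.n_beads, 60.0, rng)
        ff = desk_forcefield()
        sim = Simulator(top, cfg, ff, seed=3)
        f1 = np.zeros((sim.n, 3))
        sim._refresh_pairs()
        e1 = _kernels.pair_forces(sim.pos, sim.box, sim._pi, sim._pj,
                                  sim._npairs, sim.types, *sim._tab, f1)
        f2 = np.zeros((sim.n, 3))
        e2 = _kernels.nonbonded(sim.pos, sim.box, sim.types, sim.excl,
                                sim.n_excl, *sim._tab, f2)
        assert e1[0] == pytest.approx(e2[0], rel=1e-12, abs=1e-12)
        assert np.allclose(f1, f2, atol=1e-10)
        for a, b in zip(e1[1:], e2[1:]):
            assert a == pytest.approx(b, rel=1e-10, abs=1e-10)


class TestIntegrator:
    def test_nve_energy_conservation_bonded_dimer(self):
        seq = ChargeSequence("KE")
        top = build_linear(seq)
        pos = np.array([[20.0, 20.0, 20.0], [20.0, 20.0, 24.1]])
        sim = Simulator(top, BoxedConfiguration(pos, np.array([40.0] * 3)),
                        default_forcefield(), friction_ps=0.0, dt_fs=2.0,
                        temperature=250.0, seed=4)
        e0 = sim.kinetic_energy + sim._epot
        drift = 0.0
        for _ in range(10):
            sim.step(1000)
            drift = max(drift, abs(sim.kinetic_energy + sim._epot - e0))
        assert drift / abs(e0) < 1e-4

    def test_momentum_conserved_without_thermostat(self, rng):
        top = free_beads_topology(50)
        cfg = random_config(50, 60.0, rng)
        sim = Simulator(top, cfg, desk_forcefield(), friction_ps=0.0, seed=5)
        p0 = (sim.masses[:, None] * sim.vel).sum(axis=0)
        sim.step(500)
        p1 = (sim.masses[:, None] * sim.vel).sum(axis=0)
        assert np.allclose(p0, p1, atol=1e-8)

    def test_trajectory_reproducible_from_seed(self, rng):
        top = free_beads_topology(30)
        cfg = random_config(30, 60.0, rng)
        runs = []
        for _ in range(2):
            sim = Simulator(top, cfg, desk_forcefield(), friction_ps=1.0,
                            seed=42)
            sim.step(200)
            runs.append(sim.pos.copy())
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_thermostat_reaches_setpoint_free_particles(self):
        top = free_beads_topology(200)
        rng = np.random.default_rng(0)
        cfg = random_config(200, 100.0, rng)
        sim = Simulator(top, cfg, interactions="none", friction_ps=1.0,
                        temperature=250.0, seed=6)
        temps = []
        for _ in range(40):
            sim.step(50)
            temps.append(sim.kinetic_temperature)
        assert np.mean(temps[10:]) == pytest.approx(250.0, rel=0.02)

    def test_ideal_gas_pressure(self):
        top = free_beads_topology(200)
        rng = np.random.default_rng(1)
        cfg = random_config(200, 100.0, rng)
        sim = Simulator(top, cfg, interactions="none", friction_ps=1.0,
                        temperature=250.0, seed=7)
        sim.step(500)
        ps = []
        for _ in range(60):
            sim.step(50)
            st = sim.frame_stats()
            ps.append([st.pxx, st.pyy, st.pzz])
        mean_p = np.mean(ps)
        expected = 200 * KB * 250.0 / 100.0 ** 3
        assert mean_p == pytest.approx(expected, rel=0.05)

    def test_instability_aborts_with_partial_output(self, rng):
        top = free_beads_topology(20)
        cfg = random_config(20, 60.0, rng)
        sim = Simulator(top, cfg, desk_forcefield(), friction_ps=0.0, seed=8)
        sim.vel *= 100.0  # kinetic temperature far above the setpoint
        with pytest.raises(EngineInstability) as err:
            sim.run(1000, report_interval=100)
        assert err.value.trajectory is not None
        assert err.value.trajectory.n_frames >= 1


class TestRunAndIO:
    def test_run_coexistence_requires_slab_and_logs_metadata(self, rng):
        from kemix.engine import run_coexistence
        from kemix.topology import BoxedConfiguration

        top = free_beads_topology(20)
        cube = random_config(20, 60.0, rng)
        with pytest.raises(ValueError, match="slab"):
            run_coexistence(cube, top, protocol={"production_steps": 10})
        slab_pos = cube.positions.copy()
        slab = BoxedConfiguration(slab_pos, np.array([60.0, 60.0, 200.0]))
        traj = run_coexistence(
            slab, top, protocol={"equilibration_steps": 50,
                                 "production_steps": 100,
                                 "report_interval": 50},
            seed=5, friction_ps=1.0)
        assert traj.n_frames == 3  # initial + 2 reports
        assert traj.metadata["seed"] == 5
        assert traj.metadata["protocol"]["production_steps"] == 100

    def test_zero_production_steps_yields_initial_frame_only(self, rng):
        top = free_beads_topology(10)
        cfg = random_config(10, 60.0, rng)
        sim = Simulator(top, cfg, desk_forcefield(), seed=9)
        traj = sim.run(0)
        assert traj.n_frames == 1
        assert len(traj.stats) == 1

    def test_bead_count_constant_and_h5_roundtrip(self, tmp_path, rng):
        seq = ChargeSequence("KEKE")
        top = build_linear(seq)
        pos = np.array([[25.0, 25.0, 20.0 + 3.8 * i] for i in range(4)])
        cfg = BoxedConfiguration(pos, np.array([50.0] * 3))
        sim = Simulator(top, cfg, desk_forcefield(), seed=10)
        traj = sim.run(200, report_interval=50)
        assert traj.positions.shape[1] == 4
        path = tmp_path / "run.h5"
        traj.save(path)
        back = Trajectory.load(path)
        assert back.n_frames == traj.n_frames
        np.testing.assert_allclose(back.positions, traj.positions, atol=1e-4)
        assert list(back.topology.bead_types) == list(top.bead_types)
        assert back.stats["temperature"].equals(traj.stats["temperature"])
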