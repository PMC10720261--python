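"""Langevin/NVE integrator contracts: limits, conservation, thermostatting,
rigid-body propagation."""

import numpy as np
import pytest

from hpslab.analysis import msd_diffusion
from hpslab.dynamics import (
    IntegrationError,
    SimulationConfig,
    init_state,
    kinetic_temperature,
    langevin_step,
    run_simulation,
)
from hpslab.params import KB
from hpslab.potentials import PairInteractionParams, total_energy_forces
from hpslab.sysbuild import initial_single_chain, relax
from hpslab.synthetic import compact_globule_calpha
from hpslab.topology import RigidGroup, build_topology
from hpslab.trajectory import Configuration

BIG_BOX = (100.0, 100.0, 100.0)


def _free_bead_topology(toy_table, n=1):
    # single isolated beads, no bonds, purely repulsive so rare encounters
    # in a huge box are irrelevant
    t = toy_table.with_overrides({"X": {"hydropathy": 0.0}})
    return build_topology(["X"] * n, t)


class TestLimits:
    def test_ballistic_limit(self, toy_table):
        """Zero forces and no thermostat: straight-line motion x = x0 + v t."""
        topo = _free_bead_topology(toy_table)
        cfg = SimulationConfig(ensemble="NVE", dt=0.01, n_steps=1000,
                               save_interval=1000, box=BIG_BOX, seed=0)
        conf = Configuration(np.array([[50.0, 50.0, 50.0]]), np.array(BIG_BOX))
        v0 = np.array([[0.3, -0.1, 0.05]])
        state = init_state(topo, conf, cfg, velocities=v0)
        langevin_step(state, topo, config=cfg, n_steps=1000)
        expected = conf.positions + v0 * 1000 * cfg.dt
        np.testing.assert_allclose(state.positions, expected, atol=1e-10)
        np.testing.assert_allclose(state.velocities, v0, atol=1e-14)

    def test_harmonic_bond_boltzmann_variance(self, toy_table):
        """A stiff harmonic bond samples length variance kB T / k."""
        topo = build_topology("XX", toy_table)
        cfg = SimulationConfig(temperature=310.0, dt=0.01, tau_damp=1.0,
                               n_steps=1_000_000, save_interval=20,
                               box=BIG_BOX, seed=42)
        conf = Configuration(
            np.array([[50.0, 50.0, 50.0], [50.0, 50.0, 50.0 + topo.bond_r0]]),
            np.array(BIG_BOX),
        )
        traj = run_simulation(topo, conf, cfg)
        bl = np.linalg.norm(traj.positions[:, 1] - traj.positions[:, 0], axis=1)
        bl = bl[len(bl) // 5:]
        expected = KB * 310.0 / topo.bond_k
        assert bl.var() == pytest.approx(expected, rel=0.03)

    def test_instability_diagnostic(self, toy_table):
        topo = _free_bead_topology(toy_table)
        cfg = SimulationConfig(ensemble="NVE", dt=0.01, n_steps=10,
                               save_interval=10, box=BIG_BOX, seed=0)
        conf = Configuration(np.array([[50.0, 50.0, 50.0]]), np.array(BIG_BOX))
        state = init_state(topo, conf, cfg, velocities=np.array([[80.0, 0.0, 0.0]]))
        with pytest.raises(IntegrationError, match="step"):
            langevin_step(state, topo, config=cfg, n_steps=10)


class TestRigidBodies:
    def _tetra_plus_chain(self, toy_table):
        tetra = np.array(
            [[0.0, 0.0, 0.0], [0.6, 0.0, 0.0], [0.3, 0.52, 0.0], [0.3, 0.17, 0.49]]
        )
        grp = RigidGroup(chain=0, start=1, stop=4, reference=tetra)
        return build_topology(["XXXX", "X" * 10], toy_table, rigid_defs=[grp])

    def test_rigid_internal_distances_preserved(self, toy_table):
        """All six internal distances of a rigid tetrahedron stay at their
        reference values while a flexible chain batters it."""
        topo = self._tetra_plus_chain(toy_table)
        box = (6.0, 6.0, 6.0)
        conf = relax(initial_single_chain(topo, box, seed=3), topo, n_sweeps=100)
        cfg = SimulationConfig(temperature=600.0, dt=0.01, tau_damp=5.0,
                               n_steps=100_000, save_interval=10_000,
                               box=box, seed=7)
        traj = run_simulation(topo, conf, cfg)
        ref = topo.rigid_groups[0].reference
        want = {
            (i, j): np.linalg.norm(ref[i] - ref[j])
            for i in range(4) for j in range(i + 1, 4)
        }
        for frame in traj.positions:
            for (i, j), d0 in want.items():
                assert np.linalg.norm(frame[i] - frame[j]) == pytest.approx(d0, abs=1e-6)

    def test_isolated_rigid_group_conserves_momentum_nve(self, toy_table):
        """Free rigid body in NVE: COM velocity and angular momentum
        magnitude are constants of motion."""
        tetra = np.array(
            [[0.0, 0.0, 0.0], [0.6, 0.0, 0.0], [0.3, 0.52, 0.0], [0.3, 0.17, 0.49]]
        )
        grp = RigidGroup(chain=0, start=1, stop=4, reference=tetra)
        topo = build_topology("XXXX", toy_table, rigid_defs=[grp])
        cfg = SimulationConfig(ensemble="NVE", temperature=310.0, dt=0.01,
                               n_steps=10_000, save_interval=10_000,
                               box=BIG_BOX, seed=11)
        conf = Configuration(tetra + 50.0, np.array(BIG_BOX))
        state = init_state(topo, conf, cfg)
        v0 = state.vcom.copy()
        l0 = np.linalg.norm(state.lbody[0])
        com0 = state.com.copy()
        langevin_step(state, topo, config=cfg, n_steps=10_000)
        np.testing.assert_allclose(state.vcom, v0, atol=1e-12)
        assert np.linalg.norm(state.lbody[0]) == pytest.approx(l0, rel=1e-10)
        np.testing.assert_allclose(
            state.com, com0 + v0 * 10_000 * cfg.dt, atol=1e-9
        )

    def test_equipartition_flexible_and_rigid_dof(self, toy_table):
        """Time-averaged kinetic temperature of flexible beads and of
        rigid-body translational+rotational DOF separately match the target."""
        grp = RigidGroup(
            chain=0, start=5, stop=14, reference=compact_globule_calpha(10, seed=2)
        )
        topo = build_topology("X" * 30, toy_table, rigid_defs=[grp])
        box = (15.0, 15.0, 15.0)
        conf = relax(initial_single_chain(topo, box, seed=5), topo, n_sweeps=150)
        cfg = SimulationConfig(temperature=310.0, dt=0.01, tau_damp=2.0,
                               n_steps=1000, save_interval=1000, box=box, seed=9)
        state = init_state(topo, conf, cfg)
        from hpslab.dynamics import _rigid_arrays

        ra = _rigid_arrays(topo)
        flex = topo.rigid_of_bead < 0
        ke_f = []
        ke_r = []
        n_chunks = 250
        for _ in range(n_chunks):
            langevin_step(state, topo, config=cfg, n_steps=1000)
            ke_f.append(0.5 * (topo.masses[flex, None] * state.velocities[flex] ** 2).sum())
            ke_r.append(
                0.5 * (ra.mass[:, None] * state.vcom**2).sum()
                + 0.5 * (state.lbody**2 / ra.inertia).sum()
            )
        burn = n_chunks // 5
        t_flex = 2 * np.mean(ke_f[burn:]) / (3 * flex.sum() * KB)
        t_rigid = 2 * np.mean(ke_r[burn:]) / (6 * KB)
        assert t_flex == pytest.approx(310.0, rel=0.03)
        assert t_rigid == pytest.approx(310.0, rel=0.03)


class TestRunSimulation:
    def _chain50(self, toy_table):
        t = toy_table.with_overrides({"X": {"hydropathy": 0.6}})
        return build_topology("X" * 50, t)

    def test_nve_energy_drift(self, toy_table):
        """Total energy conserved to a relative drift < 1e-3 (dt = 2 fs)."""
        topo = self._chain50(toy_table)
        box = (15.0, 15.0, 15.0)
        conf = relax(initial_single_chain(topo, box, seed=2), topo, n_sweeps=300)
        # equilibrate briefly so the start is not strained
        cfg_eq = SimulationConfig(temperature=310.0, dt=0.005, tau_damp=5.0,
                                  n_steps=20_000, save_interval=20_000, box=box, seed=4)
        state = init_state(topo, conf, cfg_eq)
        langevin_step(state, topo, config=cfg_eq, n_steps=20_000)

        cfg = SimulationConfig(ensemble="NVE", dt=0.002, n_steps=20_000,
                               save_interval=1000, box=box, seed=4)
        def total_energy(s):
            e, _ = total_energy_forces(s.positions, s.box, topo)
            return e + 0.5 * (topo.masses[:, None] * s.velocities**2).sum()

        e0 = total_energy(state)
        langevin_step(state, topo, config=cfg, n_steps=20_000)
        assert abs(total_energy(state) - e0) < 1e-3 * abs(e0)

    def test_kinetic_temperature_tracks_target(self, toy_table):
        topo = self._chain50(toy_table)
        box = (15.0, 15.0, 15.0)
        conf = relax(initial_single_chain(topo, box, seed=2), topo, n_sweeps=300)
        cfg = SimulationConfig(temperature=310.0, dt=0.01, tau_damp=5.0,
                               n_steps=100_000, save_interval=500, box=box, seed=8)
        traj = run_simulation(topo, conf, cfg)
        t_mean = traj.kinetic_temperature[40:].mean()
        assert t_mean == pytest.approx(310.0, rel=0.02)

    def test_same_seed_reproduces_trajectory(self, toy_table):
        topo = self._chain50(toy_table)
        box = (15.0, 15.0, 15.0)
        conf = relax(initial_single_chain(topo, box, seed=2), topo, n_sweeps=100)
        cfg = SimulationConfig(temperature=310.0, dt=0.01, tau_damp=10.0,
                               n_steps=5_000, save_interval=500, box=box, seed=123)
        t1 = run_simulation(topo, conf, cfg)
        t2 = run_simulation(topo, conf, cfg)
        np.testing.assert_array_equal(t1.positions, t2.positions)
        np.testing.assert_array_equal(t1.potential_energy, t2.potential_energy)

    def test_fluctuation_dissipation_free_diffusion(self, toy_table):
        """Free-bead diffusion D = kB T tau / m within 10% — the integrated
        form of the velocity-autocorrelation decay-time check."""
        topo = _free_bead_topology(toy_table, n=16)
        cfg = SimulationConfig(temperature=310.0, dt=0.01, tau_damp=5.0,
                               n_steps=1_000_000, save_interval=1000,
                               box=(400.0, 400.0, 400.0), seed=21)
        pos = np.tile(np.arange(16)[:, None] * 25.0, (1, 3)) + 10.0
        traj = run_simulation(topo, Configuration(pos, np.array([400.0] * 3)), cfg)
        res = msd_diffusion(traj, topo, fit_window=(100.0, 2000.0))
        d_expected = KB * 310.0 * 5.0 / 110.0
        assert res.D == pytest.approx(d_expected, rel=0.10)
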