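"""Observable calculations: Rg, density/coexistence, contacts, diffusion."""

import numpy as np
import pytest

from hpslab.analysis import (
    AMU_PER_NM3_TO_MG_PER_ML,
    ContactMap,
    DensityProfile,
    coexistence_densities,
    contact_map,
    density_profile,
    msd_diffusion,
    per_residue_contacts,
    radius_of_gyration,
    unwrap_chains,
)
from hpslab.synthetic import make_reference_trajectory, make_step_profile
from hpslab.topology import build_topology
from hpslab.trajectory import Trajectory


def _bare_traj(pos, box, dt=1.0):
    f = len(pos)
    return Trajectory(
        positions=np.asarray(pos, float), box=np.asarray(box, float),
        steps=np.arange(f), time=np.arange(f) * dt,
        potential_energy=np.zeros(f), kinetic_temperature=np.zeros(f),
        rg_mean=np.zeros(f),
    )


class TestRadiusOfGyration:
    def test_coincident_beads(self):
        assert radius_of_gyration(np.zeros((5, 3))) == 0.0

    def test_two_equal_masses(self):
        pos = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.4]])
        assert radius_of_gyration(pos) == pytest.approx(0.7)

    def test_matches_direct_summation(self, rng):
        pos = rng.uniform(-3, 3, (100, 3))
        m = rng.uniform(50, 200, 100)
        com = (m[:, None] * pos).sum(0) / m.sum()
        want = np.sqrt((m * ((pos - com) ** 2).sum(1)).sum() / m.sum())
        assert radius_of_gyration(pos, m) == pytest.approx(want, rel=1e-12)

    def test_ring_reference_trajectory(self):
        ref = make_reference_trajectory("known_rg", {"radius": 2.0, "n": 24})
        got = radius_of_gyration(ref.trajectory.positions[0])
        assert got == pytest.approx(2.0, rel=1e-12)

    def test_empty_selection_fatal(self):
        with pytest.raises(ValueError, match="empty"):
            radius_of_gyration(np.zeros((5, 3)), selection=np.array([], dtype=int))

    def test_unwrap_across_boundary(self):
        """A straight chain straddling the boundary: wrapped coordinates give
        the wrong Rg, unwrapping recovers the hand-computed value."""
        box = np.array([10.0, 10.0, 10.0])
        # 5 beads along z at 9.2, 9.6, 10.0, 10.4, 10.8 -> wrapped jumps
        z = np.array([9.2, 9.6, 10.0, 10.4, 10.8])
        pos = np.column_stack([np.full(5, 5.0), np.full(5, 5.0), z])
        wrapped = np.mod(pos, box)
        chain_id = np.zeros(5, dtype=int)
        # straight line of 5 equally spaced beads, spacing 0.4:
        # Rg = sqrt(mean([0.8^2,0.4^2,0,0.4^2,0.8^2])) = 0.4*sqrt(2)
        want = 0.4 * np.sqrt(2.0)
        assert radius_of_gyration(wrapped) != pytest.approx(want, rel=0.01)
        unwrapped = unwrap_chains(wrapped, box, chain_id)
        assert radius_of_gyration(unwrapped) == pytest.approx(want, rel=1e-9)


class TestDensityProfile:
    def _topo(self, toy_table, n_chains, length):
        return build_topology(["X" * length] * n_chains, toy_table)

    def test_uniform_gas_flat_and_mass_conserving(self, toy_table, rng):
        topo = self._topo(toy_table, 40, 1)
        box = np.array([5.0, 5.0, 50.0])
        pos = rng.uniform(0, 1, (30, 40, 3)) * box
        traj = _bare_traj(pos, box)
        prof = density_profile(traj, topo, bin_width=5.0, centering="none")
        counts = prof.frame_mass / 110.0
        # per-frame mass conservation: counts sum to N in every frame
        np.testing.assert_allclose(counts.sum(axis=1), 40.0)
        # flat within Poisson noise: expected 4 beads/bin/frame over 30 frames
        mean_per_bin = counts.mean(axis=0)
        expect = 4.0
        tol = 4.0 * np.sqrt(expect / 30)
        assert np.all(np.abs(mean_per_bin - expect) < tol)

    def test_central_slab_zero_outside(self, toy_table, rng):
        topo = self._topo(toy_table, 100, 1)
        box = np.array([5.0, 5.0, 60.0])
        pos = rng.uniform(0, 1, (5, 100, 3)) * np.array([5.0, 5.0, 10.0])
        pos[:, :, 2] += 25.0  # central 10 nm in z
        traj = _bare_traj(pos, box)
        prof = density_profile(traj, topo, bin_width=1.0, centering="com")
        outside = np.abs(prof.bin_centers) > 10.0
        assert np.all(prof.concentration[outside] == 0.0)
        inside = np.abs(prof.bin_centers) <= 5.0
        assert np.all(prof.concentration[inside] > 0)

    def test_hand_built_histogram(self, toy_table):
        topo = self._topo(toy_table, 4, 1)
        box = np.array([2.0, 2.0, 8.0])
        # frame 1: beads at z = 0.5, 1.5, 4.5, 6.5 ; frame 2: all at z=2.5
        f1 = np.column_stack([np.ones(4), np.ones(4), [0.5, 1.5, 4.5, 6.5]])
        f2 = np.column_stack([np.ones(4), np.ones(4), [2.5] * 4])
        traj = _bare_traj(np.stack([f1, f2]), box)
        prof = density_profile(traj, topo, bin_width=1.0, centering="none")
        # bins are centered at -3.5..3.5 relative to the box center z=4
        want_f1 = np.array([1, 1, 0, 0, 1, 0, 1, 0]) * 110.0
        want_f2 = np.array([0, 0, 4, 0, 0, 0, 0, 0]) * 110.0
        np.testing.assert_allclose(prof.frame_mass[0], want_f1)
        np.testing.assert_allclose(prof.frame_mass[1], want_f2)
        binvol = 2.0 * 2.0 * 1.0
        np.testing.assert_allclose(
            prof.concentration,
            (want_f1 + want_f2) / 2 / binvol * AMU_PER_NM3_TO_MG_PER_ML,
        )

    def test_no_frames_fatal(self, toy_table):
        topo = self._topo(toy_table, 4, 1)
        traj = _bare_traj(np.zeros((3, 4, 3)), np.array([2.0, 2.0, 8.0]))
        with pytest.raises(ValueError, match="no frames"):
            density_profile(traj, topo, frame_window=(3, 3))


class TestCoexistence:
    def test_recovers_generator_truth(self, rng):
        prof = make_step_profile(seed=11)
        res = coexistence_densities(prof, dilute_margin=10.0)
        assert res.phase_separated
        assert abs(res.c_dense - 300.0) <= max(2 * res.c_dense_se, 0.02 * 300)
        assert abs(res.c_sat - 3.0) <= max(2 * res.c_sat_se, 0.02 * 3.0)

    def test_flat_profile_flagged_not_separated(self, rng):
        prof = make_step_profile(c_dense=5.0, c_sat=5.0, seed=12)
        res = coexistence_densities(prof, dilute_margin=10.0)
        assert not res.phase_separated

    def test_zero_dilute_density(self, rng):
        prof = make_step_profile(c_sat=0.0, noise=0.0, seed=13)
        res = coexistence_densities(prof, dilute_margin=10.0)
        assert res.phase_separated
        assert res.c_sat == 0.0
        assert res.c_dense == pytest.approx(300.0, rel=1e-9)

    def test_no_dilute_bins_fatal(self, rng):
        prof = make_step_profile(seed=14)
        with pytest.raises(ValueError, match="dilute"):
            coexistence_densities(prof, dilute_margin=50.0)


class TestContactMap:
    def test_fixed_distance_pairs(self, toy_table):
        topo = build_topology(["X", "X"], toy_table)
        topo.bonds = np.empty((0, 2), dtype=np.int64)
        box = np.array([20.0, 20.0, 20.0])
        close = _bare_traj(np.tile(np.array([[5, 5, 5.0], [5, 5, 5.5]]), (3, 1, 1)), box)
        far = _bare_traj(np.tile(np.array([[5, 5, 5.0], [5, 5, 5.9]]), (3, 1, 1)), box)
        m_close = contact_map(close, topo, cutoff=0.8, mode="inter")
        m_far = contact_map(far, topo, cutoff=0.8, mode="inter")
        assert m_close.matrix[0, 0] == 1.0
        assert m_far.matrix[0, 0] == 0.0

    def test_known_contact_pattern(self):
        ref = make_reference_trajectory(
            "known_contacts", {"n_res": 12, "pairs": [(1, 5), (2, 9)]}
        )
        cmap = contact_map(ref.trajectory, ref.topology, cutoff=0.8, mode="inter")
        # support is exactly the pinned pairs (plus transposes); each is seen
        # in one of the two ordered chain pairs, hence frequency 1/2
        want = np.zeros((12, 12))
        want[0, 4] = want[4, 0] = 0.5
        want[1, 8] = want[8, 1] = 0.5
        np.testing.assert_allclose(cmap.matrix, want)

    def test_matches_brute_force_oracle(self, toy_table, rng):
        """Random 3-chain, 20-residue, 10-frame trajectory: the cell-based
        implementation equals an O(N^2 F) double loop exactly."""
        n_chains, nres, nf = 3, 20, 10
        topo = build_topology(["X" * nres] * n_chains, toy_table)
        box = np.array([6.0, 6.0, 6.0])
        pos = rng.uniform(0, 6.0, (nf, n_chains * nres, 3))
        traj = _bare_traj(pos, box)
        for mode in ("intra", "inter"):
            got = contact_map(traj, topo, cutoff=0.8, mode=mode)
            want = _contact_oracle(pos, box, topo, 0.8, mode)
            np.testing.assert_allclose(got.matrix, want)
            # symmetry and range invariants
            np.testing.assert_allclose(got.matrix, got.matrix.T)
            assert got.matrix.min() >= 0 and got.matrix.max() <= 1

    def test_single_chain_has_no_inter_contacts(self, toy_table):
        topo = build_topology("X" * 5, toy_table)
        traj = _bare_traj(np.zeros((2, 5, 3)) + 2.0, np.array([10.0, 10.0, 10.0]))
        with pytest.raises(ValueError, match="two chains"):
            contact_map(traj, topo, mode="inter")

    def test_bad_cutoff_fatal(self, toy_table, decamer):
        traj = _bare_traj(np.zeros((1, 10, 3)), np.array([5.0, 5.0, 5.0]))
        with pytest.raises(ValueError, match="cutoff"):
            contact_map(traj, decamer, cutoff=0.0)


def _contact_oracle(pos, box, topo, cutoff, mode):
    """Brute-force contact frequencies (independent of the KD-tree path)."""
    nres = len(topo.sequences[0])
    n_chains = topo.n_chains
    acc = np.zeros((nres, nres))
    for frame in pos:
        d = frame[:, None] - frame[None]
        d -= box * np.rint(d / box)
        r = np.sqrt((d**2).sum(-1))
        if mode == "intra":
            for c in range(n_chains):
                sl = topo.chain_slice(c)
                sub = r[sl, sl.start:sl.stop]
                for a in range(nres):
                    for b in range(a + 3, nres):
                        if sub[a, b] <= cutoff:
                            acc[a, b] += 1
                            acc[b, a] += 1
        else:
            for ca in range(n_chains):
                for cb in range(n_chains):
                    if ca == cb:
                        continue
                    sa, sb = topo.chain_slice(ca), topo.chain_slice(cb)
                    sub = r[sa, sb.start:sb.stop]
                    hits = np.argwhere(sub <= cutoff)
                    for a, b in hits:
                        acc[a, b] += 1
    if mode == "intra":
        acc = acc / (len(pos) * n_chains)
        np.fill_diagonal(acc, acc.diagonal() / 1)
    else:
        acc = acc / (len(pos) * n_chains * (n_chains - 1))
    return acc


class TestPerResidueContacts:
    def test_zero_map(self, toy_table):
        m = ContactMap(np.zeros((6, 6)), 0.8, "inter", 1)
        mean, se = per_residue_contacts(m)
        np.testing.assert_array_equal(mean, np.zeros(6))
        np.testing.assert_array_equal(se, np.zeros(6))

    def test_hand_computed_mean_and_se(self):
        m1 = ContactMap(np.array([[0.2, 0.4], [0.4, 0.0]]), 0.8, "inter", 10)
        m2 = ContactMap(np.array([[0.4, 0.2], [0.2, 0.2]]), 0.8, "inter", 10)
        mean, se = per_residue_contacts([m1, m2])
        # row sums: [0.6, 0.4] and [0.6, 0.4] -> mean [0.6, 0.4], se 0
        np.testing.assert_allclose(mean, [0.6, 0.4])
        np.testing.assert_allclose(se, [0.0, 0.0], atol=1e-15)
        m3 = ContactMap(np.array([[0.0, 0.2], [0.2, 0.2]]), 0.8, "inter", 10)
        mean, se = per_residue_contacts([m1, m3])
        np.testing.assert_allclose(mean, [(0.6 + 0.2) / 2, (0.4 + 0.4) / 2])
        want_se = np.array([np.std([0.6, 0.2], ddof=1), 0.0]) / np.sqrt(2)
        np.testing.assert_allclose(se, want_se)

    def test_rows_equal_columns_for_symmetric_map(self, rng):
        a = rng.uniform(0, 0.5, (8, 8))
        m = ContactMap((a + a.T) / 2, 0.8, "inter", 4)
        mean_rows, _ = per_residue_contacts(m)
        np.testing.assert_allclose(mean_rows, m.matrix.sum(axis=0))

    def test_inconsistent_shapes_fatal(self):
        m1 = ContactMap(np.zeros((4, 4)), 0.8, "inter", 1)
        m2 = ContactMap(np.zeros((5, 5)), 0.8, "inter", 1)
        with pytest.raises(ValueError, match="shape"):
            per_residue_contacts([m1, m2])


class TestDiffusion:
    def test_immobile_chains(self, toy_table):
        topo = build_topology(["X"] * 5, toy_table)
        pos = np.tile(np.arange(5)[:, None] * 3.0, (30, 1, 1)) * np.array([1, 0, 0]) + 10
        traj = _bare_traj(pos, np.array([100.0] * 3), dt=1.0)
        res = msd_diffusion(traj, topo, fit_window=(1.0, 20.0))
        assert res.D == 0.0

    def test_brownian_recovery(self):
        ref = make_reference_trajectory("brownian", {"D": 0.01, "n_chains": 30,
                                                     "n_frames": 3000}, seed=5)
        res = msd_diffusion(ref.trajectory, ref.topology, fit_window=(5.0, 100.0))
        assert res.D == pytest.approx(0.01, rel=0.10)
        assert res.warning is None

    def test_ballistic_trace_warns(self, toy_table):
        topo = build_topology(["X"] * 3, toy_table)
        t = np.arange(200) * 1.0
        pos = np.zeros((200, 3, 3))
        pos[:, :, 0] = 0.3 * t[:, None]  # constant velocity
        traj = _bare_traj(pos + 50.0, np.array([1e5] * 3), dt=1.0)
        res = msd_diffusion(traj, topo, fit_window=(5.0, 100.0))
        assert res.warning is not None and "not" in res.warning or "ballistic" in res.warning

    def test_window_beyond_trajectory_fatal(self, toy_table):
        topo = build_topology(["X"] * 3, toy_table)
        traj = _bare_traj(np.zeros((10, 3, 3)), np.array([10.0] * 3), dt=1.0)
        with pytest.raises(ValueError, match="window"):
            msd_diffusion(traj, topo, fit_window=(1.0, 100.0))
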