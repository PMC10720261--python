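"""Langevin (NVT) and velocity-Verlet (NVE) dynamics with rigid bodies.

Flexible beads follow a BAOAB-splitting Langevin integrator with per-bead
friction ``gamma_i = m_i / tau``; rigid groups are propagated as rigid
bodies (COM + quaternion, no-squish free-rotor substeps) driven by the
summed member forces and torques.  Because friction is proportional to
mass, the summed member friction reduces exactly to ``M/tau`` on the COM
and ``I/tau`` on the rotation, so every degree of freedom relaxes with the
same damping time ``tau`` and satisfies fluctuation–dissipation at the
target temperature.

The NVE mode (thermostat off) exists for verification: energy drift and
momentum conservation checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from . import _kernels
from .params import KB
from .potentials import OverlapError, PairInteractionParams
from .topology import Topology
from .trajectory import Configuration, Trajectory


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Run controls.  Defaults mirror the production protocol for
    residue-level slab runs: 310 K, dt = 10 fs, damping time tau = 1000 ps."""

    temperature: float = 310.0  # K
    dt: float = 0.01  # ps (10 fs)
    tau_damp: float = 1000.0  # ps
    n_steps: int = 100_000
    save_interval: int = 1000
    seed: int = 0
    ensemble: Literal["NVT", "NVE"] = "NVT"
    box: tuple[float, float, float] = (20.0, 20.0, 168.0)  # nm

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.tau_damp <= 0:
            raise ValueError("tau_damp must be positive")
        if self.ensemble == "NVT" and self.temperature <= 0:
            raise ValueError("temperature must be positive for NVT")
        if self.ensemble not in ("NVT", "NVE"):
            raise ValueError("ensemble must be 'NVT' or 'NVE'")
        if self.save_interval < 1:
            raise ValueError("save_interval must be >= 1")


@dataclass
class State:
    """Mutable integrator state.

    Rigid-group degrees of freedom live in ``com``/``quat``/``vcom``/
    ``lbody`` (body-frame angular momentum); member bead positions in
    ``positions`` are always consistent with them.  ``velocities`` rows of
    rigid members are ignored.
    """

    positions: np.ndarray  # (N, 3) nm, unwrapped
    velocities: np.ndarray  # (N, 3) nm/ps
    box: np.ndarray  # (3,)
    com: np.ndarray  # (G, 3)
    quat: np.ndarray  # (G, 4) scalar-first, body->lab
    vcom: np.ndarray  # (G, 3)
    lbody: np.ndarray  # (G, 3) amu nm^2 / ps
    step: int = 0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def copy(self) -> "State":
        return State(
            self.positions.copy(),
            self.velocities.copy(),
            self.box.copy(),
            self.com.copy(),
            self.quat.copy(),
            self.vcom.copy(),
            self.lbody.copy(),
            self.step,
            np.random.default_rng(),  # fresh stream; use init_state for reproducible runs
        )


@dataclass
class _RigidArrays:
    indptr: np.ndarray
    members: np.ndarray
    body_coords: np.ndarray
    mass: np.ndarray
    inertia: np.ndarray  # (G, 3) principal moments


def _rigid_arrays(topology: Topology) -> _RigidArrays:
    groups = topology.rigid_groups
    indptr = np.zeros(len(groups) + 1, dtype=np.int64)
    members: list[np.ndarray] = []
    body: list[np.ndarray] = []
    mass = np.zeros(len(groups))
    inertia = np.zeros((len(groups), 3))
    for g, grp in enumerate(groups):
        idx = topology.rigid_member_indices(g)
        m = topology.masses[idx]
        ref = grp.reference
        com = (m[:, None] * ref).sum(axis=0) / m.sum()
        c = ref - com
        itens = np.einsum("i,ij,ik->jk", m, c, c)
        itens = np.trace(itens) * np.eye(3) - itens
        evals, evecs = np.linalg.eigh(itens)
        if np.linalg.det(evecs) < 0:
            evecs[:, 2] *= -1
        members.append(idx)
        body.append(c @ evecs)  # E^T c_i, rowwise
        mass[g] = m.sum()
        inertia[g] = evals
        indptr[g + 1] = indptr[g] + len(idx)
    return _RigidArrays(
        indptr=indptr,
        members=np.concatenate(members) if members else np.empty(0, dtype=np.int64),
        body_coords=np.concatenate(body) if body else np.empty((0, 3)),
        mass=mass,
        inertia=inertia,
    )


def _quat_from_matrix(R: np.ndarray) -> np.ndarray:
    # Shepperd's method
    t = np.trace(R)
    if t > 0:
        w = 0.5 * np.sqrt(1.0 + t)
        q = np.array(
            [w, (R[2, 1] - R[1, 2]) / (4 * w), (R[0, 2] - R[2, 0]) / (4 * w),
             (R[1, 0] - R[0, 1]) / (4 * w)]
        )
    else:
        k = int(np.argmax(np.diag(R)))
        i, j = (k + 1) % 3, (k + 2) % 3
        s = np.sqrt(1.0 + R[k, k] - R[i, i] - R[j, j])
        q = np.zeros(4)
        q[1 + k] = 0.5 * s
        q[0] = (R[j, i] - R[i, j]) / (2 * s)
        q[1 + i] = (R[i, k] + R[k, i]) / (2 * s)
        q[1 + j] = (R[j, k] + R[k, j]) / (2 * s)
    return q / np.linalg.norm(q)


def init_state(
    topology: Topology,
    initial: Configuration,
    config: SimulationConfig,
    velocities: np.ndarray | None = None,
) -> State:
    """Build a :class:`State` from an initial configuration.

    Rigid-group orientations are recovered by weighted Kabsch superposition
    of the reference coordinates onto the configuration.  Velocities default
    to a Maxwell–Boltzmann draw at ``config.temperature`` from the run seed;
    pass explicit ``velocities`` to override (NVE runs included).
    """
    rng = np.random.default_rng(config.seed)
    pos = np.ascontiguousarray(initial.positions, dtype=float).copy()
    n = len(pos)
    if n != topology.n_beads:
        raise ValueError("configuration size does not match topology")
    ra = _rigid_arrays(topology)
    ngrp = len(topology.rigid_groups)
    com = np.zeros((ngrp, 3))
    quat = np.zeros((ngrp, 4))
    vcom = np.zeros((ngrp, 3))
    lbody = np.zeros((ngrp, 3))
    kt = KB * config.temperature

    for g in range(ngrp):
        idx = topology.rigid_member_indices(g)
        m = topology.masses[idx]
        x = pos[idx]
        com[g] = (m[:, None] * x).sum(axis=0) / m.sum()
        b = ra.body_coords[ra.indptr[g] : ra.indptr[g + 1]]
        # weighted Kabsch: R minimizing sum m |x - com - R b|^2
        H = np.einsum("i,ij,ik->jk", m, b, x - com[g])
        U, _, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        D = np.diag([1.0, 1.0, d])
        R = Vt.T @ D @ U.T
        quat[g] = _quat_from_matrix(R)
        rmsd = np.sqrt(((x - com[g] - b @ R.T) ** 2).sum(axis=1).mean())
        if rmsd > 1e-5:
            raise ValueError(
                f"rigid group {g}: configuration deviates from reference "
                f"geometry (RMSD {rmsd:.2e} nm)"
            )

    vel = np.zeros((n, 3))
    if velocities is not None:
        vel[:] = velocities
        for g in range(ngrp):
            idx = topology.rigid_member_indices(g)
            m = topology.masses[idx]
            vcom[g] = (m[:, None] * vel[idx]).sum(axis=0) / m.sum()
            # body-frame angular momentum about COM
            Lw = np.zeros(3)
            for i, mi in zip(idx, m):
                Lw += mi * np.cross(pos[i] - com[g], vel[i])
            Rm = _rotation_matrix(quat[g])
            lbody[g] = Rm.T @ Lw
    elif config.temperature > 0:
        flex = topology.rigid_of_bead < 0
        vel[flex] = rng.standard_normal((int(flex.sum()), 3)) * np.sqrt(
            kt / topology.masses[flex, None]
        )
        if ngrp:
            vcom[:] = rng.standard_normal((ngrp, 3)) * np.sqrt(kt / ra.mass[:, None])
            lbody[:] = rng.standard_normal((ngrp, 3)) * np.sqrt(kt * ra.inertia)

    # snap member positions onto the rigid reference geometry
    if ngrp:
        _kernels.rigid_positions(com, quat, ra.indptr, ra.members, ra.body_coords, pos)

    return State(
        positions=pos,
        velocities=vel,
        box=np.asarray(config.box, dtype=float),
        com=com,
        quat=quat,
        vcom=vcom,
        lbody=lbody,
        step=0,
        rng=rng,
    )


def _rotation_matrix(q: np.ndarray) -> np.ndarray:
    R = np.empty((3, 3))
    _kernels._qrotmat(q, R)
    return R


def kinetic_temperature(state: State, topology: Topology) -> float:
    """Instantaneous kinetic temperature over all 3N_flex + 6G DOF."""
    ra = _rigid_arrays(topology)
    flex = topology.rigid_of_bead < 0
    ke = 0.5 * float(
        (topology.masses[flex, None] * state.velocities[flex] ** 2).sum()
    )
    ngrp = len(topology.rigid_groups)
    if ngrp:
        ke += 0.5 * float((ra.mass[:, None] * state.vcom**2).sum())
        ke += 0.5 * float((state.lbody**2 / ra.inertia).sum())
    dof = 3 * int(flex.sum()) + 6 * ngrp
    return 2.0 * ke / (dof * KB)


def _advance(
    state: State,
    topology: Topology,
    pair_params: PairInteractionParams,
    config: SimulationConfig,
    ra: _RigidArrays,
    flex_idx: np.ndarray,
    n_steps: int,
) -> float:
    """Advance ``n_steps`` in place; returns the final potential energy."""
    nvt = config.ensemble == "NVT"
    ou_c = np.exp(-config.dt / config.tau_damp) if nvt else -1.0
    kt = KB * config.temperature
    nrows = len(flex_idx) + 2 * len(ra.mass)
    noise = (
        state.rng.standard_normal((n_steps, nrows, 3))
        if nvt
        else np.empty((1, 1, 3))
    )
    status, at, energy, i, j = _kernels.run_chunk(
        state.positions,
        state.velocities,
        state.com,
        state.quat,
        state.vcom,
        state.lbody,
        flex_idx,
        np.flatnonzero(topology.charges != 0.0),
        topology.masses,
        ra.indptr,
        ra.members,
        ra.body_coords,
        ra.mass,
        ra.inertia,
        state.box,
        topology.sigmas,
        topology.lambdas,
        topology.charges,
        pair_params.epsilon,
        pair_params.lj_cutoff,
        pair_params.debye_length,
        pair_params.dielectric,
        pair_params.coulomb_cutoff,
        topology.bonds,
        topology.bond_r0,
        topology.bond_k,
        topology.excl_indptr,
        topology.excl_indices,
        config.dt,
        ou_c,
        kt,
        noise,
        pair_params.skin,
        n_steps,
    )
    if status == 1:
        raise OverlapError(
            f"fatal overlap between beads {i} and {j} at step {state.step + at}"
        )
    if status == 2:
        raise IntegrationError(
            f"instability at step {state.step + at}: bead {i} moved more than "
            f"{_kernels.MAX_STEP_DISP} nm in one step"
        )
    state.step += n_steps
    return float(energy)


def langevin_step(
    state: State,
    topology: Topology,
    pair_params: PairInteractionParams = PairInteractionParams(),
    config: SimulationConfig = SimulationConfig(),
    n_steps: int = 1,
) -> State:
    """Advance the state by ``n_steps`` integrator steps (in place)."""
    ra = _rigid_arrays(topology)
    flex_idx = np.flatnonzero(topology.rigid_of_bead < 0)
    _advance(state, topology, pair_params, config, ra, flex_idx, n_steps)
    return state


def settle(
    topology: Topology,
    initial: Configuration,
    temperature: float,
    seed: int,
    pair_params: PairInteractionParams = PairInteractionParams(),
    box: tuple[float, float, float] | None = None,
    ramp_steps: int = 20_000,
    thermalize_steps: int = 30_000,
) -> State:
    """Short staged equilibration for freshly packed configurations.

    Runs a small-timestep, strongly coupled Langevin ramp (1 ps damping at
    dt = 2 fs for ``ramp_steps``, then 5 ps damping at dt = 10 fs for
    ``thermalize_steps``) that drains packing strain without the
    displacement blow-ups a cold start at production settings can produce.
    Returns a thermalised :class:`State`.
    """
    box = tuple(initial.box) if box is None else box
    cfg1 = SimulationConfig(temperature=temperature, dt=0.002, tau_damp=1.0,
                            n_steps=ramp_steps, save_interval=ramp_steps,
                            seed=seed, box=box)
    state = init_state(topology, initial, cfg1)
    langevin_step(state, topology, pair_params, cfg1, n_steps=ramp_steps)
    cfg2 = replace(cfg1, dt=0.01, tau_damp=5.0)
    langevin_step(state, topology, pair_params, cfg2, n_steps=thermalize_steps)
    return state


def run_simulation(
    topology: Topology,
    initial: Configuration | State,
    config: SimulationConfig,
    pair_params: PairInteractionParams = PairInteractionParams(),
    save_path=None,
) -> Trajectory:
    """Run a simulation, saving a frame every ``config.save_interval`` steps.

    The trajectory logs potential energy, kinetic temperature and mean
    per-chain Rg at every save point.  Identical inputs and seed give
    identical trajectories.
    """
    from .analysis import radius_of_gyration  # local import to avoid cycle

    if isinstance(initial, State):
        state = initial
    else:
        state = init_state(topology, initial, config)
    ra = _rigid_arrays(topology)
    flex_idx = np.flatnonzero(topology.rigid_of_bead < 0)

    n_saves = config.n_steps // config.save_interval
    n = topology.n_beads
    positions = np.empty((n_saves, n, 3))
    steps = np.empty(n_saves, dtype=np.int64)
    pot = np.empty(n_saves)
    kin_t = np.empty(n_saves)
    rg = np.empty(n_saves)

    for s in range(n_saves):
        try:
            energy = _advance(
                state, topology, pair_params, config, ra, flex_idx,
                config.save_interval,
            )
        except (OverlapError, IntegrationError):
            # flush the partial trajectory before propagating the failure
            if save_path is not None and s > 0:
                _partial(
                    positions, steps, pot, kin_t, rg, s, state, config, save_path
                )
            raise
        positions[s] = state.positions
        steps[s] = state.step
        pot[s] = energy
        kin_t[s] = kinetic_temperature(state, topology)
        rg[s] = float(
            np.mean(
                [
                    radius_of_gyration(
                        state.positions[topology.chain_slice(c)],
                        topology.masses[topology.chain_slice(c)],
                    )
                    for c in range(topology.n_chains)
                ]
            )
        )

    traj = Trajectory(
        positions=positions,
        box=state.box.copy(),
        steps=steps,
        time=steps * config.dt,
        potential_energy=pot,
        kinetic_temperature=kin_t,
        rg_mean=rg,
        metadata={
            "temperature": config.temperature,
            "dt": config.dt,
            "tau_damp": config.tau_damp,
            "seed": config.seed,
            "ensemble": config.ensemble,
            "epsilon": pair_params.epsilon,
            "debye_length": pair_params.debye_length,
            "dielectric": pair_params.dielectric,
            "lj_cutoff": pair_params.lj_cutoff,
            "coulomb_cutoff": pair_params.coulomb_cutoff,
        },
    )
    if save_path is not None:
        traj.save(save_path)
    return traj


def _partial(positions, steps, pot, kin_t, rg, s, state, config, save_path):
    Trajectory(
        positions=positions[:s],
        box=state.box.copy(),
        steps=steps[:s],
        time=steps[:s] * config.dt,
        potential_energy=pot[:s],
        kinetic_temperature=kin_t[:s],
        rg_mean=rg[:s],
        metadata={"partial": True, "seed": config.seed},
    ).save(save_path)
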