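"""Initial configurations: single chains, chain pairs, and slab geometries.

Chains are grown as self-avoiding random walks with fixed bond length;
rigid groups are placed as intact units with randomized orientation.  Slabs
pack whole chains into the central z-window of an elongated box.  Freshly
packed systems sit close to the clash tolerance and should be relaxed with
a few capped-displacement steepest-descent sweeps (:func:`relax`) before
dynamics — this substitutes for a separate energy-minimisation stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .potentials import PairInteractionParams, total_energy_forces
from .topology import Topology
from .trajectory import Configuration


class PackingError(RuntimeError):
    pass


@dataclass(frozen=True)
class SlabSpec:
    """Slab geometry: elongated z, chains packed into a central z-window."""

    box: tuple[float, float, float] = (20.0, 20.0, 168.0)  # nm
    n_chains: int = 100
    z_window_fraction: float = 0.4  # central fraction of z used for packing

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not 0 < self.z_window_fraction <= 1:
            raise ValueError("z_window_fraction must be in (0, 1]")
        x, y, z = self.box
        if min(self.box) <= 0:
            raise ValueError("box lengths must be positive")
        if z < 2 * max(x, y):
            warnings.warn(
                "slab z-dimension is less than twice the cross-section; "
                "coexistence profiles will have poorly separated interfaces",
                stacklevel=2,
            )


def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.rint(d / box)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _clashes(candidate: np.ndarray, placed: np.ndarray, box: np.ndarray,
             min_sep: float, skip_last: int = 0) -> bool:
    """True if any candidate bead is closer than ``min_sep`` to a placed bead
    (minimum image), ignoring the last ``skip_last`` placed beads (bonded
    neighbor)."""
    if len(placed) - skip_last <= 0:
        return False
    ref = placed[: len(placed) - skip_last]
    for c in np.atleast_2d(candidate):
        d = _min_image(ref - c, box)
        if (np.einsum("ij,ij->i", d, d) < min_sep * min_sep).any():
            return True
    return False


def grow_chain(
    topology: Topology,
    chain: int,
    box,
    seed: int | np.random.Generator = 0,
    min_sep: float = 0.25,
    max_restarts: int = 200,
    max_tries_per_unit: int = 60,
    obstacles: np.ndarray | None = None,
    obstacle_sep: float = 0.3,
    z_window: tuple[float, float] | None = None,
    confine_radius: float | None = None,
) -> np.ndarray:
    """Grow one chain as a self-avoiding walk with bond length ``bond_r0``.

    Rigid groups are inserted as intact units in random orientation; their
    internal geometry reproduces the group reference exactly.  Deterministic
    for a fixed seed.  ``obstacles`` (e.g. beads of previously placed
    chains) are avoided at ``obstacle_sep`` under the minimum image;
    ``z_window`` confines every bead's wrapped z-coordinate;
    ``confine_radius`` confines the walk to a sphere about the box center
    (compact starting conformations).  Raises
    :class:`PackingError` when the walk cannot be completed (suggesting a
    larger box).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    obstree = (
        cKDTree(np.mod(obstacles, box), boxsize=box)
        if obstacles is not None and len(obstacles)
        else None
    )

    def blocked(cand: np.ndarray) -> bool:
        c2 = np.atleast_2d(cand)
        if confine_radius is not None:
            if np.any(((c2 - box / 2) ** 2).sum(axis=1) > confine_radius**2):
                return True
        if z_window is not None:
            z = np.mod(c2[:, 2], box[2])
            if np.any((z < z_window[0]) | (z > z_window[1])):
                return True
        if obstree is not None:
            hits = obstree.query_ball_point(np.mod(c2, box), obstacle_sep)
            if any(len(h) for h in hits):
                return True
        return False
    sl = topology.chain_slice(chain)
    length = sl.stop - sl.start
    r0 = topology.bond_r0

    # residue -> rigid group lookup for this chain (1-based residue windows)
    group_at: dict[int, int] = {}
    for g, grp in enumerate(topology.rigid_groups):
        if grp.chain == chain:
            group_at[grp.start] = g

    for _ in range(max_restarts):
        coords = np.empty((length, 3))
        n_placed = 0
        failed = False
        res = 1
        while res <= length:
            if res in group_at:
                g = group_at[res]
                grp = topology.rigid_groups[g]
                ref = grp.reference - grp.reference[0]
                ok = False
                for _try in range(max_tries_per_unit):
                    R = _random_rotation(rng)
                    if n_placed == 0:
                        first = _first_site(rng, box, confine_radius)
                    else:
                        first = coords[n_placed - 1] + r0 * _random_unit(rng)
                    cand = first + ref @ R.T
                    if not _clashes(
                        cand, coords[:n_placed], box, min_sep, skip_last=1
                    ) and not blocked(cand):
                        m = grp.n_members
                        coords[n_placed : n_placed + m] = cand
                        n_placed += m
                        res += m
                        ok = True
                        break
                if not ok:
                    failed = True
                    break
            else:
                ok = False
                for _try in range(max_tries_per_unit):
                    if n_placed == 0:
                        cand = _first_site(rng, box, confine_radius)
                    else:
                        cand = coords[n_placed - 1] + r0 * _random_unit(rng)
                    if not _clashes(
                        cand, coords[:n_placed], box, min_sep, skip_last=1
                    ) and not blocked(cand):
                        coords[n_placed] = cand
                        n_placed += 1
                        res += 1
                        ok = True
                        break
                if not ok:
                    failed = True
                    break
        if not failed:
            return coords
    raise PackingError(
        f"grow_chain: could not place chain {chain} after {max_restarts} restarts; "
        "try a larger box or smaller min_sep"
    )


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _first_site(rng: np.random.Generator, box: np.ndarray,
                confine_radius: float | None) -> np.ndarray:
    if confine_radius is None:
        return rng.uniform(0, 1, 3) * box
    while True:
        p = rng.uniform(-confine_radius, confine_radius, 3)
        if p @ p <= confine_radius**2:
            return box / 2 + p


def initial_single_chain(
    topology: Topology, box, seed: int = 0, min_sep: float = 0.25,
    confine_radius: float | None = None,
) -> Configuration:
    """Grow every chain independently (no inter-chain clash pass); intended
    for single-chain boxes.  ``confine_radius`` produces a compact start."""
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    parts = [
        grow_chain(topology, c, box, rng, min_sep=min_sep,
                   confine_radius=confine_radius)
        for c in range(topology.n_chains)
    ]
    return Configuration(np.vstack(parts), box)


def build_slab(
    spec: SlabSpec,
    topology: Topology,
    seed: int = 0,
    min_sep: float = 0.25,
    inter_chain_sep: float = 0.3,
    max_regrows_per_chain: int = 30,
) -> Configuration:
    """Pack ``spec.n_chains`` chains into the central z-window of the slab.

    Chains are grown in place, one after another, as self-avoiding walks
    confined to the window that also avoid all previously placed beads at
    ``inter_chain_sep`` (minimum image).  Growing in place lets late chains
    thread through the gaps left by earlier ones, which sequential
    rigid-body insertion cannot do at condensate-like densities.  Raises
    :class:`PackingError` naming the achieved chain count when the density
    is too high.
    """
    if topology.n_chains != spec.n_chains:
        raise ValueError(
            f"topology has {topology.n_chains} chains but spec requests {spec.n_chains}"
        )
    rng = np.random.default_rng(seed)
    box = np.asarray(spec.box, dtype=float)
    lz = box[2]
    half_win = 0.5 * spec.z_window_fraction * lz
    z_window = (lz / 2 - half_win, lz / 2 + half_win)

    placed: list[np.ndarray] = []
    for c in range(spec.n_chains):
        obstacles = np.vstack(placed) if placed else None
        coords = None
        for _ in range(max_regrows_per_chain):
            try:
                coords = grow_chain(
                    topology, c, box, rng, min_sep=min_sep,
                    max_restarts=20, obstacles=obstacles,
                    obstacle_sep=inter_chain_sep, z_window=z_window,
                )
                break
            except PackingError:
                continue
        if coords is None:
            raise PackingError(
                f"build_slab: packed only {c} of {spec.n_chains} chains; "
                "density too high for the requested window"
            )
        placed.append(coords)
    return Configuration(np.vstack(placed), box)


def relax(
    configuration: Configuration,
    topology: Topology,
    pair_params: PairInteractionParams = PairInteractionParams(),
    n_sweeps: int = 200,
    max_disp: float = 0.02,
    f_tol: float = 1.0e4,
) -> Configuration:
    """Capped-displacement steepest descent to remove packing strain.

    Every sweep moves each bead along its force, with the largest
    displacement capped at ``max_disp`` nm; rigid groups move and rotate as
    units (forces reduced to COM force + torque, small-angle rotation).
    Stops early once the largest force magnitude falls below ``f_tol``
    kJ/mol/nm.
    """
    pos = configuration.positions.copy()
    box = configuration.box
    rigid = [
        (topology.rigid_member_indices(g), topology.masses[topology.rigid_member_indices(g)])
        for g in range(len(topology.rigid_groups))
    ]
    in_rigid = topology.rigid_of_bead >= 0
    for _ in range(n_sweeps):
        _, forces = total_energy_forces(pos, box, topology, pair_params)
        fmax = float(np.abs(forces).max())
        if fmax < f_tol:
            break
        scale = max_disp / max(np.linalg.norm(forces, axis=1).max(), 1e-12)
        step = forces * scale
        pos[~in_rigid] += step[~in_rigid]
        for idx, m in rigid:
            fnet = forces[idx].sum(axis=0)
            com = (m[:, None] * pos[idx]).sum(axis=0) / m.sum()
            torque = np.cross(pos[idx] - com, forces[idx]).sum(axis=0)
            shift = fnet / len(idx) * scale
            pos[idx] += shift
            # small rigid rotation about COM along the torque direction
            tnorm = np.linalg.norm(torque)
            if tnorm > 1e-12:
                axis = torque / tnorm
                angle = min(scale * tnorm / max(len(idx), 1), 0.05)
                K = np.array(
                    [
                        [0, -axis[2], axis[1]],
                        [axis[2], 0, -axis[0]],
                        [-axis[1], axis[0], 0],
                    ]
                )
                R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
                pos[idx] = (pos[idx] - com) @ R.T + com
    return Configuration(pos, box)
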