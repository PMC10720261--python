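"""Synthetic systems with analytically known properties.

Three families of inputs let every analysis stage be tested without any
external downloads:

* toy sequences — sticky homopolymers (uniform, tunable hydropathy),
  block polyampholytes, and disordered fragments with a TDP-43-CTD-like
  composition (G/S/N/Q rich, low charge);
* ideal geometric rigid bodies — an ideal alpha-helix Calpha trace and a
  randomly packed compact globule standing in for folded-domain
  coordinates (synthetic, no claim of structural realism);
* reference trajectories whose target observable is known exactly: beads
  on a ring (Rg = ring radius), fixed contact patterns, and Brownian walks
  of chosen diffusion coefficient.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .params import ParameterTable, load_parameter_table, tdp43_sequence
from .topology import Topology, build_topology
from .trajectory import Trajectory


@dataclass(frozen=True)
class ToySequenceSpec:
    kind: str  # sticky_homopolymer | polyampholyte | idr_fragment
    length: int = 50
    stickiness: float | None = None  # lambda override for the toy bead
    charge_pattern: str | None = None  # e.g. "E25K25" for a diblock
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("toy sequence length must be >= 2")
        if self.stickiness is not None and not 0 <= self.stickiness <= 1.1:
            raise ValueError("stickiness override must lie in [0, 1.1]")


#: toy sticky bead: average residue geometry, neutral
_TOY_BEAD = {"mass": 110.0, "charge": 0.0, "sigma": 0.60}


def make_toy_system(
    spec: ToySequenceSpec, base_table: ParameterTable | None = None
) -> tuple[str, ParameterTable]:
    """Build a toy sequence and the parameter table that describes it.

    * ``sticky_homopolymer`` — ``length`` copies of a neutral bead ``X``
      whose hydropathy is ``spec.stickiness`` (default 1.0), giving tunable
      phase behavior;
    * ``polyampholyte`` — charge blocks from ``charge_pattern`` (default a
      symmetric E/K diblock), net charge zero for symmetric patterns;
    * ``idr_fragment`` — a shuffled sequence reproducing the residue
      composition of the TDP-43 C-terminal disordered region (aa 261-414)
      to within one residue per type.
    """
    table = base_table if base_table is not None else load_parameter_table()
    if spec.kind == "sticky_homopolymer":
        lam = 1.0 if spec.stickiness is None else spec.stickiness
        table = table.with_overrides({"X": {**_TOY_BEAD, "hydropathy": lam}})
        return "X" * spec.length, table
    if spec.kind == "polyampholyte":
        pattern = spec.charge_pattern or f"E{spec.length // 2}K{spec.length - spec.length // 2}"
        seq = _expand_pattern(pattern)
        if spec.stickiness is not None:
            table = table.with_overrides(
                {c: {"hydropathy": spec.stickiness} for c in set(seq)}
            )
        return seq, table
    if spec.kind == "idr_fragment":
        seq = _composition_sequence(
            ctd_composition(), spec.length, np.random.default_rng(spec.seed)
        )
        return seq, table
    raise ValueError(f"unknown toy system kind {spec.kind!r}")


def _expand_pattern(pattern: str) -> str:
    import re

    out = []
    for code, count in re.findall(r"([A-Z])(\d+)", pattern):
        out.append(code * int(count))
    if not out:
        raise ValueError(f"cannot parse charge pattern {pattern!r}")
    return "".join(out)


def ctd_composition() -> dict[str, float]:
    """Residue-type fractions of the TDP-43 C-terminal region (aa 261-414)."""
    ctd = tdp43_sequence()[260:414]
    return {c: ctd.count(c) / len(ctd) for c in sorted(set(ctd))}


def _composition_sequence(
    fractions: dict[str, float], length: int, rng: np.random.Generator
) -> str:
    # largest-remainder allocation, then a seeded shuffle
    codes = sorted(fractions)
    ideal = np.array([fractions[c] * length for c in codes])
    counts = np.floor(ideal).astype(int)
    rem = ideal - counts
    for k in np.argsort(-rem)[: length - counts.sum()]:
        counts[k] += 1
    seq = [c for c, n in zip(codes, counts) for _ in range(n)]
    rng.shuffle(seq)
    return "".join(seq)


# ---------------------------------------------------------------------------
# geometric rigid bodies
# ---------------------------------------------------------------------------


def ideal_helix_calpha(n_residues: int) -> np.ndarray:
    """Calpha trace of an ideal alpha helix (nm).

    Rise 0.15 nm/residue, 100 degrees twist, helix radius 0.23 nm; the
    consecutive Calpha-Calpha distance then comes out ~0.383 nm.
    """
    if n_residues < 4:
        raise ValueError("ideal_helix_calpha needs at least 4 residues")
    k = np.arange(n_residues)
    theta = np.deg2rad(100.0) * k
    return np.column_stack(
        [0.23 * np.cos(theta), 0.23 * np.sin(theta), 0.15 * k]
    )


def compact_globule_calpha(
    n_residues: int, seed: int = 0, min_sep: float = 0.45
) -> np.ndarray:
    """Randomly packed compact cluster of Calpha sites (synthetic stand-in
    for a folded domain; no structural realism claimed).

    Sites are placed by rejection sampling inside a sphere sized to typical
    folded-protein density (~0.134 nm^3 per residue), with a minimum
    inter-site separation.
    """
    if n_residues < 3:
        raise ValueError("compact_globule_calpha needs at least 3 residues")
    rng = np.random.default_rng(seed)
    radius = 1.15 * (3.0 * n_residues * 0.134 / (4.0 * np.pi)) ** (1.0 / 3.0)
    coords = np.empty((n_residues, 3))
    placed = 0
    attempts = 0
    while placed < n_residues:
        attempts += 1
        if attempts > 200_000:
            radius *= 1.1
            attempts = 0
            placed = 0
        p = rng.uniform(-radius, radius, 3)
        if p @ p > radius * radius:
            continue
        if placed and (((coords[:placed] - p) ** 2).sum(axis=1) < min_sep**2).any():
            continue
        coords[placed] = p
        placed += 1
    return coords


def tdp43_topology(
    variant: str = "WT",
    rigid: bool = True,
    table: ParameterTable | None = None,
    n_chains: int = 1,
) -> Topology:
    """Full-length TDP-43 topology with synthetic folded-domain references.

    Rigid windows: NTD 1-80, RRM1 105-177, RRM2 192-260 and the conserved
    helical region 320-343.  The helix uses the ideal alpha-helix trace; the
    three folded domains use packed compact globules (synthetic stand-ins
    for the crystallographic coordinates, adequate for excluded volume and
    rigid-body dynamics but not for native contacts).  ``variant`` is
    ``"WT"`` or ``"6WtoA"`` (all six Trp mutated to Ala).
    """
    from .topology import (
        TDP43_RIGID_WINDOWS,
        RigidGroup,
        apply_variant,
        build_topology,
        trp_to_ala_mutations,
    )

    seq = tdp43_sequence()
    if variant == "6WtoA":
        seq = apply_variant(seq, trp_to_ala_mutations(seq))
    elif variant != "WT":
        raise ValueError(f"unknown TDP-43 variant {variant!r}")
    if table is None:
        table = load_parameter_table()
    groups = []
    if rigid:
        for c in range(n_chains):
            for name, (start, stop) in TDP43_RIGID_WINDOWS.items():
                n = stop - start + 1
                ref = (
                    ideal_helix_calpha(n)
                    if name == "CR"
                    # one fixed globule per domain, shared across chains
                    else compact_globule_calpha(n, seed=zlib.crc32(name.encode()) % 2**31)
                )
                groups.append(
                    RigidGroup(chain=c, start=start, stop=stop, reference=ref, name=name)
                )
    return build_topology([seq] * n_chains, table, rigid_defs=groups)


def make_step_profile(
    c_dense: float = 300.0,
    c_sat: float = 3.0,
    n_frames: int = 60,
    lz: float = 80.0,
    bin_width: float = 1.0,
    slab_half_width: float = 6.0,
    noise: float = 0.1,
    area: float = 4.0,
    seed: int = 0,
):
    """Synthetic slab density profile with known coexistence concentrations.

    A square concentration step (``c_dense`` inside ``|z| < slab_half_width``,
    ``c_sat`` outside, mg/mL) with multiplicative Gaussian noise per bin and
    frame — the ground truth for testing coexistence-density estimation.
    """
    from .analysis import AMU_PER_NM3_TO_MG_PER_ML, DensityProfile

    rng = np.random.default_rng(seed)
    nb = int(lz / bin_width)
    z = (np.arange(nb) + 0.5) * bin_width - lz / 2
    base = np.where(np.abs(z) < slab_half_width, c_dense, c_sat)
    binvol = area * bin_width
    frame_mass = np.empty((n_frames, nb))
    for f in range(n_frames):
        conc = base * (1.0 + noise * rng.standard_normal(nb))
        frame_mass[f] = conc * binvol / AMU_PER_NM3_TO_MG_PER_ML
    mean_conc = frame_mass.mean(0) / binvol * AMU_PER_NM3_TO_MG_PER_ML
    return DensityProfile(
        bin_centers=z,
        concentration=mean_conc,
        count_density=mean_conc / 110.0 / AMU_PER_NM3_TO_MG_PER_ML,
        frame_mass=frame_mass,
        bin_width=bin_width,
        bin_volume=binvol,
        box=np.array([area**0.5, area**0.5, lz]),
        centering="none",
        offsets=np.zeros(n_frames),
    )


# ---------------------------------------------------------------------------
# reference trajectories
# ---------------------------------------------------------------------------


@dataclass
class ReferenceSystem:
    trajectory: Trajectory
    topology: Topology
    truth: dict = field(default_factory=dict)


def make_reference_trajectory(
    kind: str, params: dict | None = None, seed: int = 0
) -> ReferenceSystem:
    """Trajectories whose target observable is known analytically.

    * ``known_rg`` — ``n`` equal-mass beads on a ring of radius ``radius``:
      Rg equals the radius exactly;
    * ``known_contacts`` — two far-apart chains with selected inter-chain
      residue pairs pinned at ``contact_distance``; the contact map is
      nonzero exactly at those pairs;
    * ``brownian`` — ``n_chains`` independent single-bead random walks with
      diffusion coefficient ``D`` (nm^2/ps) at frame spacing ``dt`` (ps).
    """
    p = dict(params or {})
    rng = np.random.default_rng(seed)
    table = load_parameter_table().with_overrides({"X": {**_TOY_BEAD, "hydropathy": 0.5}})

    if kind == "known_rg":
        n = int(p.get("n", 24))
        radius = float(p.get("radius", 2.0))
        n_frames = int(p.get("n_frames", 3))
        theta = 2 * np.pi * np.arange(n) / n
        ring = np.column_stack(
            [radius * np.cos(theta), radius * np.sin(theta), np.zeros(n)]
        )
        box = np.array([10 * radius, 10 * radius, 10 * radius])
        pos = np.repeat(ring[None, :, :] + box / 2, n_frames, axis=0)
        topo = build_topology("X" * n, table)
        traj = _bare_trajectory(pos, box)
        return ReferenceSystem(traj, topo, {"rg": radius})

    if kind == "known_contacts":
        nres = int(p.get("n_res", 12))
        contacts = list(p.get("pairs", [(1, 5), (2, 9)]))  # 1-based (res_a, res_b)
        d = float(p.get("contact_distance", 0.5))
        n_frames = int(p.get("n_frames", 4))
        spacing = 3.0
        box = np.array([spacing * (nres + 2), 40.0, 40.0])
        chain_a = np.column_stack(
            [spacing * np.arange(nres) + 2, np.full(nres, 10.0), np.full(nres, 10.0)]
        )
        chain_b = np.column_stack(
            [spacing * np.arange(nres) + 2, np.full(nres, 25.0), np.full(nres, 10.0)]
        )
        used_b = set()
        for a, b in contacts:
            if b in used_b:
                raise ValueError("each chain-b residue may appear in one pinned contact")
            used_b.add(b)
            chain_b[b - 1] = chain_a[a - 1] + np.array([0.0, d, 0.0])
        pos = np.repeat(np.vstack([chain_a, chain_b])[None], n_frames, axis=0)
        # bonds would be absurdly stretched in this frozen geometry; build a
        # bond-free topology (two "chains" of disconnected beads)
        topo = build_topology(["X" * nres, "X" * nres], table)
        topo.bonds = np.empty((0, 2), dtype=np.int64)
        traj = _bare_trajectory(pos, box)
        return ReferenceSystem(traj, topo, {"pairs": contacts, "distance": d})

    if kind == "brownian":
        n_chains = int(p.get("n_chains", 20))
        diffusion = float(p.get("D", 0.01))
        dt = float(p.get("dt", 1.0))
        n_frames = int(p.get("n_frames", 2000))
        box = np.array([1e4, 1e4, 1e4])
        steps = rng.normal(
            0.0, np.sqrt(2 * diffusion * dt), size=(n_frames - 1, n_chains, 3)
        )
        pos = np.concatenate(
            [np.zeros((1, n_chains, 3)), np.cumsum(steps, axis=0)], axis=0
        ) + box / 2
        topo = build_topology(["X"] * n_chains, table)
        traj = _bare_trajectory(pos, box, dt=dt)
        return ReferenceSystem(traj, topo, {"D": diffusion, "dt": dt})

    raise ValueError(f"unknown reference trajectory kind {kind!r}")


def _bare_trajectory(pos: np.ndarray, box: np.ndarray, dt: float = 1.0) -> Trajectory:
    f = len(pos)
    return Trajectory(
        positions=np.asarray(pos, dtype=float),
        box=np.asarray(box, dtype=float),
        steps=np.arange(f, dtype=np.int64),
        time=np.arange(f, dtype=float) * dt,
        potential_energy=np.zeros(f),
        kinetic_temperature=np.zeros(f),
        rg_mean=np.zeros(f),
        metadata={"synthetic": True},
    )
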