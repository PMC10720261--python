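"""Chain topologies: beads, bonds, rigid groups, and nonbonded exclusions.

A system is a list of chains, each a string of 1-letter residue codes.  Every
residue is one bead.  Consecutive residues within a chain are joined by
harmonic bonds; selected residue windows (folded domains) can be declared
rigid, in which case their beads move as one rigid body whose internal
geometry is fixed to supplied reference coordinates.

Nonbonded exclusions comprise all bonded (1-2) pairs and all pairs within the
same rigid group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ParameterTable

#: default harmonic bond length between consecutive Calpha beads, nm
DEFAULT_BOND_R0 = 0.38
#: default harmonic bond force constant, kJ/(mol nm^2)
DEFAULT_BOND_K = 4184.0

#: default rigid residue windows for full-length TDP-43 (1-based, inclusive):
#: N-terminal domain, the two RNA-recognition motifs, and the conserved
#: helical region of the C-terminal domain.
TDP43_RIGID_WINDOWS = {
    "NTD": (1, 80),
    "RRM1": (105, 177),
    "RRM2": (192, 260),
    "CR": (320, 343),
}


class TopologyError(ValueError):
    pass


def apply_variant(
    sequence: str, mutations: list[tuple[int, str, str]]
) -> str:
    """Apply point mutations to a sequence.

    ``mutations`` is a list of ``(position, from_residue, to_residue)`` with
    1-based positions.  ``from_residue`` must match the sequence; a mismatch
    is a fatal error reporting the position and the residue actually found.
    """
    seq = list(sequence)
    for pos, src, dst in mutations:
        if not 1 <= pos <= len(seq):
            raise TopologyError(
                f"mutation position {pos} outside sequence of length {len(seq)}"
            )
        found = seq[pos - 1]
        if found != src:
            raise TopologyError(
                f"mutation {src}{pos}{dst}: sequence has {found!r} at position {pos}, "
                f"not {src!r}"
            )
        seq[pos - 1] = dst
    return "".join(seq)


def trp_to_ala_mutations(sequence: str) -> list[tuple[int, str, str]]:
    """All Trp->Ala point mutations of a sequence (e.g. the TDP-43 6WtoA variant)."""
    return [(i + 1, "W", "A") for i, c in enumerate(sequence) if c == "W"]


@dataclass
class RigidGroup:
    """A rigid body made of one contiguous residue window of one chain.

    ``start``/``stop`` are 1-based inclusive residue indices within the
    chain.  ``reference`` holds one coordinate (nm) per member residue; the
    group's internal geometry is fixed to this reference during dynamics.
    """

    chain: int
    start: int
    stop: int
    reference: np.ndarray  # (n_members, 3) nm
    name: str = ""

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        n = self.stop - self.start + 1
        if self.stop < self.start:
            raise TopologyError(f"rigid group {self.name!r}: stop < start")
        if self.reference.shape != (n, 3):
            raise TopologyError(
                f"rigid group {self.name!r}: expected {n} reference coordinates, "
                f"got shape {self.reference.shape}"
            )
        if n < 3 or _collinear(self.reference):
            raise TopologyError(
                f"rigid group {self.name!r}: needs >= 3 non-collinear reference sites"
            )

    @property
    def n_members(self) -> int:
        return self.stop - self.start + 1


def _collinear(coords: np.ndarray, tol: float = 1e-9) -> bool:
    c = coords - coords.mean(axis=0)
    # rank < 2 => all points on one line
    s = np.linalg.svd(c, compute_uv=False)
    return s[1] <= tol * max(s[0], 1.0)


@dataclass
class Topology:
    """Beads, bonds, rigid groups and exclusions of a multi-chain system."""

    sequences: list[str]
    masses: np.ndarray  # (N,) amu
    charges: np.ndarray  # (N,) e
    sigmas: np.ndarray  # (N,) nm
    lambdas: np.ndarray  # (N,)
    chain_id: np.ndarray  # (N,) int
    resid: np.ndarray  # (N,) 1-based residue index within chain
    bonds: np.ndarray  # (n_bonds, 2) int bead indices
    bond_r0: float
    bond_k: float
    rigid_groups: list[RigidGroup] = field(default_factory=list)

    # derived, filled by __post_init__
    rigid_of_bead: np.ndarray = field(init=False)  # (N,) group id or -1
    excl_indptr: np.ndarray = field(init=False)  # CSR over beads
    excl_indices: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n = self.n_beads
        self.rigid_of_bead = np.full(n, -1, dtype=np.int64)
        for g, grp in enumerate(self.rigid_groups):
            idx = self.rigid_member_indices(g)
            if np.any(self.rigid_of_bead[idx] >= 0):
                raise TopologyError("rigid groups overlap")
            self.rigid_of_bead[idx] = g
        self._build_exclusions()

    @property
    def n_beads(self) -> int:
        return len(self.masses)

    @property
    def n_chains(self) -> int:
        return len(self.sequences)

    def chain_slice(self, c: int) -> slice:
        first = int(np.searchsorted(self.chain_id, c))
        last = int(np.searchsorted(self.chain_id, c, side="right"))
        return slice(first, last)

    def rigid_member_indices(self, g: int) -> np.ndarray:
        grp = self.rigid_groups[g]
        sl = self.chain_slice(grp.chain)
        base = sl.start
        return np.arange(base + grp.start - 1, base + grp.stop, dtype=np.int64)

    def exclusion_pairs(self) -> set[tuple[int, int]]:
        """All excluded (i, j) pairs with i < j, as a set."""
        out: set[tuple[int, int]] = set()
        for i in range(self.n_beads):
            for j in self.excl_indices[self.excl_indptr[i] : self.excl_indptr[i + 1]]:
                if i < j:
                    out.add((i, int(j)))
        return out

    def _build_exclusions(self) -> None:
        n = self.n_beads
        neigh: list[set[int]] = [set() for _ in range(n)]
        for i, j in self.bonds:
            neigh[int(i)].add(int(j))
            neigh[int(j)].add(int(i))
        for g in range(len(self.rigid_groups)):
            idx = self.rigid_member_indices(g)
            for a in idx:
                neigh[int(a)].update(int(b) for b in idx if b != a)
        indptr = np.zeros(n + 1, dtype=np.int64)
        cols: list[int] = []
        for i in range(n):
            s = sorted(neigh[i])
            cols.extend(s)
            indptr[i + 1] = indptr[i] + len(s)
        self.excl_indptr = indptr
        self.excl_indices = np.asarray(cols, dtype=np.int64)


def build_topology(
    sequences: list[str] | str,
    params: ParameterTable,
    rigid_defs: list[RigidGroup] | None = None,
    bond_r0: float = DEFAULT_BOND_R0,
    bond_k: float = DEFAULT_BOND_K,
) -> Topology:
    """Assemble a :class:`Topology` from chain sequences and a parameter table.

    ``rigid_defs`` reference residue windows by chain index and 1-based
    residue range; each must carry reference coordinates (nm) for its
    members.  Bonds join consecutive residues within each chain only.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    if not sequences:
        raise TopologyError("no sequences given")
    rigid_defs = list(rigid_defs or [])

    codes = "".join(sequences)
    masses = np.array([params[c].mass for c in codes])
    charges = np.array([params[c].charge for c in codes])
    sigmas = np.array([params[c].sigma for c in codes])
    lambdas = np.array([params[c].hydropathy for c in codes])
    chain_id = np.concatenate(
        [np.full(len(s), c, dtype=np.int64) for c, s in enumerate(sequences)]
    )
    resid = np.concatenate(
        [np.arange(1, len(s) + 1, dtype=np.int64) for s in sequences]
    )

    bonds = []
    offset = 0
    for s in sequences:
        for k in range(len(s) - 1):
            bonds.append((offset + k, offset + k + 1))
        offset += len(s)
    bonds_arr = (
        np.asarray(bonds, dtype=np.int64) if bonds else np.empty((0, 2), dtype=np.int64)
    )

    seen: dict[int, list[tuple[int, int]]] = {}
    for grp in rigid_defs:
        if not 0 <= grp.chain < len(sequences):
            raise TopologyError(f"rigid group {grp.name!r}: chain {grp.chain} out of range")
        if grp.stop > len(sequences[grp.chain]):
            raise TopologyError(
                f"rigid group {grp.name!r}: range {grp.start}-{grp.stop} outside chain "
                f"of length {len(sequences[grp.chain])}"
            )
        for a, b in seen.get(grp.chain, []):
            if grp.start <= b and a <= grp.stop:
                raise TopologyError(
                    f"rigid group {grp.name!r}: overlaps another group on chain {grp.chain}"
                )
        seen.setdefault(grp.chain, []).append((grp.start, grp.stop))

    return Topology(
        sequences=list(sequences),
        masses=masses,
        charges=charges,
        sigmas=sigmas,
        lambdas=lambdas,
        chain_id=chain_id,
        resid=resid,
        bonds=bonds_arr,
        bond_r0=bond_r0,
        bond_k=bond_k,
        rigid_groups=rigid_defs,
    )
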