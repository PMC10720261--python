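"""File interfaces: FASTA sequences, Calpha PDB coordinates, run manifests.

Coordinates are nm inside the package and angstrom in PDB files; residue
indices are 1-based everywhere.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser

from .params import CANONICAL_AA


class FastaError(ValueError):
    pass


def read_fasta(path: str | Path, allow_extra_codes: str = "") -> list[tuple[str, str]]:
    """Ordered ``(id, sequence)`` pairs from a FASTA file.

    Sequences are uppercased; any character outside the 20 canonical
    amino-acid codes (plus ``allow_extra_codes``) is fatal, reported with
    its line number.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    allowed = set(CANONICAL_AA) | set(allow_extra_codes.upper())
    out = []
    for rec in records:
        seq = str(rec.seq).upper()
        bad = next((c for c in seq if c not in allowed), None)
        if bad is not None:
            line_no = _find_line(path, bad)
            raise FastaError(
                f"{path}:{line_no}: illegal residue character {bad!r} in record "
                f"{rec.id!r}"
            )
        if not seq:
            raise FastaError(f"{path}: record {rec.id!r} is empty")
        out.append((rec.id, seq))
    return out


def _find_line(path: Path, char: str) -> int:
    for n, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.startswith(">") and char in line.upper():
            return n
    return 0


def write_fasta(path: str | Path, records: list[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


def read_calpha_pdb(
    path: str | Path,
    chain: str = "A",
    residue_range: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Calpha coordinates (nm) and residue numbers from a PDB file.

    Returns one coordinate per residue of ``residue_range`` (1-based,
    inclusive; default all CA-bearing residues of the chain).  Residues in
    the range without a CA atom are fatal, listed by number.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("x", str(path))
    model = next(structure.get_models())
    if chain not in [c.id for c in model]:
        raise ValueError(f"{path}: chain {chain!r} not found")
    coords: dict[int, np.ndarray] = {}
    for res in model[chain]:
        if "CA" in res:
            coords[res.id[1]] = res["CA"].get_coord() / 10.0  # A -> nm
    if residue_range is None:
        if not coords:
            raise ValueError(f"{path}: chain {chain!r} has no CA atoms")
        resids = sorted(coords)
    else:
        lo, hi = residue_range
        resids = list(range(lo, hi + 1))
        missing = [r for r in resids if r not in coords]
        if missing:
            raise ValueError(
                f"{path}: chain {chain!r} is missing CA atoms for residue(s) "
                f"{', '.join(map(str, missing))}"
            )
    return np.array([coords[r] for r in resids]), np.array(resids)


def write_calpha_pdb(
    path: str | Path,
    positions,
    chain_id: np.ndarray,
    resid: np.ndarray,
    sequences: list[str] | None = None,
    box: np.ndarray | None = None,
) -> None:
    """Write bead coordinates as CA-only PDB; ``positions`` may be a single
    frame (N,3) or a stack of frames (F,N,3) written as MODEL records."""
    pos = np.asarray(positions, dtype=float)
    frames = pos[None] if pos.ndim == 2 else pos
    three = {
        "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
        "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
        "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
        "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    }
    with open(path, "w") as fh:
        if box is not None:
            fh.write(
                f"CRYST1{box[0]*10:9.3f}{box[1]*10:9.3f}{box[2]*10:9.3f}"
                f"  90.00  90.00  90.00 P 1           1\n"
            )
        for f, frame in enumerate(frames, start=1):
            if len(frames) > 1:
                fh.write(f"MODEL     {f:4d}\n")
            for i, xyz in enumerate(frame):
                c = int(chain_id[i])
                code = (
                    sequences[c][int(resid[i]) - 1] if sequences is not None else "G"
                )
                resname = three.get(code, "UNK")
                ch = chr(ord("A") + c % 26)
                x, y, z = xyz * 10.0
                fh.write(
                    f"ATOM  {i % 99999 + 1:5d}  CA  {resname} {ch}{int(resid[i]) % 9999:4d}"
                    f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
            fh.write("ENDMDL\n" if len(frames) > 1 else "END\n")


def save_system(path: str | Path, topology, configuration) -> None:
    """Persist a built system (topology + initial configuration) as HDF5."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["sequences"] = json.dumps(topology.sequences)
        fh.attrs["bond_r0"] = topology.bond_r0
        fh.attrs["bond_k"] = topology.bond_k
        for name in ("masses", "charges", "sigmas", "lambdas", "chain_id", "resid", "bonds"):
            fh.create_dataset(name, data=getattr(topology, name))
        fh.create_dataset("positions", data=configuration.positions)
        fh.create_dataset("box", data=configuration.box)
        grp = fh.create_group("rigid")
        for g, rg in enumerate(topology.rigid_groups):
            sub = grp.create_group(str(g))
            sub.attrs["chain"] = rg.chain
            sub.attrs["start"] = rg.start
            sub.attrs["stop"] = rg.stop
            sub.attrs["name"] = rg.name
            sub.create_dataset("reference", data=rg.reference)


def load_system(path: str | Path):
    """Inverse of :func:`save_system`; returns ``(topology, configuration)``."""
    import h5py

    from .topology import RigidGroup, Topology
    from .trajectory import Configuration

    with h5py.File(path, "r") as fh:
        groups = [
            RigidGroup(
                chain=int(sub.attrs["chain"]),
                start=int(sub.attrs["start"]),
                stop=int(sub.attrs["stop"]),
                reference=sub["reference"][...],
                name=str(sub.attrs["name"]),
            )
            for _, sub in sorted(fh["rigid"].items(), key=lambda kv: int(kv[0]))
        ]
        topo = Topology(
            sequences=json.loads(fh.attrs["sequences"]),
            masses=fh["masses"][...],
            charges=fh["charges"][...],
            sigmas=fh["sigmas"][...],
            lambdas=fh["lambdas"][...],
            chain_id=fh["chain_id"][...],
            resid=fh["resid"][...],
            bonds=fh["bonds"][...].astype(np.int64),
            bond_r0=float(fh.attrs["bond_r0"]),
            bond_k=float(fh.attrs["bond_k"]),
            rigid_groups=groups,
        )
        conf = Configuration(fh["positions"][...], fh["box"][...])
    return topo, conf


@dataclass
class RunManifest:
    """Provenance of one simulation run, sufficient to re-run bit-identically."""

    config: dict
    seed: int
    package_version: str
    input_checksums: dict[str, str] = field(default_factory=dict)
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    @staticmethod
    def checksum(path: str | Path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
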