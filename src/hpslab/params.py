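"""Per-residue parameters for the one-bead-per-residue HPS-Urry model.

Each amino acid is a single spherical bead with a mass (amu), a net charge
(elementary charges), a van der Waals diameter sigma (nm), and a
dimensionless hydropathy ("stickiness") lambda that scales the short-range
pair attraction.  The packaged default table follows the HPS-Urry
parameterisation (Urry hydrophobicity scale, mu=1, Delta=0.08); see the
provenance header of ``data/hps_urry_params.tsv``.

Internal units throughout the package: nm, kJ/mol, ps, amu, elementary
charges.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Boltzmann constant, kJ/(mol K)
KB = 0.00831446261815324


@dataclass(frozen=True)
class ResidueParams:
    """Bead parameters of one amino-acid type."""

    code: str
    mass: float  # amu
    charge: float  # elementary charges
    sigma: float  # nm
    hydropathy: float  # lambda, dimensionless

    def __post_init__(self) -> None:
        if len(self.code) != 1:
            raise ValueError(f"residue code must be one letter, got {self.code!r}")
        if self.mass <= 0:
            raise ValueError(f"residue {self.code}: mass must be positive")
        if self.sigma <= 0:
            raise ValueError(f"residue {self.code}: sigma must be positive")
        if abs(self.charge) > 1:
            raise ValueError(f"residue {self.code}: |charge| must be <= 1")
        if not -0.5 <= self.hydropathy <= 1.1:
            raise ValueError(
                f"residue {self.code}: hydropathy {self.hydropathy} outside [-0.5, 1.1]"
            )


class ParameterTable:
    """Lookup table of :class:`ResidueParams` keyed by 1-letter code.

    A *complete* table contains all 20 canonical residues; partial tables are
    allowed for toy systems built from explicit overrides.
    """

    def __init__(self, entries: Iterable[ResidueParams]):
        self._by_code: dict[str, ResidueParams] = {}
        for e in entries:
            if e.code in self._by_code:
                raise ValueError(f"duplicate residue code {e.code!r} in parameter table")
            self._by_code[e.code] = e

    def __getitem__(self, code: str) -> ResidueParams:
        try:
            return self._by_code[code]
        except KeyError:
            raise KeyError(
                f"residue type {code!r} missing from parameter table "
                f"(have: {''.join(sorted(self._by_code))})"
            ) from None

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __len__(self) -> int:
        return len(self._by_code)

    def __iter__(self):
        return iter(self._by_code.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, ParameterTable):
            return NotImplemented
        return self._by_code == other._by_code

    @property
    def codes(self) -> list[str]:
        return sorted(self._by_code)

    def is_complete(self) -> bool:
        return all(c in self._by_code for c in CANONICAL_AA)

    def validate_complete(self) -> None:
        missing = [c for c in CANONICAL_AA if c not in self._by_code]
        if missing:
            raise ValueError(
                f"parameter table incomplete: missing residue(s) {', '.join(missing)}"
            )

    def with_overrides(
        self, overrides: Mapping[str, Mapping[str, float]] | Iterable[ResidueParams]
    ) -> "ParameterTable":
        """Return a new table with some entries replaced or added.

        ``overrides`` is either a mapping ``code -> {field: value}`` (partial
        field updates of existing entries, or full specs for new codes) or an
        iterable of ready :class:`ResidueParams`.
        """
        new = dict(self._by_code)
        if isinstance(overrides, Mapping):
            for code, fields in overrides.items():
                if code in new:
                    new[code] = replace(new[code], **fields)
                else:
                    new[code] = ResidueParams(code=code, **fields)
        else:
            for e in overrides:
                new[e.code] = e
        return ParameterTable(new.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (e.code, e.mass, e.charge, e.sigma, e.hydropathy)
            for e in sorted(self._by_code.values(), key=lambda e: e.code)
        ]
        return pd.DataFrame(rows, columns=["code", "mass", "charge", "sigma", "hydropathy"])

    def write(self, path: str | Path) -> None:
        """Write the table as whitespace-delimited text with a header line."""
        frame = self.to_frame()
        with open(path, "w") as fh:
            fh.write("# hpslab residue parameter table (mass amu, sigma nm)\n")
            frame.to_csv(fh, sep="\t", index=False)


def load_parameter_table(
    path: str | Path | None = None,
    *,
    require_complete: bool = True,
    histidine_charge: float | None = None,
) -> ParameterTable:
    """Load a residue parameter table from delimited text.

    The file is whitespace- or comma-delimited with a header row naming the
    columns ``code mass charge sigma hydropathy``; ``#`` lines are comments.
    With no ``path`` the packaged HPS-Urry table is loaded.

    ``histidine_charge`` optionally overrides the His charge (the default
    table treats His as neutral, appropriate near pH 7).
    """
    if path is None:
        text = (
            resources.files("hpslab").joinpath("data/hps_urry_params.tsv").read_text()
        )
        frame = pd.read_csv(io.StringIO(text), sep=r"[,\s]+", comment="#", engine="python")
    else:
        frame = pd.read_csv(path, sep=r"[,\s]+", comment="#", engine="python")
    expected = ["code", "mass", "charge", "sigma", "hydropathy"]
    missing_cols = [c for c in expected if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"parameter table missing column(s): {', '.join(missing_cols)}")
    entries = [
        ResidueParams(
            code=str(row.code),
            mass=float(row.mass),
            charge=float(row.charge),
            sigma=float(row.sigma),
            hydropathy=float(row.hydropathy),
        )
        for row in frame.itertuples()
    ]
    table = ParameterTable(entries)
    if require_complete:
        table.validate_complete()
    if histidine_charge is not None:
        table = table.with_overrides({"H": {"charge": histidine_charge}})
    return table


def tdp43_sequence() -> str:
    """The 414-residue human TDP-43 sequence (UniProt Q13148)."""
    text = resources.files("hpslab").joinpath("data/tdp43_q13148.fasta").read_text()
    return "".join(line.strip() for line in text.splitlines() if not line.startswith(">"))
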