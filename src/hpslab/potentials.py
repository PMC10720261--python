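"""Pair potentials of the HPS-Urry model.

Two nonbonded terms act between all non-excluded bead pairs:

* an Ashbaugh–Hatch potential — a Lennard-Jones core whose attractive part
  is scaled by the mean hydropathy ``lambda_bar`` of the pair, so that
  ``lambda_bar = 1`` recovers full LJ attraction and ``lambda_bar = 0`` a
  purely repulsive (Weeks–Chandler–Andersen) wall;
* Debye–Hückel screened electrostatics between charged beads.

Consecutive beads are joined by stiff harmonic bonds.  Both nonbonded terms
are truncated (not shifted) at their cutoffs, which matches common
residue-level implementations but means absolute energies carry a small
cutoff dependence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .topology import Topology

#: e^2 / (4 pi eps0) in kJ nm / mol — Coulomb prefactor for charges in e
COULOMB_K = 138.935458


class OverlapError(RuntimeError):
    """Raised when two beads come closer than the fatal-overlap threshold."""


@dataclass(frozen=True)
class PairInteractionParams:
    """Global nonbonded interaction parameters.

    Defaults follow residue-level HPS practice: well depth
    ``epsilon = 0.8368`` kJ/mol (0.2 kcal/mol), dielectric 80, Debye length
    1.0 nm (roughly 100 mM monovalent salt).
    """

    epsilon: float = 0.8368  # kJ/mol
    lj_cutoff: float = 2.0  # nm
    debye_length: float = 1.0  # nm
    dielectric: float = 80.0
    coulomb_cutoff: float = 3.5  # nm
    skin: float = 0.3  # neighbor-list skin, nm

    def __post_init__(self) -> None:
        for name in ("epsilon", "lj_cutoff", "debye_length", "dielectric", "coulomb_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def ah_pair_energy(
    r, sigma_i, sigma_j, lambda_i, lambda_j, epsilon: float = 0.8368
):
    """Ashbaugh–Hatch pair energy (kJ/mol) at separation ``r`` (nm).

    With ``sbar = (sigma_i + sigma_j)/2``, ``lbar = (lambda_i + lambda_j)/2``
    and ``phi`` the 12-6 Lennard-Jones potential of diameter ``sbar``::

        U(r) = phi(r) + (1 - lbar) * epsilon   for r <= 2^(1/6) sbar
        U(r) = lbar * phi(r)                   otherwise

    Both branches equal ``-lbar * epsilon`` at the crossover, so U is
    continuous.  Vectorised over ``r``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise OverlapError("ah_pair_energy: r must be positive (bead overlap)")
    sbar = 0.5 * (sigma_i + sigma_j)
    lbar = 0.5 * (lambda_i + lambda_j)
    sr6 = (sbar / r) ** 6
    phi = 4.0 * epsilon * (sr6 * sr6 - sr6)
    inside = r <= 2.0 ** (1.0 / 6.0) * sbar
    out = np.where(inside, phi + (1.0 - lbar) * epsilon, lbar * phi)
    return out.item() if out.ndim == 0 else out


def dh_pair_energy(r, q_i, q_j, dielectric: float = 80.0, debye_length: float = 1.0):
    """Debye–Hückel screened Coulomb energy (kJ/mol) at separation ``r`` (nm)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise OverlapError("dh_pair_energy: r must be positive (bead overlap)")
    out = COULOMB_K * q_i * q_j * np.exp(-r / debye_length) / (dielectric * r)
    return out.item() if out.ndim == 0 else out


def total_energy_forces(
    positions: np.ndarray,
    box: np.ndarray,
    topology: Topology,
    pair_params: PairInteractionParams = PairInteractionParams(),
) -> tuple[float, np.ndarray]:
    """Total potential energy (kJ/mol) and per-bead forces (kJ/mol/nm).

    Nonbonded terms run over a cell-list neighbor search under the
    minimum-image convention; excluded pairs (bonded and intra-rigid)
    contribute nothing.  A nonbonded pair closer than 0.05 nm raises
    :class:`OverlapError` naming the pair.
    """
    pos = np.ascontiguousarray(positions, dtype=float)
    box = np.ascontiguousarray(box, dtype=float)
    pairs = _kernels.build_pairs(
        pos,
        box,
        pair_params.lj_cutoff + pair_params.skin,
        topology.excl_indptr,
        topology.excl_indices,
    )
    cpairs = _kernels.build_pairs_subset(
        pos,
        np.flatnonzero(topology.charges != 0.0),
        box,
        pair_params.coulomb_cutoff + pair_params.skin,
        topology.excl_indptr,
        topology.excl_indices,
    )
    indptr, jcol, sb2, lb = _kernels.pairs_to_csr(
        pairs, topology.sigmas, topology.lambdas, len(pos)
    )
    energy, forces, min_r, mi, mj = _kernels.energy_forces(
        pos,
        box,
        indptr,
        jcol,
        sb2,
        lb,
        cpairs,
        topology.charges,
        pair_params.epsilon,
        pair_params.lj_cutoff,
        pair_params.debye_length,
        pair_params.dielectric,
        pair_params.coulomb_cutoff,
        topology.bonds,
        topology.bond_r0,
        topology.bond_k,
    )
    if min_r < _kernels.OVERLAP_R:
        raise OverlapError(
            f"beads {mi} and {mj} overlap at r = {min_r:.4f} nm "
            f"(< {_kernels.OVERLAP_R} nm)"
        )
    return float(energy), forces
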