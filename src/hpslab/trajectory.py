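"""Configurations and trajectories, with HDF5 storage.

Coordinates are stored *unwrapped* (bonds never straddle the periodic
boundary in the stored coordinates); analysis code wraps into the primary
cell where needed.  Units: nm, ps, amu.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np


@dataclass
class Configuration:
    """A single frame: bead coordinates in an orthorhombic periodic box."""

    positions: np.ndarray  # (N, 3) nm
    box: np.ndarray  # (3,) nm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def wrapped(self) -> np.ndarray:
        return np.mod(self.positions, self.box)


@dataclass
class Trajectory:
    """Frames saved at fixed step intervals, plus per-frame observables."""

    positions: np.ndarray  # (F, N, 3) nm, unwrapped
    box: np.ndarray  # (3,) nm
    steps: np.ndarray  # (F,) integrator step index
    time: np.ndarray  # (F,) ps
    potential_energy: np.ndarray  # (F,) kJ/mol
    kinetic_temperature: np.ndarray  # (F,) K
    rg_mean: np.ndarray  # (F,) mean per-chain Rg, nm
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[1]

    def frame(self, f: int) -> Configuration:
        return Configuration(self.positions[f], self.box)

    def slice_frames(self, start: int | None = None, stop: int | None = None) -> "Trajectory":
        sl = slice(start, stop)
        return Trajectory(
            positions=self.positions[sl],
            box=self.box,
            steps=self.steps[sl],
            time=self.time[sl],
            potential_energy=self.potential_energy[sl],
            kinetic_temperature=self.kinetic_temperature[sl],
            rg_mean=self.rg_mean[sl],
            metadata=dict(self.metadata),
        )

    def discard_equilibration(self, fraction: float = 2.0 / 7.0) -> "Trajectory":
        """Drop the leading ``fraction`` of frames (default 2/7)."""
        if not 0 <= fraction < 1:
            raise ValueError("fraction must be in [0, 1)")
        return self.slice_frames(int(np.ceil(fraction * self.n_frames)), None)

    def save(self, path: str | Path) -> None:
        # track_times=False keeps identical runs byte-identical on disk
        with h5py.File(path, "w") as fh:
            fh.create_dataset(
                "positions", data=self.positions, compression="gzip", track_times=False
            )
            for name in (
                "box", "steps", "time", "potential_energy",
                "kinetic_temperature", "rg_mean",
            ):
                fh.create_dataset(name, data=getattr(self, name), track_times=False)
            fh.attrs["metadata"] = json.dumps(self.metadata, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "Trajectory":
        with h5py.File(path, "r") as fh:
            return cls(
                positions=fh["positions"][...],
                box=fh["box"][...],
                steps=fh["steps"][...],
                time=fh["time"][...],
                potential_energy=fh["potential_energy"][...],
                kinetic_temperature=fh["kinetic_temperature"][...],
                rg_mean=fh["rg_mean"][...],
                metadata=json.loads(fh.attrs.get("metadata", "{}")),
            )
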