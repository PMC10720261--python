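"""Observables: Rg, z-density profiles, coexistence concentrations,
contact maps, per-residue contact statistics, and in-condensate diffusion.

All routines assume the package's own trajectories (unwrapped coordinates,
orthorhombic periodic box).  Where wrapped input is possible the caller
unwraps first (:func:`unwrap_chains`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .topology import Topology
from .trajectory import Trajectory

#: mg/mL per amu/nm^3
AMU_PER_NM3_TO_MG_PER_ML = 1.66053906892


# ---------------------------------------------------------------------------
# radius of gyration
# ---------------------------------------------------------------------------


def radius_of_gyration(
    positions: np.ndarray,
    masses: np.ndarray | None = None,
    selection: np.ndarray | None = None,
) -> float:
    """Mass-weighted radius of gyration (nm) of a set of beads.

    ``positions`` must be unwrapped (no periodic jumps inside the selection).
    Equal masses are assumed when ``masses`` is None.
    """
    pos = np.asarray(positions, dtype=float)
    if selection is not None:
        pos = pos[selection]
        masses = None if masses is None else np.asarray(masses)[selection]
    if len(pos) == 0:
        raise ValueError("radius_of_gyration: empty selection")
    m = np.ones(len(pos)) if masses is None else np.asarray(masses, dtype=float)
    com = (m[:, None] * pos).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((pos - com) ** 2).sum(axis=1)).sum() / m.sum()))


def unwrap_chains(
    positions: np.ndarray, box: np.ndarray, chain_id: np.ndarray
) -> np.ndarray:
    """Undo periodic wrapping by walking each chain bead-to-bead.

    Consecutive beads are assumed closer than half the box in every
    dimension (true for bonded chains), so each step takes the minimum
    image relative to its predecessor.
    """
    pos = np.asarray(positions, dtype=float).copy()
    box = np.asarray(box, dtype=float)
    for c in np.unique(chain_id):
        idx = np.flatnonzero(chain_id == c)
        for prev, cur in zip(idx[:-1], idx[1:]):
            d = pos[cur] - pos[prev]
            pos[cur] = pos[prev] + d - box * np.rint(d / box)
    return pos


def chain_rg(traj: Trajectory, topology: Topology, chain: int) -> np.ndarray:
    """Per-frame Rg (nm) of one chain."""
    sl = topology.chain_slice(chain)
    m = topology.masses[sl]
    return np.array([radius_of_gyration(p[sl], m) for p in traj.positions])


# ---------------------------------------------------------------------------
# density profile and coexistence
# ---------------------------------------------------------------------------


@dataclass
class DensityProfile:
    """Mass-density profile along z, per frame and averaged.

    ``concentration`` is the frame-averaged mass concentration per bin in
    mg/mL; ``frame_mass`` keeps the per-frame mass histograms (amu) for
    block averaging.  Frames are recentered so the dense phase sits at z=0.
    """

    bin_centers: np.ndarray  # (B,) nm, z relative to the dense-phase center
    concentration: np.ndarray  # (B,) mg/mL
    count_density: np.ndarray  # (B,) beads/nm^3
    frame_mass: np.ndarray  # (F, B) amu per bin
    bin_width: float
    bin_volume: float  # nm^3
    box: np.ndarray
    centering: str
    offsets: np.ndarray  # (F,) applied z-shift per frame, nm

    @property
    def n_frames(self) -> int:
        return len(self.frame_mass)

    def block_concentration(self, n_blocks: int) -> np.ndarray:
        """(n_blocks, B) concentrations from contiguous frame blocks."""
        edges = np.linspace(0, self.n_frames, n_blocks + 1).astype(int)
        out = np.empty((n_blocks, len(self.bin_centers)))
        for b in range(n_blocks):
            chunk = self.frame_mass[edges[b] : edges[b + 1]]
            out[b] = chunk.mean(axis=0) / self.bin_volume * AMU_PER_NM3_TO_MG_PER_ML
        return out


def _largest_cluster_mask(
    wrapped: np.ndarray, box: np.ndarray, chain_id: np.ndarray, cluster_cutoff: float
) -> np.ndarray:
    """Boolean mask of beads in the largest distance-based cluster of chains."""
    tree = cKDTree(wrapped, boxsize=box)
    pairs = tree.query_pairs(cluster_cutoff, output_type="ndarray")
    n_chains = int(chain_id.max()) + 1
    parent = np.arange(n_chains)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in pairs:
        ci, cj = int(chain_id[i]), int(chain_id[j])
        if ci != cj:
            ri, rj = find(ci), find(cj)
            if ri != rj:
                parent[ri] = rj
    roots = np.array([find(c) for c in range(n_chains)])
    counts = np.bincount(roots, minlength=n_chains)
    biggest = int(np.argmax(counts))
    return np.isin(chain_id, np.flatnonzero(roots == biggest))


def _circular_center(z: np.ndarray, w: np.ndarray, lz: float) -> float:
    theta = 2.0 * np.pi * z / lz
    s = (w * np.sin(theta)).sum()
    c = (w * np.cos(theta)).sum()
    return float(np.mod(np.arctan2(s, c) / (2.0 * np.pi) * lz, lz))


def density_profile(
    traj: Trajectory,
    topology: Topology,
    bin_width: float = 1.0,
    centering: str = "cluster",
    frame_window: tuple[int, int] | None = None,
    cluster_cutoff: float = 1.2,
) -> DensityProfile:
    """Mass concentration along z, recentered per frame.

    ``centering``: ``"cluster"`` centers each frame on the mass-weighted
    (circular) mean z of the largest inter-chain cluster (cutoff
    ``cluster_cutoff`` nm between beads of different chains); ``"com"`` uses
    all beads; ``"none"`` leaves the box center at z=0.
    """
    frames = traj.positions if frame_window is None else traj.positions[slice(*frame_window)]
    if len(frames) == 0:
        raise ValueError("density_profile: no frames in window")
    box = traj.box
    lz = float(box[2])
    nbins = max(1, int(round(lz / bin_width)))
    edges = np.linspace(-lz / 2, lz / 2, nbins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    bin_volume = float(box[0] * box[1] * (edges[1] - edges[0]))
    masses = topology.masses

    frame_mass = np.empty((len(frames), nbins))
    offsets = np.empty(len(frames))
    for f, pos in enumerate(frames):
        wrapped = np.mod(pos, box)
        z = wrapped[:, 2]
        if centering == "cluster" and topology.n_chains > 1:
            mask = _largest_cluster_mask(wrapped, box, topology.chain_id, cluster_cutoff)
            center = _circular_center(z[mask], masses[mask], lz)
        elif centering in ("com", "cluster"):
            center = _circular_center(z, masses, lz)
        elif centering == "none":
            center = lz / 2
        else:
            raise ValueError(f"unknown centering mode {centering!r}")
        offsets[f] = center
        zc = np.mod(z - center + lz / 2, lz) - lz / 2
        frame_mass[f], _ = np.histogram(zc, bins=edges, weights=masses)

    mean_mass = frame_mass.mean(axis=0)
    return DensityProfile(
        bin_centers=centers,
        concentration=mean_mass / bin_volume * AMU_PER_NM3_TO_MG_PER_ML,
        count_density=_count_density(frames, box, edges, offsets) / bin_volume,
        frame_mass=frame_mass,
        bin_width=float(edges[1] - edges[0]),
        bin_volume=bin_volume,
        box=box.copy(),
        centering=centering,
        offsets=offsets,
    )


def _count_density(frames, box, edges, offsets) -> np.ndarray:
    lz = float(box[2])
    acc = np.zeros(len(edges) - 1)
    for f, pos in enumerate(frames):
        z = np.mod(pos[:, 2], lz)
        zc = np.mod(z - offsets[f] + lz / 2, lz) - lz / 2
        h, _ = np.histogram(zc, bins=edges)
        acc += h
    return acc / len(frames)


@dataclass
class CoexistenceResult:
    """Dilute- and dense-phase concentrations from a slab profile."""

    c_sat: float  # mg/mL, dilute phase
    c_dense: float  # mg/mL
    c_sat_se: float
    c_dense_se: float
    phase_separated: bool
    dense_window: tuple[float, float]  # z-range, nm
    dilute_window: float  # |z| beyond this, nm
    n_blocks: int

    def __post_init__(self) -> None:
        if self.phase_separated and not (self.c_dense > self.c_sat >= 0):
            raise ValueError("coexistence requires c_dense > c_sat >= 0")


def coexistence_densities(
    profile: DensityProfile,
    dilute_margin: float = 15.0,
    n_blocks: int = 5,
    separation_ratio: float = 2.0,
) -> CoexistenceResult:
    """Estimate c_dense and c_sat from an averaged slab profile.

    The dense plateau is the central 50% of the contiguous region above half
    the maximum concentration; the dilute phase is everything farther than
    the half-max interface plus ``dilute_margin`` (nm).  Uncertainties are
    standard errors over ``n_blocks`` contiguous frame blocks.  A profile
    whose maximum is below ``separation_ratio`` times the box-average
    concentration is flagged as not phase-separated (c_sat = c_dense =
    overall mean).
    """
    z = profile.bin_centers
    conc = profile.concentration
    # light smoothing for interface detection only
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(conc, kernel, mode="same")
    c_max = float(smooth.max())
    c_mean = float(conc.mean())

    if c_mean <= 0 or c_max < separation_ratio * c_mean:
        return CoexistenceResult(
            c_sat=c_mean,
            c_dense=c_mean,
            c_sat_se=float("nan"),
            c_dense_se=float("nan"),
            phase_separated=False,
            dense_window=(float("nan"), float("nan")),
            dilute_window=float("nan"),
            n_blocks=n_blocks,
        )

    above = smooth >= 0.5 * c_max
    imax = int(np.argmax(smooth))
    lo = imax
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = imax
    while hi < len(z) - 1 and above[hi + 1]:
        hi += 1
    z_lo, z_hi = float(z[lo]), float(z[hi])
    width = z_hi - z_lo
    dense_lo, dense_hi = z_lo + 0.25 * width, z_hi - 0.25 * width
    dense_mask = (z >= dense_lo) & (z <= dense_hi)
    dilute_mask = (z < z_lo - dilute_margin) | (z > z_hi + dilute_margin)
    if not dilute_mask.any():
        raise ValueError(
            "coexistence_densities: no dilute bins beyond the interface + margin; "
            "reduce dilute_margin or use a longer box"
        )

    blocks = profile.block_concentration(n_blocks)
    dense_b = blocks[:, dense_mask].mean(axis=1)
    dilute_b = blocks[:, dilute_mask].mean(axis=1)
    return CoexistenceResult(
        c_sat=float(conc[dilute_mask].mean()),
        c_dense=float(conc[dense_mask].mean()),
        c_sat_se=float(dilute_b.std(ddof=1) / np.sqrt(n_blocks)),
        c_dense_se=float(dense_b.std(ddof=1) / np.sqrt(n_blocks)),
        phase_separated=True,
        dense_window=(dense_lo, dense_hi),
        dilute_window=float(z_hi + dilute_margin),
        n_blocks=n_blocks,
    )


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------


@dataclass
class ContactMap:
    """Time-averaged residue–residue contact frequencies.

    ``matrix[a, b]`` is the fraction of (frame, unit) observations in which
    any bead of residue ``a+1`` lies within ``cutoff`` of any bead of
    residue ``b+1``; units are chains (intra mode) or chain pairs (inter
    mode with ``normalization="pairs"``) or whole frames (inter with
    ``normalization="frame"``).
    """

    matrix: np.ndarray  # (R, R)
    cutoff: float
    mode: str  # "intra" | "inter"
    n_frames: int
    normalization: str = "pairs"
    replicate: int | None = None

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("contact map must be symmetric")
        if self.matrix.min() < 0 or self.matrix.max() > 1 + 1e-12:
            raise ValueError("contact frequencies must lie in [0, 1]")


def contact_map(
    traj: Trajectory,
    topology: Topology,
    cutoff: float = 0.8,
    mode: str = "inter",
    frame_window: tuple[int, int] | None = None,
    min_seq_separation: int = 3,
    normalization: str = "pairs",
) -> ContactMap:
    """Residue–residue contact frequencies under a distance cutoff.

    All chains must share one sequence length.  ``intra`` mode averages the
    within-chain contact indicator over chains and frames, skipping pairs
    closer than ``min_seq_separation`` in sequence (default skips |a-b| <= 2).
    ``inter`` mode counts contacts between distinct chains, normalised per
    (frame, chain pair) (``"pairs"``) or per frame (``"frame"``).
    """
    if cutoff <= 0:
        raise ValueError("contact cutoff must be positive")
    if mode not in ("intra", "inter"):
        raise ValueError(f"unknown contact mode {mode!r}")
    lengths = {len(s) for s in topology.sequences}
    if len(lengths) != 1:
        raise ValueError("contact_map requires chains of equal length")
    nres = lengths.pop()
    n_chains = topology.n_chains
    if mode == "inter" and n_chains < 2:
        raise ValueError("inter-chain contact map needs at least two chains")

    frames = traj.positions if frame_window is None else traj.positions[slice(*frame_window)]
    if len(frames) == 0:
        raise ValueError("contact_map: no frames in window")
    box = traj.box
    chain_id = topology.chain_id
    resid0 = topology.resid - 1

    acc = np.zeros((nres, nres))
    for pos in frames:
        wrapped = np.mod(pos, box)
        tree = cKDTree(wrapped, boxsize=box)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if mode == "intra":
            seen: set[tuple[int, int, int]] = set()
            for i, j in pairs:
                ci, cj = int(chain_id[i]), int(chain_id[j])
                if ci != cj:
                    continue
                a, b = int(resid0[i]), int(resid0[j])
                if abs(a - b) < min_seq_separation:
                    continue
                if a > b:
                    a, b = b, a
                seen.add((ci, a, b))
            for _, a, b in seen:
                acc[a, b] += 1.0
        else:
            seen_pairs: set[tuple[int, int, int, int]] = set()
            frame_seen: set[tuple[int, int]] = set()
            for i, j in pairs:
                ci, cj = int(chain_id[i]), int(chain_id[j])
                if ci == cj:
                    continue
                a, b = int(resid0[i]), int(resid0[j])
                if ci > cj:
                    ci, cj = cj, ci
                    a, b = b, a
                seen_pairs.add((ci, cj, a, b))
            for _, _, a, b in seen_pairs:
                if normalization == "frame":
                    frame_seen.add((min(a, b), max(a, b)))
                else:
                    # an (a, b) contact between chains (c, c') is an (b, a)
                    # contact of the ordered pair (c', c)
                    acc[a, b] += 1.0
                    acc[b, a] += 1.0
            for a, b in frame_seen:
                acc[a, b] += 1.0
                if a != b:
                    acc[b, a] += 1.0

    if mode == "intra":
        acc = acc + np.triu(acc, 1).T  # symmetrise from upper triangle
        denom = len(frames) * n_chains
    elif normalization == "pairs":
        denom = len(frames) * (n_chains * (n_chains - 1))  # ordered chain pairs
    elif normalization == "frame":
        denom = len(frames)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return ContactMap(
        matrix=acc / denom,
        cutoff=cutoff,
        mode=mode,
        n_frames=len(frames),
        normalization=normalization,
    )


def per_residue_contacts(
    maps: ContactMap | list[ContactMap], convention: str = "sum"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue contact statistic with cross-replicate SE.

    ``convention="sum"`` reports the row sum of each map (average number of
    residue partners in contact); ``"mean"`` the row mean (a probability
    under per-pair normalisation).  Returns ``(mean, se)``; ``se`` is zero
    for a single replicate.
    """
    if isinstance(maps, ContactMap):
        maps = [maps]
    if not maps:
        raise ValueError("per_residue_contacts: no maps")
    shape = maps[0].matrix.shape
    if any(m.matrix.shape != shape for m in maps):
        raise ValueError("per_residue_contacts: inconsistent map shapes across replicates")
    if convention == "sum":
        rows = np.stack([m.matrix.sum(axis=1) for m in maps])
    elif convention == "mean":
        rows = np.stack([m.matrix.mean(axis=1) for m in maps])
    else:
        raise ValueError(f"unknown convention {convention!r}")
    mean = rows.mean(axis=0)
    se = (
        rows.std(axis=0, ddof=1) / np.sqrt(len(maps))
        if len(maps) > 1
        else np.zeros(shape[0])
    )
    return mean, se


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------


@dataclass
class DiffusionResult:
    D: float  # nm^2/ps
    r_squared: float
    loglog_slope: float
    warning: str | None = None


def msd_diffusion(
    traj: Trajectory,
    topology: Topology,
    fit_window: tuple[float, float],
    max_lags: int = 200,
) -> DiffusionResult:
    """Chain-COM diffusion coefficient from MSD(t) = 6 D t.

    COM displacements use the stored unwrapped coordinates, averaged over
    chains and sliding time origins.  ``fit_window`` is a (t_min, t_max)
    lag-time range in ps.  A log-log MSD slope well above 1 (ballistic or
    drifting motion) triggers a warning in the result.
    """
    if traj.n_frames < 3:
        raise ValueError("msd_diffusion: trajectory too short")
    t = traj.time - traj.time[0]
    dt_frame = float(t[1] - t[0])
    if fit_window[1] > t[-1]:
        raise ValueError(
            f"msd_diffusion: fit window extends to {fit_window[1]} ps but the "
            f"trajectory covers only {t[-1]} ps"
        )
    coms = np.stack(
        [
            (
                topology.masses[topology.chain_slice(c), None]
                * traj.positions[:, topology.chain_slice(c)]
            ).sum(axis=1)
            / topology.masses[topology.chain_slice(c)].sum()
            for c in range(topology.n_chains)
        ],
        axis=1,
    )  # (F, C, 3)

    nf = len(coms)
    lags = np.unique(np.linspace(1, nf - 1, min(max_lags, nf - 1)).astype(int))
    msd = np.empty(len(lags))
    for k, lag in enumerate(lags):
        d = coms[lag:] - coms[:-lag]
        msd[k] = float((d**2).sum(axis=2).mean())
    tau = lags * dt_frame

    sel = (tau >= fit_window[0]) & (tau <= fit_window[1])
    if sel.sum() < 2:
        raise ValueError("msd_diffusion: fewer than 2 lag points in fit window")
    A = np.vstack([tau[sel], np.ones(sel.sum())]).T
    coef, *_ = np.linalg.lstsq(A, msd[sel], rcond=None)
    slope, intercept = coef
    pred = A @ coef
    ss_res = float(((msd[sel] - pred) ** 2).sum())
    ss_tot = float(((msd[sel] - msd[sel].mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    pos_mask = sel & (msd > 0) & (tau > 0)
    if pos_mask.sum() >= 2:
        p = np.polyfit(np.log(tau[pos_mask]), np.log(msd[pos_mask]), 1)
        alpha = float(p[0])
    else:
        alpha = float("nan")
    warning = None
    if alpha > 1.5:
        warning = (
            f"MSD grows as t^{alpha:.2f} in the fit window: motion is not "
            "diffusive (ballistic or drifting); D estimate unreliable"
        )
    elif ss_tot > 0 and r2 < 0.9:
        warning = f"poor linear MSD fit (R^2 = {r2:.3f})"
    return DiffusionResult(
        D=float(max(slope, 0.0) / 6.0), r_squared=r2, loglog_slope=alpha, warning=warning
    )
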