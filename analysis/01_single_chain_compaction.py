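"""Single-chain compaction of full-length TDP-43: WT versus the Trp-free
6WtoA variant.

Runs residue-level implicit-solvent (HPS-Urry) Langevin dynamics of one
414-residue chain with the four structured regions (NTD, RRM1, RRM2, CR
320-343) held rigid, at 310 K, and compares the radius-of-gyration
ensembles.  Removing the six tryptophans weakens intramolecular attraction
(lambda drops from 0.92 to 0.52 at six positions), so the 6WtoA ensemble
should be more expanded than WT.

At the default desk scale (1e6 steps = 10 ns with accelerated Langevin
sampling) the ensembles are not fully converged; pass --steps to extend.
Writes results/single_chain_rg.tsv.
"""

import argparse
import sys
from pathlib import Path

import numpy as np

from hpslab.dynamics import SimulationConfig, init_state, langevin_step, run_simulation
from hpslab.potentials import PairInteractionParams
from hpslab.synthetic import tdp43_topology
from hpslab.sysbuild import initial_single_chain, relax

BOX = (25.0, 25.0, 25.0)


def run_variant(variant: str, steps: int, seed: int, tau: float = 100.0):
    topo = tdp43_topology(variant)
    pp = PairInteractionParams(skin=0.4)
    conf = relax(initial_single_chain(topo, BOX, seed=seed), topo, n_sweeps=200)
    # strong-coupling burn-in to shed the packing heat
    cfg_eq = SimulationConfig(temperature=310.0, dt=0.01, tau_damp=5.0,
                              n_steps=50_000, save_interval=50_000,
                              seed=seed, box=BOX)
    state = init_state(topo, conf, cfg_eq)
    langevin_step(state, topo, pp, cfg_eq, n_steps=50_000)
    cfg = SimulationConfig(temperature=310.0, dt=0.01, tau_damp=tau,
                           n_steps=steps, save_interval=5_000,
                           seed=seed + 1, box=BOX)
    traj = run_simulation(topo, state, cfg, pp)
    rg = traj.rg_mean
    prod = rg[len(rg) * 2 // 7:]  # discard the first 2/7 as equilibration
    return float(prod.mean()), float(prod.std(ddof=1) / np.sqrt(len(prod))), rg


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--steps", type=int, default=1_000_000)
    ap.add_argument("--seeds", type=int, nargs="+", default=[3, 4])
    ap.add_argument("--out", default="results/single_chain_rg.tsv")
    args = ap.parse_args(argv)

    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for variant in ("WT", "6WtoA"):
        for seed in args.seeds:
            mean, se, _ = run_variant(variant, args.steps, seed)
            rows.append((variant, seed, mean, se))
            print(f"{variant} seed={seed}: Rg = {mean:.3f} +- {se:.3f} nm")

    with open(args.out, "w") as fh:
        fh.write("# single-chain TDP-43 Rg at 310 K, HPS-Urry, rigid domains; "
                 f"steps={args.steps}, block-mean over last 5/7 of each run\n")
        fh.write("variant\tseed\trg_nm\trg_se_nm\n")
        for r in rows:
            fh.write(f"{r[0]}\t{r[1]}\t{r[2]:.4f}\t{r[3]:.4f}\n")

    wt = np.mean([r[2] for r in rows if r[0] == "WT"])
    var = np.mean([r[2] for r in rows if r[0] == "6WtoA"])
    print(f"\nmean Rg: WT {wt:.3f} nm, 6WtoA {var:.3f} nm "
          f"({'expanded' if var > wt else 'NOT expanded'} by Trp removal)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
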