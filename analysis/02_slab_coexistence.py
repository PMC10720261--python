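"""Slab coexistence of a sticky homopolymer: phase separation is monotone
in temperature.

Packs 30 sticky 50-mers (uniform hydropathy lambda = 1.0) into the center
of an elongated box, runs NVT Langevin dynamics at a low and a high
temperature, and measures the dense/dilute coexistence concentrations from
the z-density profile.  At 310 K the system keeps a condensed slab
coexisting with a sparse vapor of chains (dense/dilute ratio above 10); at
600 K the profile flattens and the coexistence detector flags "not
phase-separated".  Temperatures far below the transition are best avoided
for quantitative c_sat work at desk scale: a deep quench freezes
coarsening, and chains trapped outside the slab inflate the apparent
dilute-phase concentration.

Writes results/slab_coexistence.tsv.
"""

import argparse
import sys
from pathlib import Path

from hpslab.analysis import coexistence_densities, density_profile
from hpslab.dynamics import SimulationConfig, run_simulation
from hpslab.potentials import PairInteractionParams
from hpslab.synthetic import ToySequenceSpec, make_toy_system
from hpslab.sysbuild import SlabSpec, build_slab, relax
from hpslab.topology import build_topology

BOX = (10.0, 10.0, 40.0)


def run_slab(temperature: float, steps: int, seed: int):
    seq, table = make_toy_system(
        ToySequenceSpec("sticky_homopolymer", length=50, stickiness=1.0)
    )
    topo = build_topology([seq] * 30, table)
    spec = SlabSpec(box=BOX, n_chains=30, z_window_fraction=0.15)
    conf = relax(build_slab(spec, topo, seed=seed), topo, n_sweeps=300)
    # 1.5 nm short-range cutoff: for 0.6 nm beads the discarded tail is
    # ~2% of epsilon, and the neighbor lists stay small
    pp = PairInteractionParams(lj_cutoff=1.5, skin=0.4)
    cfg = SimulationConfig(temperature=temperature, dt=0.01, tau_damp=100.0,
                           n_steps=steps, save_interval=2_500,
                           seed=seed, box=BOX)
    traj = run_simulation(topo, conf, cfg, pp)
    prof = density_profile(traj.discard_equilibration(), topo, bin_width=1.0)
    return coexistence_densities(prof, dilute_margin=5.0)


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--steps", type=int, default=500_000)
    ap.add_argument("--seed", type=int, default=5)
    ap.add_argument("--temperatures", type=float, nargs="+", default=[310.0, 600.0])
    ap.add_argument("--out", default="results/slab_coexistence.tsv")
    args = ap.parse_args(argv)

    Path(args.out).parent.mkdir(parents=True, exist_ok=True)
    with open(args.out, "w") as fh:
        fh.write("# sticky homopolymer (30 x 50 beads, lambda=1.0) slab "
                 f"coexistence; steps={args.steps}\n")
        fh.write("temperature_K\tphase_separated\tc_dense_mg_ml\tc_dense_se\t"
                 "c_sat_mg_ml\tc_sat_se\n")
        for t in args.temperatures:
            res = run_slab(t, args.steps, args.seed)
            fh.write(f"{t}\t{res.phase_separated}\t{res.c_dense:.3f}\t"
                     f"{res.c_dense_se:.3f}\t{res.c_sat:.4f}\t{res.c_sat_se:.4f}\n")
            if res.phase_separated:
                ratio = res.c_dense / max(res.c_sat, 1e-9)
                print(f"T={t:.0f} K: phase-separated, c_dense={res.c_dense:.0f} "
                      f"mg/mL, c_sat={res.c_sat:.2f} mg/mL (ratio {ratio:.0f})")
            else:
                print(f"T={t:.0f} K: not phase-separated (flat profile)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
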