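# hpslab

Residue-level, implicit-solvent simulations of protein phase separation,
built around full-length TDP-43 — a 414-residue RNA-binding protein whose
aggregation is linked to ALS and related neurodegeneration.  TDP-43
combines folded domains (NTD, RRM1, RRM2, and a conserved C-terminal
helix) with long disordered linkers and a low-complexity C-terminal
domain, which makes its self-assembly expensive to sample at atomistic
resolution.  `hpslab` is for researchers who want to study such
multidomain condensation with a one-bead-per-residue model on a single
CPU.

## Model

Each residue is one bead.  Beads interact through the hydropathy-scaled
(HPS-Urry) Ashbaugh–Hatch potential

    U(r) = Φ_LJ(r) + (1 − λ̄)ε   (r ≤ 2^{1/6} σ̄),
    U(r) = λ̄ Φ_LJ(r)            (r > 2^{1/6} σ̄),

with σ̄, λ̄ the arithmetic means of the per-residue diameters and Urry
hydropathies, ε = 0.2 kcal/mol, plus Debye–Hückel electrostatics
(ε_r = 80, κ⁻¹ = 1 nm) and stiff harmonic bonds (r₀ = 0.38 nm).  Folded
domains are held rigid (quaternion rigid-body dynamics); everything is
propagated by a BAOAB Langevin integrator with friction γ_i = m_i/τ
(production protocol: 310 K, dt = 10 fs, τ = 1000 ps).  Slab-coexistence
setups (e.g. 100 chains in a 20×20×168 nm box) give flat interfaces from
which dense- and dilute-phase concentrations — hence the saturation
concentration c_sat — are measured, along with Rg, inter/intra-chain
contact maps at a 0.8 nm cutoff, and in-condensate diffusion.

See `docs/methods.md` for the full model description and numerical
choices.

## Worked example

Build a sticky 50-mer homopolymer slab and measure its coexistence
densities:

```
hpslab synth --kind sticky_homopolymer --length 50 --stickiness 1.0 --out toy
hpslab build --fasta toy.fasta --params toy_params.tsv --n-chains 30 \
             --box 10 10 40 --slab --out system.h5
hpslab run   --system system.h5 --steps 5e5 --temperature 310 --tau 100 \
             --seed 5 --out traj.h5
hpslab analyze --traj traj.h5 --system system.h5 --density --coexistence \
             --out slab
```

The same pipeline is scripted in `analysis/02_slab_coexistence.py`, which
prints (5×10⁵ steps, seed 5):

```
T=310 K: phase-separated, c_dense=453 mg/mL, c_sat=28.10 mg/mL (ratio 16)
T=600 K: not phase-separated (flat profile)
```

i.e. at 310 K the 30 chains hold a condensed slab around z = 0 whose
density (~450 mg/mL) is protein-condensate-like, coexisting with a sparse
vapor of chains, while at 600 K the same system fills the box as a
homogeneous solution — phase separation is monotone in temperature, and
the dense/dilute concentration ratio at the lower temperature exceeds 10.

The TDP-43 studies are `analysis/01_single_chain_compaction.py`
(single-chain WT versus the Trp-free 6WtoA variant: removing the six
tryptophans weakens intramolecular attraction and expands the chain) and
`analysis/03_ctd_trp_mutation.py` (the same mutation applied to the
C-terminal domain fragment raises the dilute-phase concentration of a
20-chain condensate — lower phase-separation propensity).  Each script
writes its tables under `results/`.

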