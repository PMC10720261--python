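# Methods

## Model

`hpslab` implements a one-bead-per-residue, implicit-solvent coarse-grained
model for intrinsically disordered and multidomain proteins of the
hydropathy-scale (HPS) family, in the Urry-scale parameterisation
(HPS-Urry; Regy et al., *Protein Sci* 29:2445, 2020).  Each residue is a
single spherical bead with mass *m_i* (amu), diameter σ_i (nm), net charge
*q_i* (e at neutral pH; His neutral by default) and a dimensionless
hydropathy λ_i.  Three energy terms act:

* **Short-range pair attraction** (Ashbaugh–Hatch form).  With
  σ̄ = (σ_i+σ_j)/2, λ̄ = (λ_i+λ_j)/2 and Φ_LJ the 12-6 Lennard-Jones
  potential of diameter σ̄ and well depth ε:

      U(r) = Φ_LJ(r) + (1−λ̄) ε   for r ≤ 2^(1/6) σ̄
      U(r) = λ̄ Φ_LJ(r)           for r >  2^(1/6) σ̄

  Both branches equal −λ̄ε at the crossover, so U is continuous; λ̄ = 0
  leaves a purely repulsive WCA wall, λ̄ = 1 the full LJ attraction.
  Default ε = 0.8368 kJ/mol (0.2 kcal/mol, the standard HPS convention).

* **Screened electrostatics** (Debye–Hückel):
  U = (e²/4πε₀) q_i q_j exp(−r/κ⁻¹)/(ε_r r), with ε_r = 80 and Debye
  length κ⁻¹ = 1.0 nm by default (≈100 mM monovalent salt; the ionic
  strength of the reference implicit-solvent runs is not published, so
  this is a declared, configurable choice).

* **Harmonic bonds** between consecutive residues, r₀ = 0.38 nm,
  k = 4184 kJ/(mol nm²).

Both nonbonded terms are truncated, not shifted, at their cutoffs
(defaults 2.0 nm short-range, 3.5 nm electrostatic), matching common HPS
implementations; absolute energies therefore carry a small cutoff
dependence, and a regression test checks that the discarded tail is below
0.1% of (3/2)k_BT per bead for a dilute gas.  Internal units are nm,
kJ/mol, ps, amu.

## Rigid folded domains

Residue windows declared rigid move as rigid bodies whose internal
geometry is fixed to reference Cα coordinates.  For full-length TDP-43 the
default windows are NTD 1–80, RRM1 105–177, RRM2 192–260, and the
conserved helical region 320–343.  The reference publication names the
domains but not exact residue windows for its implicit-solvent runs; these
windows follow its explicit-solvent structured-region bounds (3–77,
105–177, 192–260) rounded to domain-consistent values, and are
configurable.  Nonbonded exclusions cover bonded (1-2) pairs and all
intra-rigid pairs.

Reference coordinates can be read from Cα PDB files.  The packaged
defaults are *synthetic*: an ideal α-helix trace (0.15 nm rise, 100°
twist, 0.23 nm radius) for the conserved region and randomly packed
compact globules at folded-protein density (0.134 nm³/residue) for
NTD/RRM1/RRM2.  These stand-ins preserve excluded volume, mass
distribution and surface character but none of the native surface residue
arrangement — domain-resolved contact patterns computed from them are
qualitative only.

## Dynamics

NVT sampling uses a BAOAB-splitting Langevin integrator with per-bead
friction γ_i = m_i/τ.  The production defaults mirror the reference
protocol: T = 310 K, dt = 10 fs, damping time τ = 1000 ps.  Because
friction is proportional to mass, the summed member friction of a rigid
group reduces *exactly* to M/τ on its center of mass and to I/τ on its
rotation; every degree of freedom therefore relaxes with the same τ and a
single Ornstein–Uhlenbeck factor exp(−dt/τ) thermostats flexible beads,
rigid COM velocities and body-frame angular momenta alike.  Rigid rotation
is propagated by the symplectic no-squish free-rotor splitting on
quaternions.  The NVE mode (thermostat off) exists for verification:
energy drift < 10⁻³ relative over 10⁵ steps at dt = 2 fs, and momentum/
angular-momentum conservation for isolated rigid bodies.

Desk-scale runs in the tests use τ = 2–100 ps: the weak production
coupling (τ = 1000 ps) removes the heat of initial-configuration
relaxation too slowly for short runs.  τ only sets sampling kinetics, not
the sampled ensemble.  No center-of-mass motion removal is applied
(Langevin dynamics legitimately diffuses the COM).

## Initial configurations

Chains grow as self-avoiding random walks with exact bond length; rigid
groups are inserted as intact units in random orientation.  Slabs are
packed by growing chains *in place* inside the central z-window of an
elongated box (default 20×20×168 nm for the 100-chain TDP-43 system),
each walk avoiding all previously placed beads at 0.3 nm — in-place
growth lets late chains thread gaps, which whole-chain insertion cannot
do at condensate densities.  A capped-displacement steepest-descent pass
(`relax`) removes residual packing strain in place of a separate
minimisation stage.  Initial velocities are Maxwell–Boltzmann.

## Observables

* **Rg**: mass-weighted radius of gyration on unwrapped coordinates
  (trajectories store unwrapped positions; a chain-walking unwrapper is
  provided for wrapped input).
* **Density profile**: per-frame mass histograms along z, recentered per
  frame on the mass-weighted circular-mean z of the largest inter-chain
  cluster (distance cutoff 1.2 nm between beads of different chains);
  concentrations in mg/mL via bin volume and the atomic mass constant.
* **Coexistence**: c_dense is the mean over the central 50% of the
  contiguous region above half the maximum (smoothed) concentration;
  c_sat the mean beyond the half-max interface plus a dilute margin
  (default 15 nm, scaled down for short boxes).  Uncertainties are
  standard errors over 5 contiguous frame blocks.  A profile whose
  maximum is below twice the box-average concentration is flagged "not
  phase-separated".  The first 2/7 of every trajectory is discarded as
  equilibration by default.
* **Contact maps**: residues are in contact when any of their beads lie
  within 0.8 nm (minimum image); the cutoff is configurable and recorded
  in the output.  Intra-chain maps skip |i−j| ≤ 2 and average the
  indicator over chains and frames.  Inter-chain maps average over
  *ordered* chain pairs and frames (a one-directional residue pair in a
  two-chain system thus scores 1/2); an alternative per-frame
  normalisation ("any chain pair") is available, as are per-residue row
  sums/means with cross-replicate standard errors.
* **Diffusion**: chain-COM MSD over sliding origins, D from a linear fit
  of MSD = 6Dt in a stated lag window, with R² and the log-log slope as
  fit diagnostics (slopes ≫1 flag ballistic/drifting motion).

## Synthetic data

Every analysis stage has a generator whose ground truth it must recover:
sticky homopolymers (uniform λ, tunable phase behavior), block
polyampholytes, disordered fragments reproducing the TDP-43 CTD (aa
261–414) residue composition to within one residue per type, beads on a
ring (exact Rg), pinned contact patterns, Brownian walks of chosen D, and
square-step density profiles with known c_dense/c_sat.  Generators are
seed-deterministic.  They emulate the *statistical* structure of
condensate data — they do not reproduce native folded-domain surfaces,
sequence-specific contact patterns, or hydrodynamics, so passing recovery
tests validates the estimators, not the realism of any particular protein
model.

## Desk-scale study conditions

The reference single-chain and slab simulations run 3.5 μs (3.5×10⁸
steps); tests and the acceptance script use scaled-down versions chosen
as the package's own study conditions:

* Sticky-homopolymer slab: 30 chains × 50 beads (λ = 1.0) in 10×10×40 nm,
  3×10⁵ steps (separation is complete well before 1.5×10⁵ from the
  tight-packed start), short-range cutoff 1.5 nm (tail < 2% of ε for
  0.6 nm beads).  250 K lies well below and 600 K well above the
  transition; the dense/dilute ratio exceeds 10 at 250 K and the 600 K
  profile is flat.  Caveat for quantitative work: deep quenches freeze
  coarsening, and depending on the packing seed a few chains can stay
  trapped outside the slab and inflate the apparent c_sat; near the
  study temperature (310 K) chain exchange is active and the coexistence
  estimate is robust, which is why the acceptance script and the slab
  driver report 310 K.
* Single-chain TDP-43 WT/6WtoA: one matched pair of 3×10⁵-step runs at
  310 K from a shared compact (sphere-confined) start, checking the
  direction of the Trp→Ala expansion.  At this scale the equilibrium Rg
  fluctuations (σ ≈ 0.4–0.6 nm, correlation time ≈ 2×10⁵ steps, replica
  spread ≈ 0.5 nm) are larger than the expected mutation effect, so the
  direction check has limited power and can fail by sampling noise alone;
  quantitative reproduction of the reference ensemble means
  (3.18/3.51 nm) needs runs two orders of magnitude longer
  (analysis/01_single_chain_compaction.py --steps).
* CTD fragment slab: 20 chains of the real aa 261–414 sequence versus its
  Trp-free variant at 255 K (just below this model's CTD transition, which
  sits between 250 and 270 K at these densities), 5×10⁴ production steps
  after a staged settle: Trp removal raises the dilute-phase
  concentration (c_sat 14 → 40 mg/mL at the 2×10⁵-step exploration
  scale).

## Known limitations

* Synthetic folded-domain geometry (above): domain-level contact maps are
  qualitative.
* Truncated (unshifted) potentials make absolute energies
  cutoff-dependent; forces are exact gradients of the implemented energy.
* Single-chain Rg at desk scale has large conformational autocorrelation;
  ordering checks average over replicas and start compact, but individual
  short runs can invert the ordering by chance.
* No hydrodynamic interactions, explicit ions, or secondary-structure
  dynamics; rigid windows cannot capture mutation-induced domain
  destabilisation (relevant to Trp mutants whose Trp sits inside folded
  domains).
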