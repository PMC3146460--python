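# Methods

## Scope and model

`phosdelta` post-processes trajectories of domain–phosphopeptide
complexes; it does not run molecular dynamics. Three computations make up
the pipeline: single-trajectory end-point interaction energies (MM-GBSA),
pThr↔pSer in-silico mutation, and per-torsion Gibbs configurational
entropy. The package's own unit conventions are Å, kcal/mol, elementary
charges, degrees, and 0-based indices internally (1-based in all
user-facing reports, matching PDB convention).

### Single-trajectory contract

Complex, receptor and ligand energies are all evaluated on the same
complex-trajectory coordinates. Intramolecular bonded (valence) terms are
therefore identical in the complex and in the parts and cancel exactly in
the difference — they are never computed. As a corollary, the ΔU_vdw and
ΔU_Coul of a frame are plain intermolecular pair sums, and the solvation
terms are the only ones needing explicit complex-minus-parts evaluation.

### Energy kernels

* **Coulomb**: k_e q_i q_j / (ε r_ij) with k_e = 332.0636 kcal·Å/(mol·e²),
  hard truncation at 40 Å (no switching). The cutoff is applied where its
  meaning is unambiguous — the intermolecular pair sums; the GB sums run
  cutoff-free because the systems handled here are small.
* **Lennard-Jones**: ε[(r_min/r)¹² − 2(r_min/r)⁶] with
  r_min = r_min,i/2 + r_min,j/2 and ε = √(ε_i ε_j).
* **Generalized Born** (the igb=1 flavor): effective radii from the HCT
  pairwise-descreening integral,
  1/R_i = 1/ρ_i − Σ_j I(r_ij, ρ_i, s_j ρ_j), then the Still pair function
  f_GB = √(r² + R_i R_j exp(−r²/4R_iR_j)) in
  ΔG = −½ k_e (1/ε_in − 1/ε_out) Σ_ij q_i q_j / f_GB, self terms included,
  ε_in = 1, ε_out = 80. The stored `gb_radius` is used directly as the
  intrinsic radius ρ, so an isolated ion reproduces the Born formula with
  its stored radius exactly; callers who carry offset-style radii can pass
  a nonzero `offset`. A non-positive computed radius (possible when heavy
  descreeners engulf a small atom) raises an error naming the atom rather
  than silently producing nonsense.
* **SASA**: Shrake–Rupley point counting with deterministic golden-spiral
  sphere points (default 960), probe 1.4 Å, van der Waals radii taken
  from the Lennard-Jones r_min/2 unless a radii table is supplied.
  Per-atom areas sum to the total by construction.
* **Non-polar term**: γ·SASA + β. The defaults γ = 0.00542 kcal/(mol·Å²),
  β = 0.92 kcal/mol are the PB-style convention; the GB-style preset
  (γ = 0.005, β = 0) is available as `NONPOLAR_PRESETS["gb"]`. Because the
  published analyses do not state their coefficients, both conventions
  are explicit configuration, echoed into every output.
* **Poisson–Boltzmann** is exposed only as an adapter slot (an injected
  callable with the GB signature); GB is the implemented polar model, as
  the local analyses it serves were run with GB.

### Ensembles, shells, differences

Per-frame components are averaged within each seed, then across seeds;
the reported uncertainty is the standard error over seeds, because frames
inside one short run are autocorrelated while seeds are independent. The
phosphate shell is defined once on a reference frame (any-atom residue
criterion against the phosphate atoms {P, O1P, O2P, O3P, OG/OG1}; default
cutoff 6 Å, the midpoint of the 5–7 Å window) and reused for the mutant
so wild and mutant see the same selection; the ligand side keeps the
phosphoresidue ±1 neighbors by default. Local GB/SASA run on the reduced
subsystem (full-complex radii available by flag). ΔΔ records are
mutant − wild, so positive values mean the mutation is unfavorable.

### Mutation protocol

pThr→pSer deletes the CG2 methyl group (CG2 + three hydrogens) and
renames the residue; all other atoms keep order and coordinates
bit-identically. pSer→pThr rebuilds CG2 at 1.525 Å from CB in the ideal
fourth tetrahedral direction implied by CB's existing substituents —
this, rather than a torsion prescription for the carbon, is what
guarantees near-ideal substituent angles on regular geometry — and the
three hydrogens at 1.09 Å, staggered anti to the OG1 branch. Product
charges always come from a user-supplied parameter block; nothing is
re-derived. No minimization follows the edit (MD engines are out of
scope): placed-methyl contacts closer than 1 Å are logged as warnings,
and mutant ensembles for analysis come from the synthetic generator
instead. The shipped residue templates carry a single united CB hydrogen
in both phospho forms, so the mutation always changes exactly four atoms
and pT→pS→pT is an exact involution on names, bonds and charges.

### Dihedral entropy

Angles are measured by the standard atan2 torsion in [−180, 180) and
binned into 36 equal left-closed/right-open bins (10°; the binning of the
original entropy analysis tool is unpublished, so bin count is explicit
configuration recorded in every output). S = −R Σ p ln p with
0·ln 0 := 0 and R = 1.9872×10⁻³ kcal/(mol·K); tables report T·S at 300 K.
Seeds are pooled before histogramming; per-seed series remain available
for dispersion. Mutation differences are summed per class (phi, psi,
omega, sidechain = all chi torsions) over dihedrals matched by (residue,
torsion label); torsions existing on one side only — the pThr methyl
rotor — are excluded from the sums and reported separately, since a
difference requires a matched pair. Couplings between dihedrals are
ignored throughout, and no separate conformational/vibrational numbers
are emitted: the rotamer profile (state count, populations, circular
means and widths from a von Mises-kernel-smoothed density, default
bandwidth 15°, floor 1% occupancy with sub-floor wells merged into their
taller neighbor) carries that information qualitatively.

## Synthetic data: what it emulates, what it does not

`make_toy_complex` builds a rigid "pocket" receptor around a short
peptide carrying one phospho-analog residue: two +1 e sites at 2.85 Å
from phosphate oxygens emulate the paired-arginine phosphate clamp, and
the enclosed-cavity variant surrounds the (real or would-be) methyl site
with six non-polar atoms at 3.7–4.15 Å — the distance window where a
methyl sits comfortably in a Lennard-Jones well — while the open-loop
variant omits them. Neutral filler atoms bring the pocket to its
specified size. `sample_ensemble` redraws named peptide torsions from
von Mises mixtures each frame, rebuilds the chain from ideal internal
coordinates anchored at the first residue, and rejects frames with any
non-bonded pair closer than 2 Å; five seeds of 1000 frames (one per
picosecond of the emulated nanosecond) are the default conditions.
`ground_truth_entropy` integrates the mixture density per bin by
quadrature, giving the exact value the histogram estimator must recover.

The generator reproduces the *mechanics* a trajectory analysis faces —
multi-seed averaging, shell selection, matched/unmatched torsions,
methyl-sized cavities — with exact ground truth. It is not a physical
surrogate: the pocket is rigid, there is no solvent, no backbone
relaxation coupling, no kinetics, and the fixed-charge parameter table is
a fixture, not a force field. Passing tests therefore demonstrate
correctness of the estimators and bookkeeping, and sign/rank-level
reproduction of the methyl-deletion contrast; they do not validate force
fields or sampling on real systems.

The methyl-deletion benchmark pairs three ensembles: wild (tight chi
distributions keep the methyl in its cavity), a frame-matched mutant
(identical coordinates minus the neutral methyl — so ΔΔU_Coul is exactly
zero and ΔΔU_vdw isolates the methyl's dispersion contacts), and a
relaxed mutant resampled with chi1 shifted 47° and widened (κ 40→6),
emulating the rotational freedom the missing methyl leaves behind. The
documented expectations are sign/rank statements: ΔΔU_vdw > 0 with the
enclosed cavity and strictly smaller in magnitude for the open loop;
TΔS > 0 and sidechain-dominated.

## Numerical choices

* Histogram bins left-closed/right-open; +180° wraps to −180°.
* Energy-component identities (E_ele = U_Coul + W_polar, etc.) are
  enforced at assembly to 1e-6 and re-checked on every emitted table row
  to the 0.01 formatting granularity.
* Degenerate inputs fail loudly: empty selections, empty trajectories,
  overlapping receptor/ligand groups, missing phosphate atoms, collinear
  torsion geometry, atoms closer than 1e-6 Å.
* Toy-pocket placement retries with fresh jitter up to 100 times before
  declaring the geometry infeasible; torsion resampling aborts if more
  than 99% of proposals clash.
* All generators take explicit integer seeds; per-seed streams derive
  from (seed, seed-index) so ensembles are reproducible bit-exactly.

## Problem sizes

The shipped analyses run on one CPU in minutes. The acceptance script
uses 100 random ≤20-atom systems for the kernel oracles, ten random
mixtures at 10⁵ samples for entropy recovery, and five seeds × 150
frames per ensemble (energy averaging at stride 15) for the
methyl-deletion contrast; the default toy pipeline uses five seeds × 200
frames. These sizes were chosen as the smallest at which the seed-level
standard errors are well below the effect sizes being asserted.

## Known limitations

* The prmtop reader covers the minimal flag subset the energy kernels
  need; exotic dialects are ignored with a logged warning.
* GB is the only implemented polar model; PB requires an external solver
  injected through the adapter.
* The published per-system energy/entropy table *values* derive from
  nanosecond MD of real structures with external force fields and are
  ensemble- and binning-dependent; this package reproduces their internal
  arithmetic exactly and their qualitative contrasts on synthetic ground
  truth, not the absolute numbers.
* Mutation handles pThr↔pSer only; no general mutagenesis, charge
  re-derivation, or rotamer search.
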