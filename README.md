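# phosdelta

End-point energetics and dihedral entropy of phosphopeptide recognition.

Phosphopeptide-binding modules — FHA domains, BRCT repeats, WW domains —
steer signal transduction by grabbing phosphothreonine (pThr) or
phosphoserine (pSer) motifs, and FHA domains famously discriminate the two
even though they differ by a single methyl group. Quantifying *why* takes
two post-processing analyses of domain–peptide MD trajectories:

1. **Single-trajectory MM-GBSA interaction energies.** The binding
   interaction energy is ΔE_bind = ⟨E_complex⟩ − ⟨E_receptor⟩ − ⟨E_ligand⟩,
   with all three terms evaluated on the *complex* trajectory so
   intramolecular (valence) contributions cancel identically, leaving

       ΔE = ΔU_vdw + ΔU_Coul + ΔW_polar + ΔW_np

   where ΔU_vdw and ΔU_Coul are intermolecular Lennard-Jones and Coulomb
   sums (hard 40 Å cutoff), ΔW_polar is generalized-Born polar solvation
   (HCT pairwise-descreening effective radii, ε_in = 1, ε_out = 80), and
   ΔW_np = γ·SASA + β from Shrake–Rupley solvent-accessible surface area.
   Derived columns follow E_ele = U_Coul + W_polar and
   E_tot = E_ele + U_vdw + W_np. Energies can be computed globally
   (whole domain vs whole peptide) or locally, restricted to domain
   residues within 5–7 Å of the phosphate group. Mutant-minus-wild
   differences (ΔΔ records; positive = mutation unfavorable) mirror the
   published table layouts.

2. **Dihedral Gibbs configurational entropy.** Each torsion x (phi, psi,
   omega, sidechain chi) is binned into a periodic 10° histogram and
   scored with S = −R Σ p(x) ln p(x); mutation-induced changes TΔS are
   summed per class. Rotamer-state profiling (occupied wells of the
   circularly smoothed angle density, their populations, means and
   widths) separates conformational from vibrational flexibility.

The package also performs the in-silico pThr↔pSer mutation itself
(methyl deletion by bookkeeping, methyl construction at ideal tetrahedral
geometry) and ships a synthetic-data generator that builds charged-pocket
toy complexes and multi-seed torsion-resampled ensembles with von Mises
ground truth, so the whole pipeline is testable without MD engines or
structure downloads.

## Worked example

Run the full toy pipeline (an enclosed-cavity pocket holding a pThr-like
peptide, five independent-seed ensembles of 100 frames, methyl-deletion
mutant):

```bash
cat > run.cfg <<EOF
phosphoresidue = auto
seed = 1
n_seeds = 5
n_frames = 100
stride = 10
EOF
phosdelta report --config run.cfg --out out
```

which prints

```json
{
  "ddE_tot": 0.5702205893443502,
  "TdS_total": 0.8187610118868208
}
```

and writes `out/global_energy.tsv`:

```
domain      mutated_site  mutation  ddU_VDW  ddU_Coul  ddW_polar  ddE_ele  ddE_tot-np  ddW_np  ddE_tot
toy-pocket  1             pT->pS    1.04     0.00      -0.47      -0.47    0.57        0.00    0.57
```

and `out/entropy.tsv`:

```
domain      mutated_site  mutation  TdS_phi  TdS_psi  TdS_omega  TdS_sidechain  TdS_total
toy-pocket  1             pT->pS    0.00     0.00     0.00       0.82           0.82
```

Read: deleting the buried methyl costs ~1 kcal/mol of van der Waals
attraction (ddU_VDW = +1.04 — the mutation is unfavorable) while the
Coulomb term is untouched (the methyl is neutral and the frames are
matched); the relaxed mutant gains ~0.8 kcal/mol of T·ΔS, all of it from
the sidechain torsions — the sign/rank pattern expected for a
methyl-specific enclosed cavity. `out/bundle.json` holds every number
plus the full configuration and validates against the shipped schema;
reruns with the same seeds are byte-identical.

Other subcommands: `phosdelta simulate-toy`, `phosdelta mutate`,
`phosdelta energy`, `phosdelta entropy`, `phosdelta rmsd` (see `--help`).

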