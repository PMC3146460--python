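"""Single-trajectory interaction-energy assembly.

Combines the kernels into per-frame receptor–ligand interaction energies
(complex-minus-parts on identical coordinates, so intramolecular valence
terms cancel identically), seed-ensemble averages with across-seed
standard errors, mutant-minus-wild difference records, and the local
(phosphate-shell) variant of the calculation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_NONBONDED_CUTOFF, NONPOLAR_PRESETS
from .mm_energetics import (
    EnergyComponents,
    combine_components,
    coulomb_energy,
    gb_energy,
    lj_energy,
    nonpolar_energy,
    pb_energy,
    sasa,
)
from .system_io import Frame, SeedEnsemble, Topology, rmsd

__all__ = [
    "DeltaDeltaRecord", "ShellSelection", "EnsembleEnergy",
    "interaction_energy_frame", "ensemble_average", "delta_delta",
    "shell_select", "local_interaction_energy", "reference_frame_index",
    "combine_components",
]

_COMPONENT_FIELDS = ("U_vdw", "U_coul", "W_polar", "W_np",
                     "E_ele", "E_tot_np", "E_tot")


@dataclass(frozen=True)
class DeltaDeltaRecord:
    """Mutant-minus-wild differences of the energy components (kcal/mol).

    Positive values mean the mutation is unfavorable for binding.
    """

    label: str
    mutated_site: int
    mutation: str  # "pT->pS" or "pS->pT"
    dd_U_vdw: float
    dd_U_coul: float
    dd_W_polar: float
    dd_E_ele: float
    dd_E_tot_np: float
    dd_W_np: float
    dd_E_tot: float
    polar_model: str = "GB"
    per_seed: pd.DataFrame | None = None
    sem: dict | None = None

    def __neg__(self) -> "DeltaDeltaRecord":
        return DeltaDeltaRecord(
            self.label, self.mutated_site, self.mutation,
            -self.dd_U_vdw, -self.dd_U_coul, -self.dd_W_polar,
            -self.dd_E_ele, -self.dd_E_tot_np, -self.dd_W_np, -self.dd_E_tot,
            self.polar_model)


@dataclass(frozen=True)
class ShellSelection:
    """Domain residues within a stated distance of the phosphate group."""

    cutoff: float
    phosphate_atom_names: frozenset[str]
    selected_residues: tuple[tuple[int, str], ...]  # (index, name)
    reference_frame_index: int = 0

    @property
    def residue_indices(self) -> list[int]:
        return [i for i, _ in self.selected_residues]


@dataclass
class EnsembleEnergy:
    """Seed-ensemble averaged components with per-seed detail."""

    mean: EnergyComponents
    per_seed: pd.DataFrame  # one row per seed, component columns
    sem: dict[str, float] = field(default_factory=dict)


DEFAULT_PHOSPHATE_ATOMS = frozenset({"P", "O1P", "O2P", "O3P", "OG", "OG1"})


def interaction_energy_frame(topology: Topology, frame: Frame,
                             receptor: Sequence[int], ligand: Sequence[int],
                             polar_model: str = "GB",
                             cutoff: float = DEFAULT_NONBONDED_CUTOFF,
                             np_gamma: float = NONPOLAR_PRESETS["pb"][0],
                             np_beta: float = NONPOLAR_PRESETS["pb"][1],
                             sasa_probe: float = 1.4,
                             sasa_points: int = 960,
                             pb_solver=None) -> EnergyComponents:
    """Interaction energy of one frame under the single-trajectory contract.

    U_vdw and U_coul are direct intermolecular sums (equivalent to
    complex-minus-parts because intramolecular pairs cancel exactly);
    the solvation terms are complex minus receptor minus ligand, each
    evaluated on the same coordinates.
    """
    rec = sorted(receptor)
    lig = sorted(ligand)
    if set(rec) & set(lig):
        raise ValueError("receptor and ligand overlap")
    both = sorted(rec + lig)

    u_coul = coulomb_energy(topology, frame, rec, lig, cutoff=cutoff)
    u_vdw = lj_energy(topology, frame, rec, lig, cutoff=cutoff)

    if polar_model.upper() == "GB":
        polar = (gb_energy(topology, frame, both)
                 - gb_energy(topology, frame, rec)
                 - gb_energy(topology, frame, lig))
    elif polar_model.upper() == "PB":
        polar = (pb_energy(topology, frame, both, solver=pb_solver)
                 - pb_energy(topology, frame, rec, solver=pb_solver)
                 - pb_energy(topology, frame, lig, solver=pb_solver))
    else:
        raise ValueError(f"unknown polar model {polar_model!r}")

    s_complex, _ = sasa(topology, frame, both, probe=sasa_probe,
                        n_sphere_points=sasa_points)
    s_rec, _ = sasa(topology, frame, rec, probe=sasa_probe,
                    n_sphere_points=sasa_points)
    s_lig, _ = sasa(topology, frame, lig, probe=sasa_probe,
                    n_sphere_points=sasa_points)
    w_np = (nonpolar_energy(s_complex, np_gamma, np_beta)
            - nonpolar_energy(s_rec, np_gamma, np_beta)
            - nonpolar_energy(s_lig, np_gamma, np_beta))

    return EnergyComponents.assemble(u_vdw, u_coul, polar, w_np,
                                     polar_model=polar_model.upper())


def ensemble_average(topology: Topology, ensemble: SeedEnsemble,
                     receptor: Sequence[int], ligand: Sequence[int],
                     stride: int = 1, **kwargs) -> EnsembleEnergy:
    """Average per-frame components within each seed, then across seeds.

    The reported uncertainty is the standard error of the mean across
    seeds (frames within a run are autocorrelated; seeds are independent).
    """
    rows = []
    for traj, seed in zip(ensemble.trajectories, ensemble.seed_ids):
        if traj.n_frames == 0:
            raise ValueError(f"seed {seed}: empty trajectory")
        acc = np.zeros(len(_COMPONENT_FIELDS))
        count = 0
        for fr in traj.frames(stride=stride):
            comp = interaction_energy_frame(topology, fr, receptor, ligand, **kwargs)
            acc += [getattr(comp, f) for f in _COMPONENT_FIELDS]
            count += 1
        rows.append(dict(zip(_COMPONENT_FIELDS, acc / count), seed=seed))
    per_seed = pd.DataFrame(rows).set_index("seed")
    means = per_seed.mean(axis=0)
    nseed = len(rows)
    sem = (per_seed.std(axis=0, ddof=1) / np.sqrt(nseed)
           if nseed > 1 else per_seed.iloc[0] * 0.0)
    polar_model = kwargs.get("polar_model", "GB").upper()
    mean_comp = EnergyComponents.assemble(
        means["U_vdw"], means["U_coul"], means["W_polar"], means["W_np"],
        polar_model=polar_model)
    return EnsembleEnergy(mean=mean_comp, per_seed=per_seed,
                          sem={k: float(sem[k]) for k in _COMPONENT_FIELDS})


def delta_delta(wild: EnergyComponents | EnsembleEnergy,
                mutant: EnergyComponents | EnsembleEnergy,
                label: str, site: int, mutation: str) -> DeltaDeltaRecord:
    """Mutant-minus-wild difference record (positive = unfavorable)."""
    w = wild.mean if isinstance(wild, EnsembleEnergy) else wild
    m = mutant.mean if isinstance(mutant, EnsembleEnergy) else mutant
    if w.polar_model != m.polar_model:
        raise ValueError("wild and mutant use different polar models")

    per_seed = None
    sem = None
    if isinstance(wild, EnsembleEnergy) and isinstance(mutant, EnsembleEnergy):
        if len(wild.per_seed) == len(mutant.per_seed):
            per_seed = mutant.per_seed.reset_index(drop=True) - \
                wild.per_seed.reset_index(drop=True)
            n = len(per_seed)
            if n > 1:
                s = per_seed.std(axis=0, ddof=1) / np.sqrt(n)
                sem = {k: float(s[k]) for k in _COMPONENT_FIELDS}

    return DeltaDeltaRecord(
        label=label, mutated_site=site, mutation=mutation,
        dd_U_vdw=m.U_vdw - w.U_vdw,
        dd_U_coul=m.U_coul - w.U_coul,
        dd_W_polar=m.W_polar - w.W_polar,
        dd_E_ele=m.E_ele - w.E_ele,
        dd_E_tot_np=m.E_tot_np - w.E_tot_np,
        dd_W_np=m.W_np - w.W_np,
        dd_E_tot=m.E_tot - w.E_tot,
        polar_model=w.polar_model, per_seed=per_seed, sem=sem)


def reference_frame_index(ensemble: SeedEnsemble,
                          selection: Sequence[int] | None = None) -> tuple[int, int]:
    """(seed position, frame index) of the frame minimizing mean RMSD to all
    others in the ensemble. Used as the default shell-selection reference."""
    frames = [(si, fi, traj.frame(fi))
              for si, traj in enumerate(ensemble.trajectories)
              for fi in range(traj.n_frames)]
    best = None
    best_score = np.inf
    for si, fi, fr in frames:
        score = np.mean([rmsd(fr, other, selection) for _, _, other in frames])
        if score < best_score:
            best_score = score
            best = (si, fi)
    return best


def shell_select(topology: Topology, frame: Frame, phospho_residue: int,
                 cutoff: float = 6.0,
                 phosphate_atom_names: frozenset[str] = DEFAULT_PHOSPHATE_ATOMS,
                 domain_group: str = "receptor") -> ShellSelection:
    """Domain residues with any atom within `cutoff` of any phosphate atom.

    The phosphoresidue itself is never part of the domain-side selection.
    """
    phos_atoms = [i for i in topology.residue_atoms(phospho_residue)
                  if topology.atoms[i].name in phosphate_atom_names]
    if not phos_atoms:
        raise ValueError(
            f"residue {phospho_residue} ({topology.residues[phospho_residue].name}) "
            f"has none of the phosphate atoms {sorted(phosphate_atom_names)}")
    phos_xyz = frame.coordinates[phos_atoms]
    domain = topology.groups.get(domain_group, frozenset())
    selected: list[tuple[int, str]] = []
    for ri, res in enumerate(topology.residues):
        if ri == phospho_residue:
            continue
        atoms = [i for i in res.atom_indices if i in domain]
        if not atoms:
            continue
        d = np.linalg.norm(
            frame.coordinates[atoms][:, None, :] - phos_xyz[None, :, :], axis=2)
        if d.min() <= cutoff:
            selected.append((ri, res.name))
    return ShellSelection(cutoff=cutoff,
                          phosphate_atom_names=frozenset(phosphate_atom_names),
                          selected_residues=tuple(selected),
                          reference_frame_index=frame.frame_index)


def local_interaction_energy(topology: Topology, ensemble: SeedEnsemble,
                             shell: ShellSelection, phospho_residue: int,
                             neighbor_residues: int = 1,
                             stride: int = 1, **kwargs) -> EnsembleEnergy:
    """Shell-restricted interaction energy, GB polar model by default.

    Receptor side: atoms of the shell residues. Ligand side: the
    phosphoresidue plus `neighbor_residues` flanking peptide residues
    (restricted to the ligand group when one is defined). GB and SASA are
    evaluated on the reduced subsystem.
    """
    if not shell.selected_residues:
        raise ValueError("empty shell selection")
    rec_atoms: list[int] = []
    for ri in shell.residue_indices:
        rec_atoms.extend(topology.residue_atoms(ri))
    ligand_group = topology.groups.get("ligand")
    lig_atoms: list[int] = []
    lo = phospho_residue - neighbor_residues
    hi = phospho_residue + neighbor_residues
    for ri in range(max(lo, 0), min(hi, topology.n_residues - 1) + 1):
        for i in topology.residue_atoms(ri):
            if ligand_group is None or i in ligand_group:
                lig_atoms.append(i)
    rec_atoms = [i for i in rec_atoms if i not in set(lig_atoms)]
    kwargs.setdefault("polar_model", "GB")
    return ensemble_average(topology, ensemble, rec_atoms, lig_atoms,
                            stride=stride, **kwargs)
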