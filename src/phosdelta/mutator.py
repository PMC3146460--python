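"""In-silico phospho-threonine <-> phospho-serine substitution.

The two residues differ by one methyl group (CG2 + hydrogens). Removing
the methyl (pThr -> pSer) is pure bookkeeping; adding it back
(pSer -> pThr) builds the carbon at the ideal fourth tetrahedral position
on CB and the hydrogens at standard staggered geometry. Charges for the
product residue always come from a user-supplied parameter block — they
are never re-derived. No minimization is performed; a steric clash of the
placed methyl closer than 1 Å to any non-bonded atom is logged as a
warning, not an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import geometry
from .params import DEFAULT_NAMING, METHYL_ATOMS, TEMPLATE_BOND_LENGTHS
from .system_io import AtomRecord, Frame, Residue, Topology

logger = logging.getLogger(__name__)


class TemplateError(ValueError):
    """Residue does not match the expected phospho-residue atom template."""


class ParameterError(ValueError):
    """No parameter block supplied for the product residue."""


_PTHR_REQUIRED = ("CB", "OG1", "CG2", "HG21", "HG22", "HG23",
                  "P", "O1P", "O2P", "O3P")
_PSER_REQUIRED = ("CB", "OG1", "P", "O1P", "O2P", "O3P")


def _check_template(topology: Topology, residue_index: int,
                    required: tuple[str, ...]) -> None:
    present = {topology.atoms[i].name
               for i in topology.residue_atoms(residue_index)}
    missing = [n for n in required if n not in present]
    if missing:
        raise TemplateError(
            f"residue {residue_index} ({topology.residues[residue_index].name}) "
            f"missing template atoms: {missing}")


def _apply_parameters(atoms: list[AtomRecord], residue_index: int,
                      new_name: str, parameters: dict) -> list[AtomRecord]:
    out = []
    for a in atoms:
        if a.residue_index != residue_index:
            out.append(a)
            continue
        if a.name in parameters:
            q, rmh, eps, gbr, gbs, mass = parameters[a.name]
            out.append(replace(a, residue_name=new_name, charge=q,
                               lj_rmin_half=rmh, lj_epsilon=eps,
                               gb_radius=gbr, gb_screen=gbs, mass=mass))
        else:
            out.append(replace(a, residue_name=new_name))
    return out


def mutate_pthr_to_pser(topology: Topology, frame: Frame, residue_index: int,
                        pser_parameters: dict | None = None,
                        naming: dict[str, str] = DEFAULT_NAMING
                        ) -> tuple[Topology, Frame]:
    """Delete the CG2 methyl group and rename/re-parameterize the residue.

    `pser_parameters` maps atom name -> (charge, rmin/2, epsilon,
    gb_radius, gb_screen, mass) for the product residue and is mandatory.
    All other residues' atoms keep their indices' order and coordinates
    bit-identically.
    """
    _check_template(topology, residue_index, _PTHR_REQUIRED)
    if pser_parameters is None:
        raise ParameterError("a phosphoserine parameter block is required")
    old_name = topology.residues[residue_index].name
    new_name = naming.get(old_name, "SEP")

    drop = [i for i in topology.residue_atoms(residue_index)
            if topology.atoms[i].name in METHYL_ATOMS]
    new_top, kept = topology.without_atoms(drop)
    new_top = Topology(
        _apply_parameters(new_top.atoms, residue_index, new_name, pser_parameters),
        [Residue(new_name, r.start, r.stop) if ri == residue_index
         else r for ri, r in enumerate(new_top.residues)],
        new_top.bonds, new_top.groups)
    new_frame = Frame(frame.coordinates[kept], frame_index=frame.frame_index,
                      time=frame.time)
    return new_top, new_frame


def mutate_pser_to_pthr(topology: Topology, frame: Frame, residue_index: int,
                        pthr_parameters: dict | None = None,
                        naming: dict[str, str] = DEFAULT_NAMING,
                        clash_distance: float = 1.0
                        ) -> tuple[Topology, Frame]:
    """Build the CG2 methyl group at ideal geometry and rename the residue.

    The carbon is placed 1.525 Å from CB at the fourth tetrahedral
    position implied by CB's existing substituents; the three hydrogens
    are built at 1.09 Å staggered anti to the OG1 branch. Placed atoms
    closer than `clash_distance` to any non-bonded atom trigger a logged
    warning only.
    """
    _check_template(topology, residue_index, _PSER_REQUIRED)
    present = {topology.atoms[i].name
               for i in topology.residue_atoms(residue_index)}
    if "CG2" in present:
        raise TemplateError(
            f"residue {residue_index} already carries a CG2 methyl group")
    if pthr_parameters is None:
        raise ParameterError("a phosphothreonine parameter block is required")
    old_name = topology.residues[residue_index].name
    new_name = naming.get(old_name, "TPO")

    cb = topology.find_atom(residue_index, "CB")
    ca = topology.find_atom(residue_index, "CA")
    og = topology.find_atom(residue_index, "OG1")
    hb = topology.find_atom(residue_index, "HB")
    coords = frame.coordinates
    substituents = [coords[ca], coords[og]]
    if hb is not None:
        substituents.append(coords[hb])
    cg2_xyz = geometry.tetrahedral_completion(coords[cb], substituents, 1.525)

    h_xyz = []
    for t in (180.0, -60.0, 60.0):
        h_xyz.append(geometry.place_atom(coords[og], coords[cb], cg2_xyz,
                                         1.09, 110.0, t))

    # clash report against atoms not bonded to the new methyl
    res_atoms = set(topology.residue_atoms(residue_index))
    other = [i for i in range(topology.n_atoms) if i != cb]
    for label, xyz in [("CG2", cg2_xyz)] + list(zip(("HG21", "HG22", "HG23"), h_xyz)):
        d = np.linalg.norm(coords[other] - xyz, axis=1)
        close = np.asarray(other)[d < clash_distance]
        close = [i for i in close if not (label != "CG2" and i in res_atoms)]
        if len(close):
            logger.warning("placed %s clashes (<%.1f Å) with atoms %s",
                           label, clash_distance, list(close))

    # insert the four methyl atoms after OG1, matching the template order
    insert_at = og + 1
    new_records = []
    for name, xyz in [("CG2", cg2_xyz), ("HG21", h_xyz[0]),
                      ("HG22", h_xyz[1]), ("HG23", h_xyz[2])]:
        if name not in pthr_parameters:
            raise ParameterError(f"parameter block lacks atom {name}")
        q, rmh, eps, gbr, gbs, mass = pthr_parameters[name]
        new_records.append(AtomRecord(
            index=0, name=name, residue_index=residue_index,
            residue_name=new_name, charge=q, lj_rmin_half=rmh,
            lj_epsilon=eps, gb_radius=gbr, gb_screen=gbs, mass=mass))

    def remap(i: int) -> int:
        return i if i < insert_at else i + 4

    atoms = []
    for a in topology.atoms:
        atoms.append(replace(a, index=remap(a.index)))
    for k, rec in enumerate(new_records):
        atoms.append(replace(rec, index=insert_at + k))
    atoms.sort(key=lambda a: a.index)

    residues = []
    for ri, r in enumerate(topology.residues):
        start = remap(r.start)
        stop = r.stop + 4 if r.stop > insert_at else r.stop
        name = new_name if ri == residue_index else r.name
        residues.append(Residue(name, start, stop))

    bonds = [(remap(i), remap(j)) for i, j in topology.bonds]
    cg2_idx = insert_at
    bonds.append((remap(cb), cg2_idx))
    bonds.extend((cg2_idx, cg2_idx + k) for k in (1, 2, 3))
    groups = {name: frozenset(remap(i) for i in grp)
              for name, grp in topology.groups.items()}
    # the methyl joins whichever group CB belongs to
    for name, grp in topology.groups.items():
        if cb in grp:
            groups[name] = groups[name] | {cg2_idx, cg2_idx + 1,
                                           cg2_idx + 2, cg2_idx + 3}

    new_top = Topology(
        _apply_parameters(atoms, residue_index, new_name, pthr_parameters),
        residues, bonds, groups)
    new_coords = np.insert(frame.coordinates, insert_at,
                           np.array([cg2_xyz] + h_xyz), axis=0)
    return new_top, Frame(new_coords, frame_index=frame.frame_index,
                          time=frame.time)


# ---------------------------------------------------------------------------
# validation report
# ---------------------------------------------------------------------------

@dataclass
class MutationReport:
    atom_count_delta: int
    renamed_residues: list[tuple[int, str, str]]
    bonds_added: list[tuple[tuple[int, str], tuple[int, str]]]
    bonds_removed: list[tuple[tuple[int, str], tuple[int, str]]]
    bond_deviations: list[tuple[str, str, float]] = field(default_factory=list)
    ok: bool = True

    def summary(self) -> str:
        lines = [f"atom count delta: {self.atom_count_delta:+d}",
                 f"renamed residues: {self.renamed_residues or 'none'}",
                 f"bonds added: {len(self.bonds_added)}",
                 f"bonds removed: {len(self.bonds_removed)}"]
        if self.bond_deviations:
            lines.append("bond-length deviations > 0.1 Å from template:")
            lines += [f"  {a}-{b}: {d:.3f} Å" for a, b, d in self.bond_deviations]
        lines.append("validation " + ("PASSED" if self.ok else "FAILED"))
        return "\n".join(lines)


def _bond_name_set(top: Topology):
    out = set()
    for i, j in top.bonds:
        a = (top.atoms[i].residue_index, top.atoms[i].name)
        b = (top.atoms[j].residue_index, top.atoms[j].name)
        out.add(tuple(sorted((a, b))))
    return out


def validate_mutation(before: Topology, after: Topology,
                      after_frame: Frame | None = None,
                      tolerance: float = 0.1) -> MutationReport:
    """Report-only consistency check of a mutation.

    Lists the atom-count delta, renamed residues and bond changes; when a
    frame is supplied, bond lengths in renamed residues are checked
    against the ideal template lengths and deviations beyond `tolerance`
    fail the report.
    """
    renamed = []
    if before.n_residues == after.n_residues:
        for ri, (rb, ra) in enumerate(zip(before.residues, after.residues)):
            if rb.name != ra.name:
                renamed.append((ri, rb.name, ra.name))
    bonds_before = _bond_name_set(before)
    bonds_after = _bond_name_set(after)
    report = MutationReport(
        atom_count_delta=after.n_atoms - before.n_atoms,
        renamed_residues=renamed,
        bonds_added=sorted(bonds_after - bonds_before),
        bonds_removed=sorted(bonds_before - bonds_after))

    if after_frame is not None:
        changed = {ri for ri, _, _ in renamed}
        for i, j in after.bonds:
            ai, aj = after.atoms[i], after.atoms[j]
            if ai.residue_index not in changed and aj.residue_index not in changed:
                continue
            ideal = TEMPLATE_BOND_LENGTHS.get(frozenset((ai.name, aj.name)))
            if ideal is None:
                continue
            actual = float(np.linalg.norm(
                after_frame.coordinates[i] - after_frame.coordinates[j]))
            if abs(actual - ideal) > tolerance:
                report.bond_deviations.append((ai.name, aj.name, actual))
    report.ok = not report.bond_deviations
    return report
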