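"""Molecular-system data model and file I/O.

The in-memory containers are deliberately small: an ordered atom table with
the per-atom parameters the implicit-solvent energy kernels need (charge,
Lennard-Jones rmin/2 and epsilon, GB intrinsic radius and screen), a residue
partition, a bond list, and named atom groups ("receptor", "ligand").

Supported formats:

* AMBER parameter-topology (prmtop), minimal flag subset, read-only;
* a plain sectioned parameter table (read/write) carrying the same fields;
* multi-model PDB (read/write, fixed column);
* DCD (read/write, via mdtraj's low-level DCD file object).

All text readers transparently accept gzip-compressed files.
"""

from __future__ import annotations

import gzip
import logging
import shutil
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .constants import (
    DEFAULT_GB_RADII,
    DEFAULT_GB_RADIUS_FALLBACK,
    DEFAULT_GB_SCREEN,
    DEFAULT_GB_SCREEN_FALLBACK,
    PRMTOP_CHARGE_SCALE,
    SOLVENT_RESIDUE_NAMES,
)
from . import geometry

logger = logging.getLogger(__name__)


class TopologyFormatError(ValueError):
    """A required section is missing or malformed in a topology file."""


class TopologyConsistencyError(ValueError):
    """Sections of a topology file disagree (e.g. atom counts)."""


class TrajectoryFormatError(ValueError):
    """A trajectory file is truncated or inconsistent with its topology."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """One atom with the parameters the energy kernels consume.

    charge in e, lj_rmin_half in Å, lj_epsilon in kcal/mol, gb_radius in Å,
    gb_screen dimensionless, mass in amu. Indices are 0-based.
    """

    index: int
    name: str
    residue_index: int
    residue_name: str
    charge: float
    lj_rmin_half: float
    lj_epsilon: float
    gb_radius: float
    gb_screen: float
    mass: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.charge):
            raise ValueError(f"atom {self.index}: non-finite charge")
        if self.lj_epsilon < 0:
            raise ValueError(f"atom {self.index}: negative LJ epsilon")
        if self.gb_radius <= 0:
            raise ValueError(f"atom {self.index}: non-positive GB radius")


@dataclass(frozen=True)
class Residue:
    name: str
    start: int  # first atom index
    stop: int   # one past last atom index

    @property
    def atom_indices(self) -> range:
        return range(self.start, self.stop)


@dataclass
class Topology:
    """Atoms + residue partition + bonds + named groups."""

    atoms: list[AtomRecord]
    residues: list[Residue]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    groups: dict[str, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        n = len(self.atoms)
        cursor = 0
        for res in self.residues:
            if res.start != cursor or res.stop <= res.start:
                raise TopologyConsistencyError(
                    f"residue ranges do not partition the atom list at {res}")
            cursor = res.stop
        if cursor != n:
            raise TopologyConsistencyError(
                f"residues cover {cursor} atoms, topology has {n}")
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise TopologyConsistencyError(f"bond ({i},{j}) out of range")
        rec = self.groups.get("receptor")
        lig = self.groups.get("ligand")
        if rec is not None and lig is not None and rec & lig:
            raise TopologyConsistencyError("receptor and ligand groups overlap")
        for name, grp in self.groups.items():
            for i in grp:
                if not 0 <= i < n:
                    raise TopologyConsistencyError(f"group {name!r}: index {i} out of range")

    # -- convenience -------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    def lj_rmin_half(self) -> np.ndarray:
        return np.array([a.lj_rmin_half for a in self.atoms])

    def lj_epsilon(self) -> np.ndarray:
        return np.array([a.lj_epsilon for a in self.atoms])

    def gb_radii(self) -> np.ndarray:
        return np.array([a.gb_radius for a in self.atoms])

    def gb_screens(self) -> np.ndarray:
        return np.array([a.gb_screen for a in self.atoms])

    def residue_of_atom(self, atom_index: int) -> int:
        return self.atoms[atom_index].residue_index

    def residue_atoms(self, residue_index: int) -> list[int]:
        return list(self.residues[residue_index].atom_indices)

    def find_atom(self, residue_index: int, name: str) -> int | None:
        for i in self.residues[residue_index].atom_indices:
            if self.atoms[i].name == name:
                return i
        return None

    def with_groups(self, **groups: Iterable[int]) -> "Topology":
        new = dict(self.groups)
        new.update({k: frozenset(v) for k, v in groups.items()})
        return Topology(self.atoms, self.residues, list(self.bonds), new)

    def subset_mask(self, keep: Sequence[bool]) -> "Topology":
        """Topology with only the atoms where keep is True, indices remapped."""
        keep = list(keep)
        old_to_new: dict[int, int] = {}
        new_atoms: list[AtomRecord] = []
        for old_idx, flag in enumerate(keep):
            if flag:
                old_to_new[old_idx] = len(new_atoms)
                new_atoms.append(self.atoms[old_idx])
        new_residues: list[Residue] = []
        res_remap: dict[int, int] = {}
        cursor = 0
        for ri, res in enumerate(self.residues):
            kept = [i for i in res.atom_indices if keep[i]]
            if not kept:
                continue
            res_remap[ri] = len(new_residues)
            new_residues.append(Residue(res.name, cursor, cursor + len(kept)))
            cursor += len(kept)
        new_atoms = [
            replace(a, index=i, residue_index=res_remap[a.residue_index])
            for i, a in enumerate(new_atoms)
        ]
        new_bonds = [
            (old_to_new[i], old_to_new[j])
            for i, j in self.bonds if keep[i] and keep[j]
        ]
        new_groups = {
            name: frozenset(old_to_new[i] for i in grp if keep[i])
            for name, grp in self.groups.items()
        }
        return Topology(new_atoms, new_residues, new_bonds, new_groups)

    def without_atoms(self, drop: Iterable[int]) -> tuple["Topology", np.ndarray]:
        """Remove atoms; returns (topology, kept-old-indices array)."""
        drop = set(drop)
        keep = [i not in drop for i in range(self.n_atoms)]
        kept_idx = np.array([i for i in range(self.n_atoms) if keep[i]])
        return self.subset_mask(keep), kept_idx


@dataclass
class Frame:
    """One coordinate snapshot, Å."""

    coordinates: np.ndarray  # (N, 3)
    frame_index: int = 0
    time: float | None = None  # ps

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (N, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Trajectory:
    """Ordered frames of one system. Coordinates stacked (F, N, 3) in Å."""

    coordinates: np.ndarray
    times: np.ndarray | None = None
    seed_id: int | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("trajectory coordinates must be (F, N, 3)")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, i: int) -> Frame:
        t = None if self.times is None else float(self.times[i])
        return Frame(self.coordinates[i], frame_index=i, time=t)

    def frames(self, stride: int = 1) -> Iterator[Frame]:
        for i in range(0, self.n_frames, stride):
            yield self.frame(i)


@dataclass
class SeedEnsemble:
    """Independent-seed trajectories of one system sharing one topology."""

    trajectories: list[Trajectory]
    seed_ids: list[int]

    def __post_init__(self):
        if not self.trajectories:
            raise ValueError("ensemble needs at least one trajectory")
        n = self.trajectories[0].n_atoms
        for t in self.trajectories:
            if t.n_atoms != n:
                raise ValueError("trajectories differ in atom count")
        if len(self.seed_ids) != len(self.trajectories):
            raise ValueError("one seed id per trajectory required")

    @property
    def n_seeds(self) -> int:
        return len(self.trajectories)


# ---------------------------------------------------------------------------
# text helpers
# ---------------------------------------------------------------------------

def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    # also sniff magic for extensionless gzip
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _maybe_decompress_binary(path) -> Path:
    """Return a readable plain file path, decompressing .gz to a temp file."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic != b"\x1f\x8b":
        return path
    tmp = tempfile.NamedTemporaryFile(suffix=".dcd", delete=False)
    with gzip.open(path, "rb") as src:
        shutil.copyfileobj(src, tmp)
    tmp.close()
    return Path(tmp.name)


# ---------------------------------------------------------------------------
# prmtop reader (minimal flag subset)
# ---------------------------------------------------------------------------

_PRMTOP_REQUIRED = [
    "POINTERS", "ATOM_NAME", "CHARGE", "MASS", "ATOM_TYPE_INDEX",
    "NONBONDED_PARM_INDEX", "LENNARD_JONES_ACOEF", "LENNARD_JONES_BCOEF",
    "RESIDUE_LABEL", "RESIDUE_POINTER",
]


def _parse_prmtop_sections(path) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: str | None = None
    with _open_text(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("%VERSION"):
                continue
            if line.startswith("%FLAG"):
                current = line.split()[1]
                sections[current] = []
            elif line.startswith("%FORMAT"):
                continue
            elif line.startswith("%COMMENT"):
                continue
            elif current is not None:
                sections[current].append(line)
    return sections


def _section_tokens(sections, name) -> list[str]:
    return " ".join(sections[name]).split()


def _section_fixed_width(sections, name, width) -> list[str]:
    out: list[str] = []
    for line in sections[name]:
        for off in range(0, len(line), width):
            tok = line[off:off + width]
            if tok.strip():
                out.append(tok.strip())
    return out


def read_prmtop(path, groups: dict[str, Iterable[int]] | None = None,
                strip_solvent: bool = True) -> Topology:
    """Read the minimal AMBER prmtop flag subset into a Topology.

    Charges are converted from prmtop internal units to e (divide by
    18.2223); per-type LJ A/B coefficients are converted to (rmin/2, ε)
    from the diagonal pairs. RADII/SCREEN are honored when present and
    otherwise filled from an mbondi-style default table keyed on the
    leading letter of the atom name.
    """
    sections = _parse_prmtop_sections(path)
    for name in _PRMTOP_REQUIRED:
        if name not in sections:
            raise TopologyFormatError(f"prmtop missing mandatory section {name}")
    known = set(_PRMTOP_REQUIRED) | {
        "RADII", "SCREEN", "BONDS_INC_HYDROGEN", "BONDS_WITHOUT_HYDROGEN",
        "TITLE", "AMBER_ATOM_TYPE",
    }
    for name in sections:
        if name not in known:
            logger.warning("prmtop: ignoring unknown flag %s", name)

    pointers = [int(x) for x in _section_tokens(sections, "POINTERS")]
    natom, ntypes = pointers[0], pointers[1]
    nres = pointers[11]

    names = _section_fixed_width(sections, "ATOM_NAME", 4)
    charges = [float(x) / PRMTOP_CHARGE_SCALE
               for x in _section_tokens(sections, "CHARGE")]
    masses = [float(x) for x in _section_tokens(sections, "MASS")]
    type_idx = [int(x) for x in _section_tokens(sections, "ATOM_TYPE_INDEX")]
    nb_parm = [int(x) for x in _section_tokens(sections, "NONBONDED_PARM_INDEX")]
    acoef = [float(x) for x in _section_tokens(sections, "LENNARD_JONES_ACOEF")]
    bcoef = [float(x) for x in _section_tokens(sections, "LENNARD_JONES_BCOEF")]
    res_labels = _section_fixed_width(sections, "RESIDUE_LABEL", 4)
    res_ptr = [int(x) for x in _section_tokens(sections, "RESIDUE_POINTER")]

    for label, seq in [("ATOM_NAME", names), ("CHARGE", charges),
                       ("MASS", masses), ("ATOM_TYPE_INDEX", type_idx)]:
        if len(seq) != natom:
            raise TopologyConsistencyError(
                f"{label} has {len(seq)} entries, POINTERS says {natom} atoms")
    if len(res_labels) != nres or len(res_ptr) != nres:
        raise TopologyConsistencyError("residue sections disagree with POINTERS")

    # diagonal LJ pairs -> per-type rmin/2, epsilon
    rmin_half_by_type = np.zeros(ntypes)
    eps_by_type = np.zeros(ntypes)
    for t in range(ntypes):
        k = nb_parm[ntypes * t + t] - 1
        if k < 0:
            continue
        a, b = acoef[k], bcoef[k]
        if a > 0 and b > 0:
            rmin = (2.0 * a / b) ** (1.0 / 6.0)
            rmin_half_by_type[t] = rmin / 2.0
            eps_by_type[t] = b * b / (4.0 * a)

    if "RADII" in sections:
        radii = [float(x) for x in _section_tokens(sections, "RADII")]
    else:
        logger.warning("prmtop has no RADII; filling from default table")
        radii = [DEFAULT_GB_RADII.get(n[0].upper(), DEFAULT_GB_RADIUS_FALLBACK)
                 for n in names]
    if "SCREEN" in sections:
        screens = [float(x) for x in _section_tokens(sections, "SCREEN")]
    else:
        screens = [DEFAULT_GB_SCREEN.get(n[0].upper(), DEFAULT_GB_SCREEN_FALLBACK)
                   for n in names]

    res_starts = [p - 1 for p in res_ptr] + [natom]
    residues = [Residue(res_labels[i], res_starts[i], res_starts[i + 1])
                for i in range(nres)]

    atoms = []
    for i in range(natom):
        ri = next(j for j in range(nres)
                  if res_starts[j] <= i < res_starts[j + 1])
        t = type_idx[i] - 1
        atoms.append(AtomRecord(
            index=i, name=names[i], residue_index=ri,
            residue_name=res_labels[ri], charge=charges[i],
            lj_rmin_half=float(rmin_half_by_type[t]),
            lj_epsilon=float(eps_by_type[t]),
            gb_radius=radii[i], gb_screen=screens[i], mass=masses[i]))

    bonds: list[tuple[int, int]] = []
    for sec in ("BONDS_INC_HYDROGEN", "BONDS_WITHOUT_HYDROGEN"):
        if sec in sections:
            vals = [int(x) for x in _section_tokens(sections, sec)]
            for off in range(0, len(vals), 3):
                bonds.append((vals[off] // 3, vals[off + 1] // 3))

    top = Topology(atoms, residues, bonds,
                   {k: frozenset(v) for k, v in (groups or {}).items()})
    if strip_solvent:
        solvent = [a.residue_name in SOLVENT_RESIDUE_NAMES for a in top.atoms]
        if any(solvent):
            top = top.subset_mask([not s for s in solvent])
    return top


# ---------------------------------------------------------------------------
# param-table (sectioned plain text) read/write
# ---------------------------------------------------------------------------

def write_param_table(topology: Topology, path) -> None:
    """Write the plain sectioned parameter-table format."""
    lines = ["[atoms]",
             "# index name resindex resname charge rmin_half epsilon gb_radius gb_screen mass"]
    for a in topology.atoms:
        lines.append(
            f"{a.index} {a.name} {a.residue_index} {a.residue_name} "
            f"{a.charge:.10g} {a.lj_rmin_half:.10g} {a.lj_epsilon:.10g} "
            f"{a.gb_radius:.10g} {a.gb_screen:.10g} {a.mass:.10g}")
    lines.append("[bonds]")
    for i, j in topology.bonds:
        lines.append(f"{i} {j}")
    lines.append("[groups]")
    for name, grp in topology.groups.items():
        lines.append(name + " " + " ".join(str(i) for i in sorted(grp)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_param_table(path, strip_solvent: bool = True) -> Topology:
    atoms: list[AtomRecord] = []
    bonds: list[tuple[int, int]] = []
    groups: dict[str, frozenset[int]] = {}
    section = None
    with _open_text(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("["):
                section = line.strip("[]")
                continue
            toks = line.split()
            if section == "atoms":
                atoms.append(AtomRecord(
                    index=int(toks[0]), name=toks[1],
                    residue_index=int(toks[2]), residue_name=toks[3],
                    charge=float(toks[4]), lj_rmin_half=float(toks[5]),
                    lj_epsilon=float(toks[6]), gb_radius=float(toks[7]),
                    gb_screen=float(toks[8]), mass=float(toks[9])))
            elif section == "bonds":
                bonds.append((int(toks[0]), int(toks[1])))
            elif section == "groups":
                groups[toks[0]] = frozenset(int(x) for x in toks[1:])
            else:
                raise TopologyFormatError(f"param-table: line outside a section: {line!r}")
    if not atoms:
        raise TopologyFormatError("param-table missing mandatory section [atoms]")
    # rebuild residue partition from the atom table
    residues: list[Residue] = []
    for a in atoms:
        if a.residue_index == len(residues):
            residues.append(Residue(a.residue_name, a.index, a.index + 1))
        elif a.residue_index == len(residues) - 1:
            residues[-1] = Residue(residues[-1].name, residues[-1].start, a.index + 1)
        else:
            raise TopologyConsistencyError("atom residue indices not contiguous")
    top = Topology(atoms, residues, bonds, groups)
    if strip_solvent:
        solvent = [a.residue_name in SOLVENT_RESIDUE_NAMES for a in top.atoms]
        if any(solvent):
            top = top.subset_mask([not s for s in solvent])
    return top


def read_topology(path, format: str = "auto", **kwargs) -> Topology:
    """Read a topology; format in {"amber-prmtop", "param-table", "auto"}."""
    if format == "auto":
        with _open_text(path) as fh:
            head = fh.read(200)
        format = "amber-prmtop" if "%FLAG" in head or "%VERSION" in head else "param-table"
    if format == "amber-prmtop":
        return read_prmtop(path, **kwargs)
    if format == "param-table":
        return read_param_table(path, **kwargs)
    raise ValueError(f"unknown topology format {format!r}")


# ---------------------------------------------------------------------------
# PDB (multi-model, fixed column)
# ---------------------------------------------------------------------------

def write_pdb(topology: Topology, trajectory_or_frame, path) -> None:
    """Write fixed-column PDB; multiple frames become MODEL blocks."""
    if isinstance(trajectory_or_frame, Frame):
        coords = trajectory_or_frame.coordinates[None]
    else:
        coords = trajectory_or_frame.coordinates
    with open(path, "w") as fh:
        multi = coords.shape[0] > 1
        for m in range(coords.shape[0]):
            if multi:
                fh.write(f"MODEL     {m + 1:4d}\n")
            for a in topology.atoms:
                x, y, z = coords[m, a.index]
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                fh.write(
                    f"ATOM  {a.index + 1:5d} {name:<4.4s} {a.residue_name:<4.4s}"
                    f"{a.residue_index + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def read_pdb_frames(path, topology: Topology | None = None) -> np.ndarray:
    """Read coordinates from a (multi-model) PDB, shape (F, N, 3)."""
    frames: list[list[list[float]]] = []
    current: list[list[float]] = []
    with _open_text(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                current.append([float(line[30:38]), float(line[38:46]),
                                float(line[46:54])])
            elif rec.startswith(("ENDMDL", "END")):
                if current:
                    frames.append(current)
                    current = []
    if current:
        frames.append(current)
    if not frames:
        raise TrajectoryFormatError(f"no coordinates found in {path}")
    n0 = len(frames[0])
    for k, f in enumerate(frames):
        if len(f) != n0:
            raise TrajectoryFormatError(
                f"truncated frame: last complete frame index {k - 1}")
    coords = np.array(frames)
    if topology is not None and coords.shape[1] != topology.n_atoms:
        raise TrajectoryFormatError(
            f"PDB has {coords.shape[1]} atoms per frame, topology has {topology.n_atoms}")
    return coords


# ---------------------------------------------------------------------------
# DCD via mdtraj's low-level file object (coordinates already in Å)
# ---------------------------------------------------------------------------

def write_dcd(trajectory: Trajectory, path) -> None:
    from mdtraj.formats import DCDTrajectoryFile
    with DCDTrajectoryFile(str(path), "w") as fh:
        fh.write(np.asarray(trajectory.coordinates, dtype=np.float32))


def read_dcd(path, topology: Topology | None = None) -> np.ndarray:
    from mdtraj.formats import DCDTrajectoryFile
    real = _maybe_decompress_binary(path)
    with DCDTrajectoryFile(str(real)) as fh:
        xyz, _, _ = fh.read()
    coords = np.asarray(xyz, dtype=float)
    if topology is not None and coords.shape[1] != topology.n_atoms:
        raise TrajectoryFormatError(
            f"DCD has {coords.shape[1]} atoms per frame, topology has {topology.n_atoms}")
    return coords


def read_trajectory(path, topology: Topology | None = None,
                    format: str = "auto", seed_id: int | None = None) -> Trajectory:
    """Read a trajectory; format in {"dcd", "multi-model-pdb", "auto"}."""
    if format == "auto":
        suffix = Path(path).name.lower()
        format = "dcd" if ".dcd" in suffix else "multi-model-pdb"
    if format == "dcd":
        coords = read_dcd(path, topology)
    elif format == "multi-model-pdb":
        coords = read_pdb_frames(path, topology)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    return Trajectory(coords, seed_id=seed_id)


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def rmsd(frame: Frame, reference: Frame, selection: Sequence[int] | None = None,
         superpose: bool = True) -> float:
    """RMSD (Å) between two frames over a selection.

    With superpose=True the optimal rigid-body least-squares fit (Kabsch)
    is applied before the deviation is measured.
    """
    if selection is None:
        selection = range(frame.n_atoms)
    sel = np.asarray(list(selection), dtype=int)
    if sel.size == 0:
        raise ValueError("empty selection")
    p = frame.coordinates[sel]
    q = reference.coordinates[sel]
    if superpose:
        pc = p - p.mean(axis=0)
        qc = q - q.mean(axis=0)
        rot = geometry.kabsch_rotation(pc, qc)
        p = (rot @ pc.T).T
        q = qc
    diff = p - q
    return float(np.sqrt((diff * diff).sum() / sel.size))
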