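"""Dihedral Gibbs configurational entropy and rotamer-state profiling.

Each torsion angle is treated as an independent one-dimensional degree of
freedom. Its entropy is the Gibbs formula S = -R Σ p ln p over a periodic
equal-width histogram of the sampled angle, and mutation-induced changes
are summed per class (phi, psi, omega, sidechain). Rotamer states are the
occupied wells of the circularly smoothed angle density: their count is
the conformational part of the flexibility story and their widths the
vibrational part.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .constants import GAS_CONSTANT
from .geometry import torsion, wrap_angle
from .system_io import Frame, SeedEnsemble, Topology, Trajectory

logger = logging.getLogger(__name__)

BACKBONE_CLASSES = ("phi", "psi", "omega")

#: torsion chains for known sidechains: residue name -> list of
#: (label, 4 atom names); atoms may come from the previous residue via "-".
_SIDECHAIN_TABLE = {
    # phospho-threonine-like (methyl present)
    "TPO": [("chi1", ("N", "CA", "CB", "OG1")),
            ("chi2", ("CA", "CB", "OG1", "P")),
            ("chi3", ("CB", "OG1", "P", "O1P")),
            ("methyl", ("OG1", "CB", "CG2", "HG21"))],
    # phospho-serine-like
    "SEP": [("chi1", ("N", "CA", "CB", "OG1")),
            ("chi2", ("CA", "CB", "OG1", "P")),
            ("chi3", ("CB", "OG1", "P", "O1P"))],
    "THR": [("chi1", ("N", "CA", "CB", "OG1"))],
    "SER": [("chi1", ("N", "CA", "CB", "OG"))],
}
# allow OG naming on the phospho-serine template
_SIDECHAIN_TABLE["SEP_OG"] = [("chi1", ("N", "CA", "CB", "OG")),
                              ("chi2", ("CA", "CB", "OG", "P")),
                              ("chi3", ("CB", "OG", "P", "O1P"))]


@dataclass(frozen=True)
class DihedralDefinition:
    atom_indices: tuple[int, int, int, int]
    dihedral_class: str  # phi | psi | omega | chi1 | chi2 | ... | methyl
    residue_index: int

    def __post_init__(self):
        if len(set(self.atom_indices)) != 4:
            raise ValueError("dihedral needs four distinct atoms")

    @property
    def entropy_class(self) -> str:
        """Coarse class used in the decomposition: backbone name or 'sidechain'."""
        return (self.dihedral_class
                if self.dihedral_class in BACKBONE_CLASSES else "sidechain")

    @property
    def match_key(self) -> tuple[int, str]:
        """Key used to pair wild and mutant dihedrals."""
        return (self.residue_index, self.dihedral_class)


@dataclass
class DihedralSeries:
    definition: DihedralDefinition
    angles: np.ndarray  # degrees in [-180, 180)
    seed_id: int | None = None

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.size and (self.angles.min() < -180.0 or
                                 self.angles.max() >= 180.0):
            self.angles = wrap_angle(self.angles)


@dataclass
class EntropyRecord:
    """Class-wise T·ΔS (kcal/mol) with total = sum of the four classes."""

    tds_phi: float
    tds_psi: float
    tds_omega: float
    tds_sidechain: float
    tds_total: float
    temperature: float = 300.0
    bin_count: int = 36
    per_dihedral: dict = field(default_factory=dict)
    unmatched: list = field(default_factory=list)

    @classmethod
    def from_class_sums(cls, tds_phi: float, tds_psi: float, tds_omega: float,
                        tds_sidechain: float, temperature: float = 300.0,
                        bin_count: int = 36, **kw) -> "EntropyRecord":
        total = tds_phi + tds_psi + tds_omega + tds_sidechain
        return cls(tds_phi, tds_psi, tds_omega, tds_sidechain, total,
                   temperature=temperature, bin_count=bin_count, **kw)


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def extract_dihedrals(topology: Topology,
                      residues: Iterable[int] | None = None) -> list[DihedralDefinition]:
    """Backbone phi/psi/omega plus known sidechain chi chains.

    Backbone torsions need the neighbor residue's atoms (no phi at a chain
    start, no psi/omega partner at an end). Residues missing a backbone
    atom are skipped with a logged warning. Glycine-like residues (no CB)
    yield no chi torsions.
    """
    if residues is None:
        residues = range(topology.n_residues)
    out: list[DihedralDefinition] = []
    for ri in residues:
        n = topology.find_atom(ri, "N")
        ca = topology.find_atom(ri, "CA")
        c = topology.find_atom(ri, "C")
        if None in (n, ca, c):
            logger.warning("residue %d (%s): missing backbone atom, skipped",
                           ri, topology.residues[ri].name)
            continue
        if ri > 0:
            c_prev = topology.find_atom(ri - 1, "C")
            ca_prev = topology.find_atom(ri - 1, "CA")
            if c_prev is not None:
                out.append(DihedralDefinition((c_prev, n, ca, c), "phi", ri))
            if c_prev is not None and ca_prev is not None:
                out.append(DihedralDefinition((ca_prev, c_prev, n, ca), "omega", ri))
        if ri < topology.n_residues - 1:
            n_next = topology.find_atom(ri + 1, "N")
            if n_next is not None:
                out.append(DihedralDefinition((n, ca, c, n_next), "psi", ri))
        # sidechain chains by residue-name table
        rname = topology.residues[ri].name
        table = _SIDECHAIN_TABLE.get(rname)
        if table is None and rname.startswith("SEP"):
            table = _SIDECHAIN_TABLE["SEP"]
        if table is None:
            continue
        if rname == "SEP" and topology.find_atom(ri, "OG1") is None \
                and topology.find_atom(ri, "OG") is not None:
            table = _SIDECHAIN_TABLE["SEP_OG"]
        for label, names in table:
            idx = [topology.find_atom(ri, nm) for nm in names]
            if None in idx:
                continue
            out.append(DihedralDefinition(tuple(idx), label, ri))
    return out


def dihedral_angle(frame: Frame, defn: DihedralDefinition) -> float:
    """Signed torsion in degrees, [-180, 180), atan2 construction."""
    a, b, c, d = (frame.coordinates[i] for i in defn.atom_indices)
    return torsion(a, b, c, d)


def dihedral_series(topology: Topology, ensemble_or_traj,
                    definitions: Sequence[DihedralDefinition],
                    pool_seeds: bool = True) -> dict:
    """Angle time series for each definition over a trajectory or ensemble.

    With pool_seeds, frames from all seeds are concatenated in seed order
    into one pooled series per dihedral (the presentation used for the
    distribution plots); otherwise a list of per-seed series is returned.
    """
    if isinstance(ensemble_or_traj, Trajectory):
        trajs, seeds = [ensemble_or_traj], [ensemble_or_traj.seed_id]
    else:
        trajs = ensemble_or_traj.trajectories
        seeds = ensemble_or_traj.seed_ids
    per_seed: dict = {d: [] for d in definitions}
    for traj, seed in zip(trajs, seeds):
        coords = traj.coordinates
        for d in definitions:
            a, b, c, e = d.atom_indices
            angles = _torsion_batch(coords[:, a], coords[:, b],
                                    coords[:, c], coords[:, e])
            per_seed[d].append(DihedralSeries(d, angles, seed_id=seed))
    if pool_seeds:
        return {d: DihedralSeries(d, np.concatenate([s.angles for s in lst]))
                for d, lst in per_seed.items()}
    return per_seed


def _torsion_batch(a, b, c, d) -> np.ndarray:
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
    x = (n1 * n2).sum(axis=1)
    y = (m1 * n2).sum(axis=1)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


# ---------------------------------------------------------------------------
# entropy
# ---------------------------------------------------------------------------

def histogram_probabilities(angles: np.ndarray, bins: int = 36) -> np.ndarray:
    """Equal-width periodic histogram probabilities over [-180, 180).

    Bins are left-closed/right-open; angles are wrapped first.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    a = wrap_angle(np.asarray(angles, dtype=float))
    counts, _ = np.histogram(a, bins=bins, range=(-180.0, 180.0))
    return counts / counts.sum()


def gibbs_entropy(series, bins: int = 36,
                  temperature: float = 300.0) -> tuple[float, float]:
    """(S in kcal/(mol·K), T·S in kcal/mol) of a pooled angle series.

    S = -R Σ p ln p with 0·ln 0 := 0 and R = 1.9872e-3 kcal/(mol·K).
    """
    angles = series.angles if isinstance(series, DihedralSeries) else np.asarray(series)
    if angles.size == 0:
        raise ValueError("empty angle series")
    p = histogram_probabilities(angles, bins=bins)
    nz = p[p > 0]
    s = float(-GAS_CONSTANT * (nz * np.log(nz)).sum())
    return s, temperature * s


def entropy_from_probabilities(p: np.ndarray,
                               temperature: float = 300.0) -> tuple[float, float]:
    """Gibbs entropy of an explicit binned distribution."""
    p = np.asarray(p, dtype=float)
    p = p / p.sum()
    nz = p[p > 0]
    s = float(-GAS_CONSTANT * (nz * np.log(nz)).sum())
    return s, temperature * s


def entropy_decomposition(wild: Iterable[DihedralSeries],
                          mutant: Iterable[DihedralSeries],
                          temperature: float = 300.0,
                          bins: int = 36) -> EntropyRecord:
    """Class-wise T·ΔS = T·(S_mutant − S_wild) over matched dihedrals.

    Dihedrals are paired by (residue index, torsion label); torsions that
    exist on only one side — e.g. the threonine methyl rotor — are
    excluded from the sums and reported in `unmatched`.
    """
    wild_map = {s.definition.match_key: s for s in wild}
    mut_map = {s.definition.match_key: s for s in mutant}
    matched = sorted(set(wild_map) & set(mut_map))
    if not matched:
        raise ValueError("no matchable dihedrals between wild and mutant")
    unmatched = sorted((set(wild_map) ^ set(mut_map)))
    class_sums = {"phi": 0.0, "psi": 0.0, "omega": 0.0, "sidechain": 0.0}
    per_dihedral = {}
    for key in matched:
        w = wild_map[key]
        m = mut_map[key]
        _, ts_w = gibbs_entropy(w, bins=bins, temperature=temperature)
        _, ts_m = gibbs_entropy(m, bins=bins, temperature=temperature)
        dts = ts_m - ts_w
        per_dihedral[key] = {"tds_wild": ts_w, "tds_mutant": ts_m, "tds_delta": dts}
        class_sums[w.definition.entropy_class] += dts
    return EntropyRecord.from_class_sums(
        class_sums["phi"], class_sums["psi"], class_sums["omega"],
        class_sums["sidechain"], temperature=temperature, bin_count=bins,
        per_dihedral=per_dihedral, unmatched=list(unmatched))


# ---------------------------------------------------------------------------
# rotamer states
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RotamerStates:
    n_states: int
    populations: tuple[float, ...]
    circular_means: tuple[float, ...]  # degrees
    widths: tuple[float, ...]          # circular std per state, degrees


def circular_mean(angles_deg: np.ndarray) -> float:
    rad = np.radians(angles_deg)
    return float(wrap_angle(np.degrees(
        np.arctan2(np.sin(rad).mean(), np.cos(rad).mean()))))


def circular_std(angles_deg: np.ndarray) -> float:
    rad = np.radians(angles_deg)
    r = np.hypot(np.sin(rad).mean(), np.cos(rad).mean())
    r = min(max(r, 1e-12), 1.0)
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))


def rotamer_states(series, smoothing: float = 15.0,
                   floor: float = 0.01, grid: int = 360) -> RotamerStates:
    """Occupied wells of a torsion distribution.

    The empirical angle density is smoothed with a circular (von Mises)
    kernel of the given bandwidth (degrees); states are the maximal
    regions between valleys of the smoothed density whose peak exceeds
    `floor` occupancy-density (uniform = 1/360 per degree scaled to 1);
    sub-floor regions are merged into their taller neighbor. Populations
    sum to 1.
    """
    angles = series.angles if isinstance(series, DihedralSeries) else np.asarray(series)
    if angles.size < 100:
        logger.warning("rotamer_states: only %d samples (<100 recommended)",
                       angles.size)
    rad = np.radians(wrap_angle(angles))
    kappa = (180.0 / (np.pi * smoothing)) ** 2  # kernel concentration
    grid_rad = np.linspace(-np.pi, np.pi, grid, endpoint=False)
    # von Mises KDE, normalization irrelevant for valley finding
    diff = grid_rad[:, None] - rad[None, :]
    dens = np.exp(kappa * (np.cos(diff) - 1.0)).sum(axis=1)
    dens /= dens.sum()

    # circular local minima
    left = np.roll(dens, 1)
    right = np.roll(dens, -1)
    valleys = np.where((dens <= left) & (dens < right))[0]
    if valleys.size == 0:
        pop = 1.0
        return RotamerStates(1, (pop,), (circular_mean(angles),),
                             (circular_std(angles),))

    # segments between consecutive valleys (circular)
    segments: list[np.ndarray] = []
    vs = sorted(valleys.tolist())
    for k in range(len(vs)):
        start = vs[k]
        stop = vs[(k + 1) % len(vs)]
        if stop > start:
            segments.append(np.arange(start, stop))
        else:
            segments.append(np.concatenate([np.arange(start, grid),
                                            np.arange(0, stop)]))
    # assign samples to segments via grid index
    idx = ((np.degrees(rad) + 180.0) / 360.0 * grid).astype(int) % grid
    seg_of_grid = np.empty(grid, dtype=int)
    for si, seg in enumerate(segments):
        seg_of_grid[seg] = si
    assign = seg_of_grid[idx]

    # a state must hold at least `floor` of the samples
    occupancy = np.array([(assign == si).mean() for si in range(len(segments))])
    keep = [si for si in range(len(segments)) if occupancy[si] >= floor]
    if not keep:
        keep = [int(np.argmax(occupancy))]
    # merge dropped segments into the taller circular neighbor among kept
    for si in range(len(segments)):
        if si in keep:
            continue
        order = sorted(keep, key=lambda kk: min(
            abs(kk - si), len(segments) - abs(kk - si)))
        target = order[0]
        assign[assign == si] = target

    states = []
    for si in keep:
        sel = angles[assign == si]
        if sel.size == 0:
            continue
        states.append((sel.size / angles.size, circular_mean(sel),
                       circular_std(sel)))
    states.sort(key=lambda t: -t[0])
    return RotamerStates(
        n_states=len(states),
        populations=tuple(s[0] for s in states),
        circular_means=tuple(s[1] for s in states),
        widths=tuple(s[2] for s in states))


def angle_shift(series_a, series_b) -> float:
    """Absolute circular shift (degrees) between two distributions' means."""
    a = series_a.angles if isinstance(series_a, DihedralSeries) else np.asarray(series_a)
    b = series_b.angles if isinstance(series_b, DihedralSeries) else np.asarray(series_b)
    return abs(wrap_angle(circular_mean(b) - circular_mean(a)))
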