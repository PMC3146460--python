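"""Molecular-mechanics and implicit-solvent energy kernels.

The four kernels behind the end-point interaction-energy decomposition:

* intermolecular Coulomb with hard cutoff,
* intermolecular Lennard-Jones (rmin/epsilon form, Lorentz–Berthelot-style
  combining on rmin/2 and geometric mean on epsilon),
* generalized-Born polar solvation with HCT pairwise-descreening effective
  radii (the igb=1 flavor) and the canonical Still pair function,
* Shrake–Rupley solvent-accessible surface area and the linear
  SASA→energy non-polar term.

All energies are kcal/mol, all distances Å, charges in e.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .constants import (
    COULOMB_CONSTANT,
    DEFAULT_NONBONDED_CUTOFF,
    DEFAULT_SASA_POINTS,
    DEFAULT_SASA_PROBE,
    GB_EXTERIOR_DIELECTRIC,
    GB_INTERIOR_DIELECTRIC,
    NONPOLAR_PRESETS,
)
from .system_io import Frame, Topology


class GroupOverlapError(ValueError):
    """Intermolecular kernels require disjoint atom groups."""


class SingularGeometryError(ValueError):
    """Two atoms closer than the numerical floor."""


class BornRadiusError(ArithmeticError):
    """A computed effective Born radius came out non-positive."""


@dataclass(frozen=True)
class EnergyComponents:
    """The decomposed interaction-energy terms and their derived sums.

    Invariants (enforced on assembly): E_ele = U_coul + W_polar,
    E_tot = E_ele + U_vdw + W_np, E_tot_np = E_tot - W_np.
    """

    U_vdw: float
    U_coul: float
    W_polar: float
    W_np: float
    E_ele: float
    E_tot_np: float
    E_tot: float
    polar_model: str = "GB"

    @classmethod
    def assemble(cls, U_vdw: float, U_coul: float, W_polar: float,
                 W_np: float, polar_model: str = "GB") -> "EnergyComponents":
        E_ele, E_tot, E_tot_np = combine_components(U_vdw, U_coul, W_polar, W_np)
        return cls(U_vdw=U_vdw, U_coul=U_coul, W_polar=W_polar, W_np=W_np,
                   E_ele=E_ele, E_tot_np=E_tot_np, E_tot=E_tot,
                   polar_model=polar_model)

    def __post_init__(self):
        if abs(self.E_ele - (self.U_coul + self.W_polar)) > 1e-6:
            raise ValueError("E_ele != U_coul + W_polar")
        if abs(self.E_tot - (self.E_ele + self.U_vdw + self.W_np)) > 1e-6:
            raise ValueError("E_tot != E_ele + U_vdw + W_np")
        if abs(self.E_tot_np - (self.E_tot - self.W_np)) > 1e-6:
            raise ValueError("E_tot_np != E_tot - W_np")


def combine_components(U_vdw: float, U_coul: float, W_polar: float,
                       W_np: float) -> tuple[float, float, float]:
    """Derived sums: (E_ele, E_tot, E_tot_np)."""
    E_ele = U_coul + W_polar
    E_tot = E_ele + U_vdw + W_np
    E_tot_np = E_tot - W_np
    return E_ele, E_tot, E_tot_np


# ---------------------------------------------------------------------------
# pair kernels
# ---------------------------------------------------------------------------

def _check_groups(group_a: Sequence[int], group_b: Sequence[int]):
    a = np.asarray(list(group_a), dtype=int)
    b = np.asarray(list(group_b), dtype=int)
    if np.intersect1d(a, b).size:
        raise GroupOverlapError("groups overlap; intermolecular kernels need disjoint sets")
    return a, b


def _pair_distances(frame: Frame, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    diff = frame.coordinates[a][:, None, :] - frame.coordinates[b][None, :, :]
    r = np.sqrt((diff * diff).sum(axis=2))
    if np.any(r < 1e-6):
        raise SingularGeometryError("atom pair closer than 1e-6 Å")
    return r


def coulomb_energy(topology: Topology, frame: Frame,
                   group_a: Sequence[int], group_b: Sequence[int],
                   cutoff: float = DEFAULT_NONBONDED_CUTOFF,
                   dielectric: float = 1.0) -> float:
    """Intermolecular Coulomb sum with hard truncation at the cutoff."""
    a, b = _check_groups(group_a, group_b)
    r = _pair_distances(frame, a, b)
    q = topology.charges()
    qq = np.outer(q[a], q[b])
    mask = r <= cutoff
    return float(COULOMB_CONSTANT / dielectric * (qq[mask] / r[mask]).sum())


def lj_energy(topology: Topology, frame: Frame,
              group_a: Sequence[int], group_b: Sequence[int],
              cutoff: float = DEFAULT_NONBONDED_CUTOFF) -> float:
    """Intermolecular Lennard-Jones sum, ε[(rmin/r)^12 − 2(rmin/r)^6]."""
    a, b = _check_groups(group_a, group_b)
    r = _pair_distances(frame, a, b)
    rmh = topology.lj_rmin_half()
    eps = topology.lj_epsilon()
    rmin = rmh[a][:, None] + rmh[b][None, :]
    e = np.sqrt(np.outer(eps[a], eps[b]))
    mask = (r <= cutoff) & (e > 0)
    s6 = (rmin[mask] / r[mask]) ** 6
    return float((e[mask] * (s6 * s6 - 2.0 * s6)).sum())


# ---------------------------------------------------------------------------
# generalized Born (HCT pairwise descreening, Still pair function)
# ---------------------------------------------------------------------------

def effective_born_radii(topology: Topology, frame: Frame,
                         group: Sequence[int], offset: float = 0.0) -> np.ndarray:
    """HCT effective Born radii for the atoms of `group`.

    The descreening integral over each neighbor j (intrinsic radius ρ_j,
    screen s_j) reduces the inverse radius of i below 1/ρ_i:

        1/R_i = 1/ρ_i − Σ_j I(r_ij, ρ_i, s_j ρ_j)

    with the standard closed-form pairwise integral I. The stored
    gb_radius is used directly as ρ (see the package methods note on the
    offset convention); `offset` subtracts a constant first if nonzero.
    """
    idx = np.asarray(list(group), dtype=int)
    coords = frame.coordinates[idx]
    rho = topology.gb_radii()[idx] - offset
    if np.any(rho <= 0):
        bad = idx[np.argmin(rho)]
        raise BornRadiusError(f"non-positive intrinsic radius for atom {bad}")
    scaled = topology.gb_screens()[idx] * rho

    n = idx.size
    inv_r = 1.0 / rho
    if n > 1:
        diff = coords[:, None, :] - coords[None, :, :]
        r = np.sqrt((diff * diff).sum(axis=2))
        np.fill_diagonal(r, np.inf)
        sr = scaled[None, :]            # s_j ρ_j for each neighbor j
        rho_i = rho[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            L = np.maximum(np.abs(r - sr), rho_i)
            U = r + sr
            active = (U > rho_i) & np.isfinite(r)
            I = 0.5 * (1.0 / L - 1.0 / U
                       + (r / 4.0) * (1.0 / U ** 2 - 1.0 / L ** 2)
                       + (1.0 / (2.0 * r)) * np.log(L / U)
                       + (sr ** 2 / (4.0 * r)) * (1.0 / L ** 2 - 1.0 / U ** 2))
            I = np.where(active, I, 0.0)
        inv_r = inv_r - I.sum(axis=1)
    if np.any(inv_r <= 0):
        bad = idx[int(np.argmin(inv_r))]
        raise BornRadiusError(f"non-positive effective Born radius for atom {bad}")
    return 1.0 / inv_r


def gb_energy(topology: Topology, frame: Frame, group: Sequence[int],
              interior_dielectric: float = GB_INTERIOR_DIELECTRIC,
              exterior_dielectric: float = GB_EXTERIOR_DIELECTRIC,
              offset: float = 0.0) -> float:
    """Generalized-Born polar solvation free energy of a group, kcal/mol.

    ΔG = −½ k_e (1/ε_in − 1/ε_out) Σ_ij q_i q_j / f_GB(r_ij, R_i, R_j)
    with f_GB = sqrt(r² + R_i R_j exp(−r²/(4 R_i R_j))) and the self terms
    (i = j, f_GB = R_i) included; no cutoff is applied.
    """
    idx = np.asarray(list(group), dtype=int)
    born = effective_born_radii(topology, frame, idx, offset=offset)
    q = topology.charges()[idx]
    coords = frame.coordinates[idx]
    diff = coords[:, None, :] - coords[None, :, :]
    r2 = (diff * diff).sum(axis=2)
    rr = born[:, None] * born[None, :]
    fgb = np.sqrt(r2 + rr * np.exp(-r2 / (4.0 * rr)))
    tau = 1.0 / interior_dielectric - 1.0 / exterior_dielectric
    return float(-0.5 * COULOMB_CONSTANT * tau * (np.outer(q, q) / fgb).sum())


# ---------------------------------------------------------------------------
# SASA (Shrake–Rupley with deterministic golden-spiral points)
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere points (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def sasa(topology: Topology, frame: Frame, group: Sequence[int],
         probe: float = DEFAULT_SASA_PROBE,
         n_sphere_points: int = DEFAULT_SASA_POINTS,
         radii: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Solvent-accessible surface area of a group, Å².

    Shrake–Rupley point counting on probe-expanded van der Waals spheres.
    Radii default to the Lennard-Jones rmin/2 of each atom. Returns
    (total area, per-atom areas); per-atom areas sum to the total.
    """
    idx = np.asarray(list(group), dtype=int)
    coords = frame.coordinates[idx]
    if radii is None:
        radii = topology.lj_rmin_half()[idx]
    else:
        radii = np.asarray(radii, dtype=float)
    expanded = radii + probe
    pts = _sphere_points(n_sphere_points)
    n = idx.size
    areas = np.zeros(n)
    if n == 1:
        areas[0] = 4.0 * np.pi * expanded[0] ** 2
        return float(areas.sum()), areas
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff * diff).sum(axis=2))
    for i in range(n):
        neighbors = np.where((dist[i] < expanded[i] + expanded) &
                             (np.arange(n) != i))[0]
        test = coords[i] + expanded[i] * pts  # (P, 3)
        if neighbors.size:
            d2 = ((test[:, None, :] - coords[neighbors][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (expanded[neighbors] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * frac
    return float(areas.sum()), areas


def nonpolar_energy(sasa_value: float, gamma: float = NONPOLAR_PRESETS["pb"][0],
                    beta: float = NONPOLAR_PRESETS["pb"][1]) -> float:
    """Linear SASA non-polar solvation term, γ·SASA + β (kcal/mol)."""
    if sasa_value < 0:
        raise ValueError("SASA must be non-negative")
    return gamma * sasa_value + beta


# ---------------------------------------------------------------------------
# Poisson–Boltzmann adapter interface
# ---------------------------------------------------------------------------

#: Signature an external PB solver must match to stand in for gb_energy.
PBSolver = Callable[[Topology, Frame, Sequence[int]], float]


def pb_energy(topology: Topology, frame: Frame, group: Sequence[int],
              solver: PBSolver | None = None) -> float:
    """Polar solvation via an external Poisson–Boltzmann solver.

    This package implements GB only; PB is an adapter slot. The callable
    receives (topology, frame, group) and must return kcal/mol.
    """
    if solver is None:
        raise NotImplementedError(
            "no Poisson-Boltzmann solver configured; supply solver= or use the GB model")
    return float(solver(topology, frame, group))
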