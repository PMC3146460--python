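"""Energy kernels against closed forms and brute-force oracles."""

import numpy as np
import pytest

from phosdelta.constants import COULOMB_CONSTANT
from phosdelta.mm_energetics import (
    BornRadiusError, EnergyComponents, GroupOverlapError,
    SingularGeometryError, coulomb_energy, effective_born_radii,
    combine_components, gb_energy, lj_energy, nonpolar_energy, pb_energy, sasa,
)
from phosdelta.system_io import Frame

from conftest import simple_topology


def _pair_frame(r):
    return Frame(np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]))


# ---------------------------------------------------------------------------
# Coulomb
# ---------------------------------------------------------------------------

class TestCoulomb:
    def test_unit_charges_at_one_angstrom(self, two_atom_top):
        e = coulomb_energy(two_atom_top, _pair_frame(1.0), [0], [1])
        assert e == pytest.approx(COULOMB_CONSTANT)

    def test_hard_cutoff(self, two_atom_top):
        assert coulomb_energy(two_atom_top, _pair_frame(40.01), [0], [1]) == 0.0
        assert coulomb_energy(two_atom_top, _pair_frame(39.99), [0], [1]) != 0.0

    def test_dielectric_scaling(self, two_atom_top):
        e1 = coulomb_energy(two_atom_top, _pair_frame(2.0), [0], [1], dielectric=1.0)
        e4 = coulomb_energy(two_atom_top, _pair_frame(2.0), [0], [1], dielectric=4.0)
        assert e4 == pytest.approx(e1 / 4.0)

    def test_overlapping_groups_rejected(self, two_atom_top):
        with pytest.raises(GroupOverlapError):
            coulomb_energy(two_atom_top, _pair_frame(1.0), [0, 1], [1])

    def test_singular_geometry_rejected(self, two_atom_top):
        with pytest.raises(SingularGeometryError):
            coulomb_energy(two_atom_top, _pair_frame(1e-8), [0], [1])

    def test_matches_brute_force_on_random_systems(self):
        # independent O(N^2) double loop, written before the kernel
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(4, 21))
            q = rng.uniform(-1, 1, n)
            xyz = rng.uniform(-15, 15, (n, 3))
            na = int(rng.integers(1, n))
            top = simple_topology(list(q))
            frame = Frame(xyz)
            a, b = list(range(na)), list(range(na, n))
            expected = 0.0
            for i in a:
                for j in b:
                    r = np.sqrt(((xyz[i] - xyz[j]) ** 2).sum())
                    if r <= 40.0:
                        expected += COULOMB_CONSTANT * q[i] * q[j] / r
            assert coulomb_energy(top, frame, a, b) == pytest.approx(expected, abs=1e-8)

    def test_additive_over_partition(self):
        rng = np.random.default_rng(7)
        top = simple_topology(list(rng.uniform(-1, 1, 9)))
        frame = Frame(rng.uniform(-8, 8, (9, 3)))
        whole = coulomb_energy(top, frame, [0, 1, 2], list(range(3, 9)))
        parts = (coulomb_energy(top, frame, [0, 1, 2], [3, 4, 5]) +
                 coulomb_energy(top, frame, [0, 1, 2], [6, 7, 8]))
        assert whole == pytest.approx(parts, abs=1e-10)


# ---------------------------------------------------------------------------
# Lennard-Jones
# ---------------------------------------------------------------------------

class TestLennardJones:
    def test_minimum_is_minus_epsilon(self):
        top = simple_topology([0.0, 0.0], rmin_half=[1.6, 2.0],
                              epsilon=[0.2, 0.05])
        rmin = 1.6 + 2.0
        eps = np.sqrt(0.2 * 0.05)
        assert lj_energy(top, _pair_frame(rmin), [0], [1]) == pytest.approx(-eps)

    def test_zero_crossing(self):
        top = simple_topology([0.0, 0.0], rmin_half=[1.7, 1.7], epsilon=[0.3, 0.3])
        r0 = (1.7 + 1.7) / 2.0 ** (1.0 / 6.0)
        assert lj_energy(top, _pair_frame(r0), [0], [1]) == pytest.approx(0.0, abs=1e-10)

    def test_matches_brute_force_on_random_systems(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = 8
            rmh = rng.uniform(1.2, 2.2, n)
            eps = rng.uniform(0.01, 0.3, n)
            # keep pairs off the steep repulsive wall so the comparison
            # is meaningful at 1e-8 absolute
            while True:
                xyz = rng.uniform(-10, 10, (n, 3))
                d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=2)
                if d[np.triu_indices(n, 1)].min() > 2.0:
                    break
            top = simple_topology([0.0] * n, rmin_half=list(rmh), epsilon=list(eps))
            a, b = [0, 1, 2], [3, 4, 5, 6, 7]
            expected = 0.0
            for i in a:
                for j in b:
                    r = np.sqrt(((xyz[i] - xyz[j]) ** 2).sum())
                    if r <= 40.0:
                        rm = rmh[i] + rmh[j]
                        e = np.sqrt(eps[i] * eps[j])
                        expected += e * ((rm / r) ** 12 - 2 * (rm / r) ** 6)
            got = lj_energy(top, Frame(xyz), a, b)
            assert got == pytest.approx(expected, abs=1e-8)


# ---------------------------------------------------------------------------
# generalized Born
# ---------------------------------------------------------------------------

def _hct_radii_oracle(xyz, rho, screen):
    """Scalar-loop HCT radii, independent of the vectorized kernel."""
    n = len(rho)
    out = []
    for i in range(n):
        inv = 1.0 / rho[i]
        for j in range(n):
            if j == i:
                continue
            r = float(np.linalg.norm(xyz[i] - xyz[j]))
            sj = screen[j] * rho[j]
            U = r + sj
            if rho[i] >= U:
                continue
            L = max(abs(r - sj), rho[i])
            term = (1.0 / L - 1.0 / U
                    + r / 4.0 * (1.0 / U ** 2 - 1.0 / L ** 2)
                    + 1.0 / (2.0 * r) * np.log(L / U)
                    + sj ** 2 / (4.0 * r) * (1.0 / L ** 2 - 1.0 / U ** 2))
            inv -= 0.5 * term
        out.append(1.0 / inv)
    return np.array(out)


class TestGeneralizedBorn:
    def test_born_ion_limit(self):
        # single ion: ΔG = -(ke/2)(1 - 1/80) q² / a
        top = simple_topology([1.0], gb_radius=[2.0])
        e = gb_energy(top, Frame(np.zeros((1, 3))), [0])
        assert e == pytest.approx(-166.0318 * (1 - 1.0 / 80) * 1.0 / 2.0, abs=1e-3)
        assert e == pytest.approx(-81.98, abs=0.01)

    def test_separability_limit(self):
        # far apart, the energy approaches the sum of the Born self terms
        top = simple_topology([0.5, 0.5], gb_radius=[1.8, 2.2])
        far = gb_energy(top, _pair_frame(1e5), [0, 1])
        selfsum = (gb_energy(top, Frame(np.zeros((1, 3))), [0]) +
                   gb_energy(top, _pair_frame(1e5), [1]))
        assert far == pytest.approx(selfsum, abs=0.01)

    def test_hct_radii_match_independent_oracle(self):
        rng = np.random.default_rng(3)
        xyz = rng.uniform(-2.5, 2.5, (5, 3))
        rho = rng.uniform(1.2, 2.0, 5)
        screen = rng.uniform(0.7, 0.95, 5)
        top = simple_topology([0.1] * 5, gb_radius=list(rho),
                              gb_screen=list(screen))
        got = effective_born_radii(top, Frame(xyz), range(5))
        want = _hct_radii_oracle(xyz, rho, screen)
        np.testing.assert_allclose(got, want, atol=1e-4)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(4)
        xyz = rng.uniform(-3, 3, (6, 3))
        top = simple_topology(list(rng.uniform(-0.5, 0.5, 6)))
        e0 = gb_energy(top, Frame(xyz), range(6))
        # rotate + translate
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        e1 = gb_energy(top, Frame(xyz @ rot.T + np.array([5.0, -3.0, 2.0])), range(6))
        assert e1 == pytest.approx(e0, abs=1e-9)

    def test_descreening_lowers_self_energy_magnitude_increase(self):
        # a buried charge has a larger effective radius -> weaker solvation
        top = simple_topology([1.0, 0.0], gb_radius=[1.5, 1.8])
        alone = gb_energy(simple_topology([1.0], gb_radius=[1.5]),
                          Frame(np.zeros((1, 3))), [0])
        paired = gb_energy(top, _pair_frame(2.5), [0, 1])
        assert paired > alone  # less negative

    def test_nonpositive_radius_named(self):
        # tiny atom engulfed by six heavy descreeners overshoots the
        # pairwise integral and must fail loudly, naming the atom
        xyz = np.vstack([[0.0, 0.0, 0.0], 2.0 * np.eye(3), -2.0 * np.eye(3)])
        top = simple_topology([0.0] * 7, gb_radius=[0.35] + [2.5] * 6,
                              gb_screen=[0.9] * 7)
        with pytest.raises(BornRadiusError, match="atom 0"):
            effective_born_radii(top, Frame(xyz), range(7))


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

class TestSasa:
    def test_isolated_sphere_closed_form(self):
        top = simple_topology([0.0], rmin_half=[1.7])
        total, per_atom = sasa(top, Frame(np.zeros((1, 3))), [0], probe=1.4)
        assert total == pytest.approx(4 * np.pi * 3.1 ** 2, rel=0.01)
        assert total == pytest.approx(120.76, rel=0.01)
        assert per_atom.sum() == pytest.approx(total)

    def test_fully_enclosed_atom_has_zero_area(self):
        # cage of 26 large spheres around a small central atom
        offsets = [np.array([i, j, k], dtype=float)
                   for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
                   if (i, j, k) != (0, 0, 0)]
        xyz = np.vstack([[0.0, 0.0, 0.0]] + [2.0 * o / np.linalg.norm(o)
                                             for o in offsets])
        n = len(xyz)
        top = simple_topology([0.0] * n, rmin_half=[1.2] + [2.0] * (n - 1))
        _, per_atom = sasa(top, Frame(xyz), range(n))
        assert per_atom[0] == 0.0

    def test_two_spheres_vs_analytic_caps(self):
        r1, r2, probe, d = 1.9, 1.6, 1.4, 2.8
        e1, e2 = r1 + probe, r2 + probe
        top = simple_topology([0.0, 0.0], rmin_half=[r1, r2])
        total, per_atom = sasa(top, _pair_frame(d), [0, 1])
        # analytic buried caps of two intersecting spheres
        h1 = e1 - (d ** 2 + e1 ** 2 - e2 ** 2) / (2 * d)
        h2 = e2 - (d ** 2 + e2 ** 2 - e1 ** 2) / (2 * d)
        want1 = 4 * np.pi * e1 ** 2 - 2 * np.pi * e1 * h1
        want2 = 4 * np.pi * e2 ** 2 - 2 * np.pi * e2 * h2
        assert per_atom[0] == pytest.approx(want1, rel=0.01)
        assert per_atom[1] == pytest.approx(want2, rel=0.01)
        assert total == pytest.approx(want1 + want2, rel=0.01)

    def test_total_area_monotone_on_approach(self):
        top = simple_topology([0.0, 0.0], rmin_half=[1.7, 1.7])
        totals = [sasa(top, _pair_frame(d), [0, 1])[0]
                  for d in (8.0, 6.0, 5.0, 4.0, 3.0, 2.0)]
        assert all(a >= b - 1e-9 for a, b in zip(totals, totals[1:]))


class TestNonpolar:
    @pytest.mark.parametrize("area,gamma,beta,expected", [
        (0.0, 0.00542, 0.92, 0.92),
        (1000.0, 0.00542, 0.92, 6.34),
        (200.0, 0.005, 0.0, 1.0),
    ])
    def test_linear_form(self, area, gamma, beta, expected):
        assert nonpolar_energy(area, gamma, beta) == pytest.approx(expected)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            nonpolar_energy(-1.0)


class TestComponents:
    def test_assembly_identities_enforced(self):
        c = EnergyComponents.assemble(1.0, 2.0, 3.0, 4.0)
        assert c.E_ele == pytest.approx(5.0)
        assert c.E_tot == pytest.approx(10.0)
        assert c.E_tot_np == pytest.approx(6.0)
        with pytest.raises(ValueError):
            EnergyComponents(1, 2, 3, 4, E_ele=99.0, E_tot_np=6.0, E_tot=10.0)

    def test_all_zero(self):
        assert combine_components(0, 0, 0, 0) == (0, 0, 0)


def test_pb_adapter_requires_solver(two_atom_top):
    with pytest.raises(NotImplementedError):
        pb_energy(two_atom_top, _pair_frame(3.0), [0, 1])
    # an injected solver is used verbatim
    assert pb_energy(two_atom_top, _pair_frame(3.0), [0, 1],
                     solver=lambda t, f, g: -12.5) == -12.5
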