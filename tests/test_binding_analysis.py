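"""Interaction-energy assembly: worked published rows, oracles, shells."""

import numpy as np
import pytest

from phosdelta.binding_analysis import (
    delta_delta, ensemble_average, interaction_energy_frame,
    local_interaction_energy, shell_select,
)
from phosdelta.constants import COULOMB_CONSTANT
from phosdelta.mm_energetics import (
    EnergyComponents, combine_components, coulomb_energy, gb_energy,
    lj_energy, nonpolar_energy, sasa,
)
from phosdelta.system_io import Frame, SeedEnsemble, Trajectory
from phosdelta.tables import GLOBAL_ROWS, LOCAL_ROWS

from conftest import simple_topology


class TestCombineComponents:
    @pytest.mark.parametrize("row", GLOBAL_ROWS + LOCAL_ROWS,
                             ids=lambda r: f"{r['domain']}-s{r['site']}")
    def test_published_rows_reassemble(self, row):
        """Printed component columns reproduce the printed derived columns."""
        e_ele, e_tot, e_tot_np = combine_components(
            row["dd_U_vdw"], row["dd_U_coul"], row["dd_W_polar"], row["dd_W_np"])
        printed = row["printed"]
        # E_ele can carry a 0.01 print-rounding offset (one published row);
        # E_tot is consistent with the *printed* E_ele in that case
        assert e_ele == pytest.approx(printed["dd_E_ele"], abs=0.011)
        e_tot_from_printed = (printed["dd_E_ele"] + row["dd_U_vdw"] +
                              row["dd_W_np"])
        assert printed["dd_E_tot"] == pytest.approx(e_tot_from_printed, abs=0.011)
        assert e_tot_np == pytest.approx(e_tot - row["dd_W_np"], abs=1e-12)

    def test_headline_row_exact(self):
        e_ele, e_tot, e_tot_np = combine_components(2.50, -34.34, 37.83, 0.75)
        assert e_ele == pytest.approx(3.49)
        assert e_tot == pytest.approx(6.74)
        assert e_tot_np == pytest.approx(5.99)

    def test_local_headline_row(self):
        e_ele, e_tot, _ = combine_components(3.12, -8.36, 5.71, 0.03)
        assert e_ele == pytest.approx(-2.65)
        assert 0.49 <= round(e_tot, 2) <= 0.50


class TestInteractionEnergyFrame:
    def test_noninteracting_limit(self):
        # two widely separated pairs: all interaction terms ~ 0
        top = simple_topology([0.4, -0.4, 0.3, -0.3],
                              groups={"receptor": {0, 1}, "ligand": {2, 3}})
        xyz = np.array([[0.0, 0, 0], [2.0, 0, 0],
                        [1e5, 0, 0], [1e5 + 2.0, 0, 0]])
        comp = interaction_energy_frame(top, Frame(xyz), [0, 1], [2, 3])
        assert comp.U_vdw == 0.0
        assert comp.U_coul == 0.0
        assert comp.W_polar == pytest.approx(0.0, abs=0.01)

    def test_matches_complex_minus_parts_oracle(self):
        rng = np.random.default_rng(12)
        q = rng.uniform(-0.6, 0.6, 6)
        while True:
            xyz = rng.uniform(-4, 4, (6, 3))
            d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=2)
            if d[np.triu_indices(6, 1)].min() > 2.2:
                break
        top = simple_topology(list(q))
        frame = Frame(xyz)
        rec, lig = [0, 1, 2], [3, 4, 5]
        comp = interaction_energy_frame(top, frame, rec, lig)

        def total_pairs(group):
            e_c = e_l = 0.0
            for ii, i in enumerate(group):
                for j in group[ii + 1:]:
                    r = np.linalg.norm(xyz[i] - xyz[j])
                    e_c += COULOMB_CONSTANT * q[i] * q[j] / r
                    rm = 3.4
                    e_l += 0.1 * ((rm / r) ** 12 - 2 * (rm / r) ** 6)
            return e_c, e_l

        c_all, l_all = total_pairs(rec + lig)
        c_r, l_r = total_pairs(rec)
        c_l, l_l = total_pairs(lig)
        assert comp.U_coul == pytest.approx(c_all - c_r - c_l, abs=1e-8)
        assert comp.U_vdw == pytest.approx(l_all - l_r - l_l, abs=1e-8)
        # solvation terms equal complex-minus-parts of the standalone kernels
        both = rec + lig
        assert comp.W_polar == pytest.approx(
            gb_energy(top, frame, both) - gb_energy(top, frame, rec)
            - gb_energy(top, frame, lig), abs=1e-10)
        w_np = (nonpolar_energy(sasa(top, frame, both)[0])
                - nonpolar_energy(sasa(top, frame, rec)[0])
                - nonpolar_energy(sasa(top, frame, lig)[0]))
        assert comp.W_np == pytest.approx(w_np, abs=1e-10)

    def test_coulomb_bilinearity(self):
        top1 = simple_topology([0.3, -0.2], groups={})
        top2 = simple_topology([0.6, -0.4])
        frame = Frame(np.array([[0.0, 0, 0], [3.0, 0, 0]]))
        c1 = interaction_energy_frame(top1, frame, [0], [1]).U_coul
        c2 = interaction_energy_frame(top2, frame, [0], [1]).U_coul
        assert c2 == pytest.approx(4.0 * c1)

    def test_group_overlap_rejected(self):
        top = simple_topology([0.1, 0.1])
        with pytest.raises(ValueError, match="overlap"):
            interaction_energy_frame(top, Frame(np.array([[0.0, 0, 0], [3.0, 0, 0]])),
                                     [0], [0, 1])


def _two_atom_ensemble(top, distances_per_seed):
    trajs = []
    for s, dists in enumerate(distances_per_seed):
        coords = np.zeros((len(dists), 2, 3))
        coords[:, 1, 0] = dists
        trajs.append(Trajectory(coords, seed_id=s))
    return SeedEnsemble(trajs, list(range(len(trajs))))


class TestEnsembleAverage:
    def test_identical_frames_zero_sem(self):
        top = simple_topology([0.5, -0.5])
        ens = _two_atom_ensemble(top, [[3.0, 3.0, 3.0], [3.0, 3.0]])
        out = ensemble_average(top, ens, [0], [1])
        single = interaction_energy_frame(top, Frame(ens.trajectories[0].coordinates[0]),
                                          [0], [1])
        assert out.mean.E_tot == pytest.approx(single.E_tot, abs=1e-10)
        assert out.sem["E_tot"] == pytest.approx(0.0, abs=1e-12)

    def test_mean_of_two_seed_means(self):
        top = simple_topology([0.5, -0.5])
        ens = _two_atom_ensemble(top, [[3.0], [4.0]])
        out = ensemble_average(top, ens, [0], [1])
        a = interaction_energy_frame(top, Frame(ens.trajectories[0].coordinates[0]), [0], [1])
        b = interaction_energy_frame(top, Frame(ens.trajectories[1].coordinates[0]), [0], [1])
        assert out.mean.U_coul == pytest.approx((a.U_coul + b.U_coul) / 2)

    def test_matches_closed_form_average(self):
        top = simple_topology([0.4, -0.7])
        dists = [2.5, 3.0, 3.5, 4.0]
        ens = _two_atom_ensemble(top, [dists])
        out = ensemble_average(top, ens, [0], [1])
        expected = np.mean([COULOMB_CONSTANT * 0.4 * -0.7 / r for r in dists])
        assert out.mean.U_coul == pytest.approx(expected, abs=1e-8)

    def test_stride(self):
        top = simple_topology([0.4, -0.7])
        ens = _two_atom_ensemble(top, [[2.0, 99.0, 2.0, 99.0]])
        out = ensemble_average(top, ens, [0], [1], stride=2)
        expected = COULOMB_CONSTANT * 0.4 * -0.7 / 2.0
        assert out.mean.U_coul == pytest.approx(expected)

    def test_empty_trajectory_rejected(self):
        top = simple_topology([0.5, -0.5])
        ens = SeedEnsemble([Trajectory(np.zeros((0, 2, 3)))], [0])
        with pytest.raises(ValueError, match="empty"):
            ensemble_average(top, ens, [0], [1])


class TestDeltaDelta:
    def _comp(self, *vals, **kw):
        return EnergyComponents.assemble(*vals, **kw)

    def test_identical_gives_zero_record(self):
        w = self._comp(1.0, -2.0, 3.0, 0.5)
        rec = delta_delta(w, w, "sys", 1, "pT->pS")
        assert rec.dd_E_tot == 0.0 and rec.dd_U_vdw == 0.0

    def test_antisymmetry(self):
        w = self._comp(1.0, -2.0, 3.0, 0.5)
        m = self._comp(2.0, -1.0, 2.5, 0.7)
        fwd = delta_delta(w, m, "sys", 1, "pT->pS")
        rev = delta_delta(m, w, "sys", 1, "pT->pS")
        for f in ("dd_U_vdw", "dd_U_coul", "dd_W_polar", "dd_E_ele",
                  "dd_E_tot_np", "dd_W_np", "dd_E_tot"):
            assert getattr(fwd, f) == pytest.approx(-getattr(rev, f))

    def test_linearity_with_combine_components(self):
        w = self._comp(1.0, -2.0, 3.0, 0.5)
        m = self._comp(2.5, -1.0, 2.0, 0.9)
        rec = delta_delta(w, m, "sys", 1, "pT->pS")
        e_ele, e_tot, e_tot_np = combine_components(
            rec.dd_U_vdw, rec.dd_U_coul, rec.dd_W_polar, rec.dd_W_np)
        assert rec.dd_E_ele == pytest.approx(e_ele)
        assert rec.dd_E_tot == pytest.approx(e_tot)
        assert rec.dd_E_tot_np == pytest.approx(e_tot_np)

    def test_polar_model_mismatch_rejected(self):
        w = self._comp(1.0, -2.0, 3.0, 0.5, polar_model="GB")
        m = self._comp(1.0, -2.0, 3.0, 0.5, polar_model="PB")
        with pytest.raises(ValueError, match="polar"):
            delta_delta(w, m, "sys", 1, "pT->pS")


class TestShellSelect:
    def _shell_fixture(self):
        # ligand: phospho-like residue with one P atom at origin;
        # receptor: residue A at 4 Å, residue B at 8 Å
        top = simple_topology([0.0, 0.0, 0.0], names=["P", "XA", "XB"],
                              groups={"receptor": {1, 2}, "ligand": {0}})
        xyz = np.array([[0.0, 0, 0], [4.0, 0, 0], [8.0, 0, 0]])
        return top, Frame(xyz)

    def test_constructed_geometry(self):
        top, frame = self._shell_fixture()
        sel = shell_select(top, frame, 0, cutoff=6.0)
        assert sel.residue_indices == [1]

    def test_monotone_in_cutoff(self, toy_complex):
        top, frame = toy_complex
        pp = next(ri for ri, r in enumerate(top.residues) if r.name == "TPO")
        s5 = set(shell_select(top, frame, pp, cutoff=5.0).residue_indices)
        s7 = set(shell_select(top, frame, pp, cutoff=7.0).residue_indices)
        assert s5 <= s7

    def test_large_cutoff_selects_whole_domain(self, toy_complex):
        top, frame = toy_complex
        pp = next(ri for ri, r in enumerate(top.residues) if r.name == "TPO")
        sel = shell_select(top, frame, pp, cutoff=1e4)
        domain_res = {top.atoms[i].residue_index
                      for i in top.groups["receptor"]}
        assert set(sel.residue_indices) == domain_res

    def test_missing_phosphate_atoms_named(self):
        top = simple_topology([0.0, 0.0], names=["XX", "YY"],
                              groups={"receptor": {1}, "ligand": {0}})
        with pytest.raises(ValueError, match="residue 0"):
            shell_select(top, Frame(np.zeros((2, 3))), 0)


class TestLocalEnergy:
    def test_whole_shell_equals_global_gb(self, small_benchmark):
        b = small_benchmark
        top = b.topology_wild
        short = SeedEnsemble([Trajectory(b.wild.trajectories[0].coordinates[:2])],
                             [0])
        sel = shell_select(top, b.frame_wild, b.phospho_residue, cutoff=1e4)
        local = local_interaction_energy(top, short, sel, b.phospho_residue,
                                         neighbor_residues=10 ** 6)
        rec = sorted(top.groups["receptor"])
        lig = sorted(top.groups["ligand"])
        glob = ensemble_average(top, short, rec, lig, polar_model="GB")
        for f in ("U_vdw", "U_coul", "W_polar", "W_np", "E_tot"):
            assert getattr(local.mean, f) == pytest.approx(
                getattr(glob.mean, f), abs=1e-6)

    def test_empty_shell_rejected(self, small_benchmark):
        b = small_benchmark
        from phosdelta.binding_analysis import ShellSelection
        empty = ShellSelection(6.0, frozenset({"P"}), ())
        with pytest.raises(ValueError, match="empty"):
            local_interaction_energy(b.topology_wild, b.wild, empty,
                                     b.phospho_residue)

    def test_restricted_sums_match_brute_force(self, toy_complex):
        top, frame = toy_complex
        pp = next(ri for ri, r in enumerate(top.residues) if r.name == "TPO")
        sel = shell_select(top, frame, pp, cutoff=6.0)
        assert sel.selected_residues  # the pocket was built around the site
        ens = SeedEnsemble([Trajectory(frame.coordinates[None])], [0])
        out = local_interaction_energy(top, ens, sel, pp, neighbor_residues=1)
        rec_atoms = [i for ri in sel.residue_indices
                     for i in top.residue_atoms(ri)]
        lig_atoms = [i for ri in (pp - 1, pp, pp + 1)
                     for i in top.residue_atoms(ri)
                     if i in top.groups["ligand"]]
        assert out.mean.U_coul == pytest.approx(
            coulomb_energy(top, frame, rec_atoms, lig_atoms), abs=1e-8)
        assert out.mean.U_vdw == pytest.approx(
            lj_energy(top, frame, rec_atoms, lig_atoms), abs=1e-8)
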