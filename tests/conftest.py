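"""Shared fixtures: hand-built topologies and a small benchmark bundle."""

from __future__ import annotations

import numpy as np
import pytest

from phosdelta.system_io import AtomRecord, Frame, Residue, Topology


def simple_topology(charges, rmin_half=None, epsilon=None, gb_radius=None,
                    gb_screen=None, names=None, groups=None):
    """One-residue-per-atom topology for kernel tests."""
    n = len(charges)
    rmin_half = rmin_half or [1.7] * n
    epsilon = epsilon or [0.1] * n
    gb_radius = gb_radius or [1.5] * n
    gb_screen = gb_screen or [0.8] * n
    names = names or [f"X{i}" for i in range(n)]
    atoms = [AtomRecord(i, names[i], i, "RES", charges[i], rmin_half[i],
                        epsilon[i], gb_radius[i], gb_screen[i], 12.0)
             for i in range(n)]
    residues = [Residue("RES", i, i + 1) for i in range(n)]
    return Topology(atoms, residues, [], groups or {})


@pytest.fixture
def two_atom_top():
    return simple_topology([1.0, 1.0])


@pytest.fixture(scope="session")
def toy_complex():
    from phosdelta.synthetic_data import ToySpec, make_toy_complex
    return make_toy_complex(ToySpec(seed=11))


@pytest.fixture(scope="session")
def small_benchmark():
    """Enclosed-cavity methyl-deletion bundle at reduced size."""
    from phosdelta.synthetic_data import ToySpec, methyl_deletion_benchmark
    return methyl_deletion_benchmark(ToySpec(seed=5), seed=5,
                                     n_seeds=3, n_frames=60)


# ---------------------------------------------------------------------------
# a 5-atom prmtop written and decoded by hand
# ---------------------------------------------------------------------------

def _lj_ab(eps, rmin):
    return eps * rmin ** 12, 2.0 * eps * rmin ** 6


def prmtop_text(include_radii=True, natom_names=5):
    a11, b11 = _lj_ab(0.1, 3.8)  # type 1: rmin/2 = 1.9, eps = 0.1
    names = ["N1", "C2", "O3", "H4", "P5"][:natom_names]
    name_field = "".join(f"{n:<4s}" for n in names)
    lines = [
        "%VERSION  VERSION_STAMP = V0001.000",
        "%FLAG POINTERS", "%FORMAT(10I8)",
        "       5       2       0       0       0       0       0       0       0       0",
        "       0       2       0       0       0       0       0       0       0       0",
        "       0       0       0       0       0       0       0       0       0       0",
        "       0",
        "%FLAG ATOM_NAME", "%FORMAT(20a4)",
        name_field,
        "%FLAG CHARGE", "%FORMAT(5E16.8)",
        "  1.82223000E+01 -1.82223000E+01  9.11115000E+00  0.00000000E+00 -9.11115000E+00",
        "%FLAG MASS", "%FORMAT(5E16.8)",
        "  1.40100000E+01  1.20100000E+01  1.60000000E+01  1.00800000E+00  3.09700000E+01",
        "%FLAG ATOM_TYPE_INDEX", "%FORMAT(10I8)",
        "       1       1       2       2       1",
        "%FLAG NONBONDED_PARM_INDEX", "%FORMAT(10I8)",
        "       1       2       2       3",
        "%FLAG LENNARD_JONES_ACOEF", "%FORMAT(5E16.8)",
        f"  {a11:.8E}  0.00000000E+00  0.00000000E+00",
        "%FLAG LENNARD_JONES_BCOEF", "%FORMAT(5E16.8)",
        f"  {b11:.8E}  0.00000000E+00  0.00000000E+00",
        "%FLAG RESIDUE_LABEL", "%FORMAT(20a4)",
        "ALA GLU ",
        "%FLAG RESIDUE_POINTER", "%FORMAT(10I8)",
        "       1       4",
        "%FLAG BONDS_INC_HYDROGEN", "%FORMAT(10I8)",
        "       6       9       1",
        "%FLAG BONDS_WITHOUT_HYDROGEN", "%FORMAT(10I8)",
        "       0       3       1",
    ]
    if include_radii:
        lines += [
            "%FLAG RADII", "%FORMAT(5E16.8)",
            "  1.55000000E+00  1.70000000E+00  1.50000000E+00  1.20000000E+00  1.85000000E+00",
            "%FLAG SCREEN", "%FORMAT(5E16.8)",
            "  7.90000000E-01  7.20000000E-01  8.50000000E-01  8.50000000E-01  8.60000000E-01",
        ]
    return "\n".join(lines) + "\n"


#: manual decode of the fixture above, used to check the reader
PRMTOP_EXPECTED = {
    "names": ["N1", "C2", "O3", "H4", "P5"],
    "charges": [1.0, -1.0, 0.5, 0.0, -0.5],
    "masses": [14.01, 12.01, 16.0, 1.008, 30.97],
    "rmin_half": [1.9, 1.9, 0.0, 0.0, 1.9],
    "epsilon": [0.1, 0.1, 0.0, 0.0, 0.1],
    "radii": [1.55, 1.7, 1.5, 1.2, 1.85],
    "residues": [("ALA", 0, 3), ("GLU", 3, 5)],
    "bonds": {(2, 3), (0, 1)},
}


@pytest.fixture
def prmtop_file(tmp_path):
    p = tmp_path / "toy.prmtop"
    p.write_text(prmtop_text())
    return p
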