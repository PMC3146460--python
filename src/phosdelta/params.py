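"""Self-contained phospho-residue parameter blocks.

A small parameter table (charges in e, LJ rmin/2 in Å and ε in kcal/mol,
GB intrinsic radius in Å, screen, mass in amu) for the simplified
phospho-threonine/serine residue templates used by the mutator and the
synthetic complexes. These are plausible fixed-charge values chosen so the
phosphate carries a net -2 e dianionic charge and the methyl group is
electrically neutral; they are a shipped fixture, not a derived force
field.
"""

from __future__ import annotations

#: name -> (charge, rmin_half, epsilon, gb_radius, gb_screen, mass)
PTHR_PARAMS: dict[str, tuple[float, float, float, float, float, float]] = {
    "N":    (-0.40, 1.824, 0.170, 1.55, 0.79, 14.01),
    "CA":   (0.05, 1.908, 0.109, 1.70, 0.72, 12.01),
    "C":    (0.55, 1.908, 0.086, 1.70, 0.72, 12.01),
    "O":    (-0.55, 1.661, 0.210, 1.50, 0.85, 16.00),
    "CB":   (0.20, 1.908, 0.109, 1.70, 0.72, 12.01),
    "HB":   (0.05, 1.387, 0.016, 1.20, 0.85, 1.008),
    "OG1":  (-0.50, 1.683, 0.170, 1.50, 0.85, 16.00),
    "CG2":  (0.00, 1.908, 0.109, 1.70, 0.72, 12.01),
    "HG21": (0.00, 1.487, 0.016, 1.20, 0.85, 1.008),
    "HG22": (0.00, 1.487, 0.016, 1.20, 0.85, 1.008),
    "HG23": (0.00, 1.487, 0.016, 1.20, 0.85, 1.008),
    "P":    (1.30, 2.100, 0.200, 1.85, 0.86, 30.97),
    "O1P":  (-0.90, 1.661, 0.210, 1.50, 0.85, 16.00),
    "O2P":  (-0.90, 1.661, 0.210, 1.50, 0.85, 16.00),
    "O3P":  (-0.90, 1.661, 0.210, 1.50, 0.85, 16.00),
}

#: The serine analog: the methyl atoms are absent, everything else shared.
PSER_PARAMS: dict[str, tuple[float, float, float, float, float, float]] = {
    k: v for k, v in PTHR_PARAMS.items()
    if k not in ("CG2", "HG21", "HG22", "HG23")
}

#: Generic backbone parameters for the glycine-like filler residues.
GLY_PARAMS: dict[str, tuple[float, float, float, float, float, float]] = {
    "N":  (-0.40, 1.824, 0.170, 1.55, 0.79, 14.01),
    "CA": (0.05, 1.908, 0.109, 1.70, 0.72, 12.01),
    "C":  (0.55, 1.908, 0.086, 1.70, 0.72, 12.01),
    "O":  (-0.20, 1.661, 0.210, 1.50, 0.85, 16.00),
}

#: Atom ordering of the shipped residue templates (single united CB
#: hydrogen in both, so the mutation changes exactly the 4 methyl atoms).
PTHR_ATOM_ORDER = ["N", "CA", "C", "O", "CB", "HB", "OG1",
                   "CG2", "HG21", "HG22", "HG23", "P", "O1P", "O2P", "O3P"]
PSER_ATOM_ORDER = [n for n in PTHR_ATOM_ORDER
                   if n not in ("CG2", "HG21", "HG22", "HG23")]
GLY_ATOM_ORDER = ["N", "CA", "C", "O"]

#: Methyl atoms added/removed by the pThr<->pSer mutation.
METHYL_ATOMS = ("CG2", "HG21", "HG22", "HG23")

#: Intra-residue bonds of the phospho templates, by atom name.
PTHR_BONDS = [("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB"),
              ("CB", "HB"), ("CB", "OG1"), ("CB", "CG2"),
              ("CG2", "HG21"), ("CG2", "HG22"), ("CG2", "HG23"),
              ("OG1", "P"), ("P", "O1P"), ("P", "O2P"), ("P", "O3P")]
PSER_BONDS = [b for b in PTHR_BONDS if "CG2" not in b]
GLY_BONDS = [("N", "CA"), ("CA", "C"), ("C", "O")]

#: Ideal bond lengths (Å) used for template validation and methyl building.
TEMPLATE_BOND_LENGTHS = {
    frozenset(("N", "CA")): 1.458,
    frozenset(("CA", "C")): 1.525,
    frozenset(("C", "O")): 1.231,
    frozenset(("CA", "CB")): 1.530,
    frozenset(("CB", "HB")): 1.090,
    frozenset(("CB", "OG1")): 1.420,
    frozenset(("CB", "CG2")): 1.525,
    frozenset(("CG2", "HG21")): 1.090,
    frozenset(("CG2", "HG22")): 1.090,
    frozenset(("CG2", "HG23")): 1.090,
    frozenset(("OG1", "P")): 1.610,
    frozenset(("P", "O1P")): 1.480,
    frozenset(("P", "O2P")): 1.480,
    frozenset(("P", "O3P")): 1.480,
}

#: Default residue-name map for the mutation (PDB-style phospho names).
DEFAULT_NAMING = {"TPO": "SEP", "SEP": "TPO"}
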