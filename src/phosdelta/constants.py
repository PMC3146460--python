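"""Physical constants and unit conventions.

Units throughout the package: Å, kcal/mol, elementary charge (e),
degrees for angles, amu for masses, 0-based indices internally.
"""

#: Coulomb constant, kcal·Å/(mol·e²).
COULOMB_CONSTANT = 332.0636

#: AMBER prmtop stores charges multiplied by this factor (sqrt of the
#: Coulomb constant as used by sander); divide to recover units of e.
PRMTOP_CHARGE_SCALE = 18.2223

#: Gas constant, kcal/(mol·K).
GAS_CONSTANT = 1.9872e-3

#: Default dielectric constants for the generalized-Born model
#: (protein interior / aqueous exterior).
GB_INTERIOR_DIELECTRIC = 1.0
GB_EXTERIOR_DIELECTRIC = 80.0

#: Default non-bonded cutoff for Coulomb/Lennard-Jones sums, Å.
DEFAULT_NONBONDED_CUTOFF = 40.0

#: Water probe radius for solvent-accessible surface area, Å.
DEFAULT_SASA_PROBE = 1.4

#: Default number of sphere test points for the Shrake–Rupley estimate.
DEFAULT_SASA_POINTS = 960

#: SASA→energy coefficients, kcal/(mol·Å²) and kcal/mol.
#: The "pb" preset is the Amber PBSA convention, "gb" the GBSA one.
NONPOLAR_PRESETS = {
    "pb": (0.00542, 0.92),
    "gb": (0.005, 0.0),
}

#: Intrinsic GB radii (Å) by leading element letter, used when a topology
#: carries no explicit radii section (mbondi-style table).
DEFAULT_GB_RADII = {
    "H": 1.2,
    "C": 1.7,
    "N": 1.55,
    "O": 1.5,
    "S": 1.8,
    "P": 1.85,
    "F": 1.5,
}
DEFAULT_GB_RADIUS_FALLBACK = 1.5

#: GB descreening (screening) parameters by leading element letter.
DEFAULT_GB_SCREEN = {
    "H": 0.85,
    "C": 0.72,
    "N": 0.79,
    "O": 0.85,
    "S": 0.96,
    "P": 0.86,
}
DEFAULT_GB_SCREEN_FALLBACK = 0.8

#: Residue names stripped on topology load (implicit-solvent post-processing).
SOLVENT_RESIDUE_NAMES = frozenset({"WAT", "HOH", "Na+", "Cl-", "NA+", "CL-", "NA", "CL"})
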