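"""Physical constants and unit conversions used throughout the package.

Canonical internal units: orbital energies in eV, total electronic energies
in hartree, derived energetics (cohesive/adsorption) in kJ/mol, dipoles in
Debye, QTAIM/NBO quantities in atomic units, geometry in Angstrom.

All conversion factors are CODATA-2018 values kept to >= 10 significant
digits so that round-trips through any unit dialect agree to well below
parsing precision.
"""

# energy
HARTREE_TO_EV = 27.211386245988
HARTREE_TO_KJ_MOL = 2625.4996394799
HARTREE_TO_KCAL_MOL = 627.5094740631
EV_TO_KJ_MOL = HARTREE_TO_KJ_MOL / HARTREE_TO_EV

# thermodynamics
BOLTZMANN_EV_PER_K = 8.617333262e-5       # eV/K
GAS_CONSTANT_J_MOL_K = 8.314462618        # J/(mol K)

# length
BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

# sensor-model defaults
DEFAULT_TEMPERATURE_K = 298.0
DEFAULT_ATTEMPT_FREQUENCY_HZ = 1.0e12     # typical surface attempt frequency
DEFAULT_RICHARDSON_A = 6.0e5              # A m^-2, Richardson-type prefactor

SUPPORTED_ELEMENTS = ("H", "B", "C", "N", "O", "Si")

# loose whitelist for geometry validation; covers main-group elements that
# plausibly appear in XYZ files fed to the geometry helpers
KNOWN_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Ga Ge As Se Br Kr".split()
)
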