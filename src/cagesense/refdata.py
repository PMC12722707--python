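"""Published reference values for the doped-C60 acetone-sensing systems.

These fixtures transcribe the printed result tables of the source
DFT/QTAIM study of acetone adsorption on pristine and B/N/Si-doped C60:
frontier orbital energies with their derived descriptors, sensor metrics
(adsorption energy, recovery time, conductivity), QTAIM bond-critical-
point properties, NBO second-order perturbation rows, and the dipole
moments before/after acetone binding. The raw wavefunctions and
geometries were never deposited, so the printed tables are the only
machine-readable ground truth; the reproduction pipeline
(:mod:`cagesense.reporting`) re-derives every derivable column from the
primary ones.

All energies in eV unless noted; sigma in A m^-2; tau in s; Eads in
kJ/mol; QTAIM quantities in a.u.; dipoles in Debye.
"""

from __future__ import annotations

from types import MappingProxyType

CAGES = ("C60", "BC59", "NC59", "SiC59")
COMPLEXES = ("C60@Acetone", "BC59@Acetone", "NC59@Acetone", "SiC59@Acetone")
SPECIES = CAGES + COMPLEXES

#: complex label -> bare-cage label (the alpha species in the ECT convention)
CAGE_OF = MappingProxyType({
    "C60@Acetone": "C60",
    "BC59@Acetone": "BC59",
    "NC59@Acetone": "NC59",
    "SiC59@Acetone": "SiC59",
})

#: label -> (E_HOMO, E_LUMO) in eV — the primary (non-derived) columns
FRONTIER = MappingProxyType({
    "C60": (-5.38, -3.70),
    "BC59": (-4.93, -3.58),
    "NC59": (-5.20, -3.79),
    "SiC59": (-5.12, -3.94),
    "C60@Acetone": (-4.43, -3.78),
    "BC59@Acetone": (-4.93, -3.95),
    "NC59@Acetone": (-4.86, -3.20),
    "SiC59@Acetone": (-4.34, -3.60),
})

#: label -> printed derived descriptor columns
#: (hlg eV, eta eV, mu eV, s eV^-1, dn_max, ect-or-None)
DESCRIPTORS = MappingProxyType({
    "C60": (1.68, 0.84, -4.54, 0.59, 5.40, None),
    "BC59": (1.35, 0.67, -4.25, 0.74, 6.30, None),
    "NC59": (1.41, 0.70, -4.49, 0.70, 6.37, None),
    "SiC59": (1.18, 0.59, -4.53, 0.84, 7.67, None),
    "C60@Acetone": (0.65, 0.325, -4.10, 1.53, 12.63, -7.22),
    "BC59@Acetone": (0.98, 0.49, -4.44, 1.02, 9.06, -2.75),
    "NC59@Acetone": (1.66, 0.83, -4.03, 0.60, 4.85, 1.52),
    "SiC59@Acetone": (0.74, 0.37, -3.97, 1.35, 10.72, -3.05),
})

#: label -> (Eads kJ/mol or None, tau s or None, sigma A m^-2)
SENSOR = MappingProxyType({
    "C60": (None, None, 2.19e9),
    "BC59": (None, None, 2.35e9),
    "NC59": (None, None, 2.32e9),
    "SiC59": (None, None, 2.43e9),
    "C60@Acetone": (-35.81, 3.92e-11, 2.70e9),
    "BC59@Acetone": (-109.28, 1.19e-10, 2.53e9),
    "NC59@Acetone": (-39.67, 4.35e-11, 2.20e9),
    "SiC59@Acetone": (-137.17, 1.50e-10, 2.65e9),
})

#: label -> (rho, G, V, laplacian, Hb) at the sensor-acetone BCP, a.u.
QTAIM = MappingProxyType({
    "C60@Acetone": (0.0071, 0.0047, -0.0014, -0.0062, 0.0033),
    "BC59@Acetone": (0.099, 0.158, 0.054, -0.103, 0.212),
    "NC59@Acetone": (0.006, 0.0048, -0.0014, -0.006, 0.0034),
    "SiC59@Acetone": (0.083, 0.125, 0.018, -0.107, 0.143),
})

#: NBO rows: (complex, donor, donor_type, acceptor, acceptor_type,
#:            E2 as printed, dE a.u., F a.u.)
#: The printed table header labels E2 "kJ mol-1"; recomputation of the
#: sigma/pi rows via q F^2/dE matches the printed magnitudes only on a
#: kcal/mol scale, so the tag is carried as data, not trusted.
NBO_ROWS = (
    ("C60@Acetone", "C1-C2", "σ", "C1-C6", "σ*", 2.61, 1.09, 0.048),
    ("C60@Acetone", "C1-C6", "π", "C7-C19", "π*", 12.73, 0.25, 0.051),
    ("C60@Acetone", "O61", "LP", "C60-C62", "π*", 1.79, 0.94, 0.037),
    ("BC59@Acetone", "C1-C2", "σ", "C2-C3", "σ*", 1.28, 1.08, 0.047),
    ("BC59@Acetone", "C1-C6", "π", "C2-C3", "π*", 6.26, 0.25, 0.050),
    ("BC59@Acetone", "C35", "LP", "C34-C47", "π*", 29.40, 0.13, 0.088),
    ("NC59@Acetone", "C1-C2", "σ", "C2-C3", "σ*", 1.12, 1.08, 0.044),
    ("NC59@Acetone", "C8-C20", "π", "C55-C56", "π*", 6.29, 0.26, 0.051),
    ("NC59@Acetone", "C47", "LP", "C34-C35", "π*", 39.04, 0.11, 0.093),
    ("SiC59@Acetone", "C1-C2", "σ", "C6-C17", "σ*", 3.04, 1.02, 0.050),
    ("SiC59@Acetone", "C2-C3", "π", "C4-C5", "π*", 12.59, 0.26, 0.051),
    ("SiC59@Acetone", "O61", "LP", "C36-C37", "π*", 0.07, 0.52, 0.006),
)

#: cage -> (dipole magnitude bare, dipole magnitude with acetone), Debye
DIPOLES = MappingProxyType({
    "C60": (0.00, 17.44),
    "BC59": (1.50, 13.45),
    "NC59": (1.39, 8.58),
    "SiC59": (0.35, 19.55),
})

#: cage -> cohesive energy, kJ/mol per atom (published sign convention)
COHESIVE = MappingProxyType({
    "C60": -197.0,
    "NC59": -196.0,
    "BC59": -195.0,
    "SiC59": -195.0,
})
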