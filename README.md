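# cagesense

Post-quantum-chemistry analysis for doped-fullerene gas sensors.

Acetone in exhaled breath is a biomarker for heart failure, and a water
pollutant; C60 fullerene cages with a single B, N or Si substitution
(BC59, NC59, SiC59) are candidate materials for sensing and adsorbing it.
Screening such sensors computationally produces a small set of numbers per
candidate — frontier orbital energies, total energies, dipole vectors,
bond-critical-point and NBO tables — from which everything that matters
for sensor design is *derived*. `cagesense` is that derivation layer, for
people who run (or read) the DFT but want the analysis to be reproducible,
unit-safe and testable:

* **Conceptual-DFT descriptors** — HOMO–LUMO gap, chemical hardness
  η = (E_L − E_H)/2, chemical potential μ = (E_H + E_L)/2, softness
  S = 1/(2η), maximum charge transfer ΔN_max = −μ/η, and the
  charge-transfer direction descriptor ECT = ΔN_max(α) − ΔN_max(β);
  Gaussian-broadened DOS curves.
* **Sensor energetics** — cohesive energy, counterpoise-corrected
  adsorption energy E_ads = E_complex − (E_host + E_guest) + E_BSSE,
  Arrhenius recovery time τ = v₀⁻¹ exp(−E_ads/RT), Richardson-type
  conductivity σ = A T³ᐟ² exp(−HLG/2kT) (two documented unit conventions),
  dipole magnitudes and binding-response deltas.
* **QTAIM / NBO** — total energy density H_b = G + V, Rozas-style bond
  classification from (sign ∇²ρ, sign H_b), ranking by BCP density, and
  second-order NBO stabilization E(2) = q F²/ΔE.
* **Promolecular NCI** — analytic density/gradient/Hessian on a grid from
  tabulated atomic exponential fits, reduced density gradient
  RDG = |∇ρ|/(2(3π²)^{1/3}ρ^{4/3}) and sign(λ₂)ρ scatter data, cube
  output.
* **Synthetic data + reproduction pipeline** — a seeded generator for
  every input format, and reports that re-derive the published descriptor,
  conductivity and QTAIM tables for the four cage–acetone systems from
  their primary printed columns.

See `docs/methods.md` for the model conventions (including the two places
where printed formulas and printed tables disagree, and which side this
package follows) and `docs/formats.md` for the file formats.

## Worked example

```python
from cagesense import (descriptor_set, frontier, parse_species_log,
                       SensorConventions, conductivity, recovery_time)
from cagesense.synthetic import GeneratorSpec, make_species

# a species with the pristine-C60 frontier pair, rendered to the log dialect
_, log_text = make_species(GeneratorSpec(seed=1, label="C60",
                                         target_homo=-5.38, target_lumo=-3.70))
record = parse_species_log(log_text)
d = descriptor_set(*frontier(record))
print(f"HLG = {d.hlg:.2f} eV, eta = {d.eta:.2f} eV, "
      f"S = {d.s:.2f} 1/eV, dNmax = {d.dn_max:.2f}")

published = SensorConventions(sigma_mode="published")
print(f"sigma = {conductivity(d.hlg, published):.3e} A/m^2")
print(f"tau(Eads=-35.81 kJ/mol) = {recovery_time(-35.81):.3e} s")
```

prints

```
HLG = 1.68 eV, eta = 0.84 eV, S = 0.60 1/eV, dNmax = 5.40
sigma = 2.199e+09 A/m^2
tau(Eads=-35.81 kJ/mol) = 1.891e-06 s
```

i.e. the pristine cage's 1.68 eV gap, its derived hardness/softness/charge
capacity, the conductivity that gap implies in the published unit
convention (printed as 2.19 × 10⁹ A m⁻²), and the microsecond-scale
desorption time of the weakest-bound complex.

The same stages are exposed as a CLI:

```
cagesense synth fixtures --seed 1
cagesense descriptors fixtures/*.log
cagesense qtaim fixtures/bcp.csv
cagesense reproduce --table 2
cagesense reproduce --table 3 --sigma-mode published
cagesense reproduce --table 5
```

`reproduce` exits non-zero if any re-derived cell misses its
print-precision tolerance.

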