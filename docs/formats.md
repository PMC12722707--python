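# File formats

## Species log dialect

`cagesense` reads one deliberately constrained, fully specified log format
instead of the heterogeneous outputs of production quantum-chemistry codes.
A log is UTF-8 text made of named blocks; `#` starts a comment; blank lines
are ignored; the Unicode minus (U+2212) is normalized to the ASCII hyphen.

```
[species]
label = C60

[energy]
unit = hartree          # hartree | eV | kJ/mol
-2285.123456789

[orbitals]
unit = eV               # eV | hartree | kJ/mol
-5.38 2                 # one "energy occupancy" pair per line
-3.70 0

[dipole]
unit = debye
0.0 0.0 0.0

[bsse]                  # optional counterpoise correction
unit = kJ/mol
5.0
```

Rules:

* exactly one `[species]`, `[energy]`, `[orbitals]` and `[dipole]` block;
  `[bsse]` optional. A missing block raises a parse error naming the block.
* occupancies are 0, 1 or 2; levels are sorted ascending by energy on
  parse. An occupied level lying above a virtual one is legal but flags the
  record with `non-monotone-occupancy` and emits a warning.
* all energies are converted to the canonical units on parse (orbitals to
  eV, total energy to hartree); the same physical spectrum expressed in any
  input unit parses to identical eV values to better than 1e-6.
* `render_species_log` / `parse_species_log` round-trip every field to
  1e-9.

## BCP tables (CSV)

Comma-separated, dot decimal, UTF-8, header row required:

```
pair_label,rho,g,v,lap
BC59@Acetone,0.099,0.158,0.054,-0.103
```

All values in atomic units. Rows with `rho <= 0` are rejected with a
diagnostic warning; the rest of the table still parses.

## NBO tables (plain text)

A header line followed by one whitespace-separated row per interaction:

```
donor type acceptor type E2[kJ/mol] dE(a.u.) F(a.u.)
C1-C2 σ C1-C6 σ* 2.61 1.09 0.048
```

* donor types: `σ`/`sigma`, `π`/`pi`, `LP` (also `LP(1)`, `LP(2)`);
  acceptor types: `σ*`/`sigma*`, `π*`/`pi*`. Unknown tokens raise an error
  naming the token.
* the bracketed tag in the `E2[...]` header token is carried verbatim as
  the unit of the printed E(2) column — it is data, not trusted metadata.
* an optional eighth column gives the donor occupancy q (default 2).
* rows with a non-positive energy denominator are rejected with a warning.

## Other formats

* Geometries: standard XYZ (count, comment, `El x y z` in Angstrom).
* NCI volumetric output: Gaussian cube (lengths in bohr, values in a.u.).
* NCI scatter and all report tables: two-or-more-column CSV.
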