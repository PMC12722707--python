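# Methods

`cagesense` implements the post-quantum-chemistry analysis layer for a
family of doped-fullerene gas sensors: pristine C60 and its B-, N- and
Si-substituted cages (BC59, NC59, SiC59) interacting with acetone, a
breath biomarker for heart failure and an environmental pollutant. The
package does not run DFT. It consumes small text representations of what a
DFT run produces — orbital spectra, total energies, dipole vectors,
tabulated bond-critical-point and NBO data — and computes every derived
quantity the sensing analysis needs.

## Conceptual-DFT descriptors

From the frontier orbital energies (eV), identified by occupancy (HOMO =
highest level with occupancy > 0, LUMO = lowest with occupancy 0):

* gap `HLG = |E_HOMO - E_LUMO|`
* chemical hardness `eta = (E_LUMO - E_HOMO)/2`
* chemical potential `mu = (E_HOMO + E_LUMO)/2`
* chemical softness `S = 1/(2 eta)`
* maximum charge transfer `dNmax = -mu/eta`
* charge-transfer direction `ECT = dNmax(alpha) - dNmax(beta)`

Two conventions required a decision:

* **Softness.** The literature this package reproduces typesets softness
  as `eta/2`, yet every tabulated S value it prints is `1/(2 eta)`
  (hardness 0.84 eV alongside softness 0.59 eV^-1, etc.). The tabulated
  convention — the reciprocal, which is also the standard definition — is
  implemented.
* **ECT species order.** The published convention nominally puts acetone
  as the beta species, but all four printed ECT values equal
  dNmax(bare cage) - dNmax(cage@acetone). `ect()` is therefore generic
  over two dNmax values and the reproduction pipeline feeds
  (cage, complex), which matches print for all four complexes within 0.02
  (two cells reflect rounding of intermediates to two decimals).

Report tables round half-to-even at two decimals; reproduction tolerances
are print-precision driven: ±0.01 for HLG/eta/mu/S/dNmax, ±0.02 for ECT.

## Density of states

`dos_curve` broadens each level with a unit-area Gaussian (default width
0.25 eV, a typical choice for rendering molecular DOS; the source tables
state none) on a grid spanning the spectrum ±5 widths. The integral over
the grid equals the level count to within 1% at the default 0.01 eV step.

## Adsorption energetics and sensor metrics

* **Adsorption energy.** `Eads = E_complex - (E_host + E_guest) + E_BSSE`,
  totals in hartree, result in kJ/mol (1 hartree = 2625.4996394799
  kJ/mol), counterpoise correction already in kJ/mol and required
  non-negative. Negative Eads = favourable binding.
* **Cohesive energy.** The literal per-atom expression
  `-(E_complex - sum E_i)/n` is positive for a bound cage; stability
  figures in the sensing literature print the more-negative-is-more-stable
  convention. Default mode `published` returns `-|literal|`; mode
  `physical` returns the literal value.
* **Recovery time.** `tau = v0^-1 exp(-Eads/(R T))` with Eads in J/mol,
  default attempt frequency v0 = 1e12 s^-1 and T = 298 K. `tau(0) = 1/v0`
  exactly; tau grows with binding strength and shrinks with temperature.
  Exponents above 700 return `inf` with a warning rather than overflowing.
  The published recovery-time column for these complexes is *not*
  reproducible from this expression under any unit convention — the
  printed values scale linearly with |Eads| (slope ≈ 1.1e-12 s·mol/kJ)
  rather than exponentially — so the reproduction report marks that column
  non-reproducible and the package's own acceptance for tau is
  property-based (exact zero-limit, monotonicities, and an independent
  arithmetic oracle at Eads = -35.81 kJ/mol giving 1.9e-6 s).
* **Conductivity.** `sigma = A T^{3/2} exp(-x)` with A = 6e5 A m^-2.
  The printed form of the exponent is dimensionally inconsistent; two
  modes are shipped:
  * `physical` (default): `x = HLG/(2 k_B T)`, k_B = 8.617333262e-5 eV/K —
    the dimensionally consistent band-gap form;
  * `published`: `x = HLG(numeric eV)/(2 R T in kJ/mol)` (≈ 4.955 at
    298 K) — the only convention that reproduces the printed conductivity
    table, which it does for all eight species within 1%.
  Both modes are strictly decreasing in the gap at fixed temperature.

## QTAIM and NBO

Total energy density at a bond critical point is `Hb = G + V` (a.u.).
The (sign(lap), sign(Hb)) pair classifies the contact: strong (−,−),
moderate (−,+), weak (+,+); the (+,−) quadrant is outside the scheme and
flagged `unclassified`. Magnitudes below 1e-10 a.u. sit on a class
boundary; the near-zero quantity is resolved so the well-determined sign
decides the class (near-zero lap counts negative, near-zero Hb positive),
keeping boundary cases out of the unclassified quadrant, and the result is
flagged. All four published sensor–acetone contacts recompute to their
printed Hb exactly (±1e-4, the print precision) and classify moderate.

NBO stabilization is the standard second-order term
`E(2) = q F(i,j)^2 / dE` (the typeset variant `dE - q F^2/dE` appearing in
some sources is a typesetting artifact). Default output unit is kcal/mol,
which reproduces the printed sigma→sigma* and pi→pi* magnitudes (2.65
recomputed vs 2.61 printed for the reference row) even though the printed
header claims kJ/mol; the header tag is preserved verbatim on parsed
records as data. The two large lone-pair rows (29.40, 39.04) are
inconsistent with the expression under any occupancy/unit combination and
are ingested, not recomputed. Likewise the published Laplacians do not
satisfy the virial-type relation 1/4 lap = 2G + V and are taken as
printed.

## Promolecular NCI

The density is a sum of spherically averaged atomic densities
`rho_el(d) = sum_k c_k exp(-d/zeta_k)` (d in bohr), with two- or
three-term fits tabulated in `nci_grid.py` for H, B, C, N, O and Si — the
standard promolecular approach when wavefunctions are unavailable.
Gradient and Hessian come from the same model analytically (for spherical
f: `H = f'' uu^T + (f'/d)(I - uu^T)` per atom); tests verify both against
central finite differences to 1e-6 a.u. at random off-nucleus points.
Derived fields:

* `RDG = |grad rho| / (2 (3 pi^2)^{1/3} rho^{4/3})`
* `sign(lambda_2) rho`, lambda_2 the middle Hessian eigenvalue.

Defaults: grid spacing 0.1 Å with a 2 Å bounding margin; scatter cutoffs
rho < 0.05 a.u. and RDG < 2.0, common NCI practice. Note that any isolated
atom carries a negative-lambda2 envelope at moderate RDG, so contact
detection in tests uses a tight RDG cutoff (0.3) that isolates the
near-zero-RDG internuclear spike. Tests use coarser spacings (0.25–0.5 Å)
on two-atom toys to keep runtimes in milliseconds; the fields are smooth
exponentials, so spacing affects only sampling, not the per-point values.

## Synthetic data

The generator emulates the *shape* of the study's inputs, not its physics:
orbital spectra with an exactly placed frontier pair and seeded filler
levels strictly outside the gap window (0.5 eV minimum offset plus
optional jitter), adsorption systems whose complex energy is back-solved
from a target Eads so that parameter-recovery is exact to float precision,
and BCP rows constructed per requested Rozas class. Default frontier
targets are the pristine-cage pair (−5.38, −3.70 eV) and the default Eads
target −35.81 kJ/mol, i.e. the weakest published complex; the `synth` CLI
fixture set emits one species per published frontier pair. All draws come
from one `numpy` generator seeded per spec — no global random state — and
logs render to byte-identical text for identical specs.

Passing tests on synthetic data therefore demonstrate the correctness of
the arithmetic pipeline and the parsers, and — via the transcribed printed
tables — agreement with the published derived columns. They do not
validate the underlying electronic-structure theory level, real orbital
spectra shapes, geometries, or any quantity the study never printed.

## Known limitations

* Only the documented log dialect is parsed; production logs need an
  adapter.
* Atomic-density fits cover H/B/C/N/O/Si; other elements raise.
* The published recovery-time and large lone-pair E(2) values are carried
  as data because they cannot be derived from the stated expressions (see
  above); no attempt is made to reverse-engineer their provenance into
  the default computation path.
* Published bond-length/angle tables cannot be re-derived because the
  optimized coordinates were never deposited; the geometry module provides
  the generic operations only.
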