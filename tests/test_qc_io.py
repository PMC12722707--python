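"""Parsers and renderers: round-trips, unit discipline, error reporting."""

import math

import pytest

from cagesense.qc_io import (
    BCPRecord,
    LogParseError,
    NBOInteraction,
    OrbitalLevel,
    QcIoWarning,
    SpeciesRecord,
    parse_bcp_table,
    parse_nbo_table,
    parse_species_log,
    render_bcp_table,
    render_nbo_table,
    render_species_log,
)
from conftest import random_species

SAMPLE_LOG = """\
[species]
label = C60

[energy]
unit = hartree
-2285.123456789

[orbitals]
unit = eV
-5.38 2
-3.70 0

[dipole]
unit = debye
0.0 0.0 0.0
"""


class TestSpeciesLog:
    def test_frontier_pair_from_fixture_log(self):
        record = parse_species_log(SAMPLE_LOG)
        assert record.label == "C60"
        assert record.total_energy == pytest.approx(-2285.123456789)
        energies = [l.energy for l in record.levels]
        occs = [l.occupancy for l in record.levels]
        assert energies == pytest.approx([-5.38, -3.70])
        assert occs == [2, 0]

    def test_dipole_block_passes_through(self):
        text = SAMPLE_LOG.replace("0.0 0.0 0.0", "3.0 4.0 0.0")
        record = parse_species_log(text)
        assert record.dipole_vector == pytest.approx((3.0, 4.0, 0.0))

    def test_round_trip_identity(self, rng):
        for i in range(25):
            record = random_species(rng, label=f"species-{i}")
            back = parse_species_log(render_species_log(record))
            assert back.label == record.label
            assert back.total_energy == pytest.approx(record.total_energy, abs=1e-9)
            assert len(back.levels) == len(record.levels)
            for a, b in zip(back.levels, record.levels):
                assert a.energy == pytest.approx(b.energy, abs=1e-9)
                assert a.occupancy == b.occupancy
            for a, b in zip(back.dipole_vector, record.dipole_vector):
                assert a == pytest.approx(b, abs=1e-9)
            if record.bsse is None:
                assert back.bsse is None
            else:
                assert back.bsse == pytest.approx(record.bsse, abs=1e-9)

    @pytest.mark.parametrize("unit,scale", [
        ("eV", 1.0),
        ("hartree", 1.0 / 27.211386245988),
        ("kJ/mol", 2625.4996394799 / 27.211386245988),
    ])
    def test_orbital_unit_dialects_agree(self, unit, scale):
        """The same physical level expressed in any dialect lands on one eV value."""
        homo, lumo = -5.38 * scale, -3.70 * scale
        text = (f"[species]\nlabel = X\n[energy]\nunit = hartree\n-1.0\n"
                f"[orbitals]\nunit = {unit}\n{homo!r} 2\n{lumo!r} 0\n"
                f"[dipole]\nunit = debye\n0 0 0\n")
        record = parse_species_log(text)
        assert record.levels[0].energy == pytest.approx(-5.38, abs=1e-6)
        assert record.levels[1].energy == pytest.approx(-3.70, abs=1e-6)

    @pytest.mark.parametrize("block", ["species", "energy", "orbitals", "dipole"])
    def test_missing_block_names_the_block(self, block):
        text = "\n".join(seg for seg in SAMPLE_LOG.split("\n\n")
                         if not seg.startswith(f"[{block}]"))
        with pytest.raises(LogParseError) as err:
            parse_species_log(text)
        assert err.value.block == block

    def test_occupied_above_virtual_flags_warning(self):
        text = SAMPLE_LOG.replace("-5.38 2\n-3.70 0", "-5.38 2\n-3.70 0\n-2.0 2")
        with pytest.warns(QcIoWarning):
            record = parse_species_log(text)
        assert "non-monotone-occupancy" in record.warnings

    def test_levels_sorted_ascending_regardless_of_input_order(self):
        text = SAMPLE_LOG.replace("-5.38 2\n-3.70 0", "-3.70 0\n-5.38 2")
        record = parse_species_log(text)
        assert [l.energy for l in record.levels] == pytest.approx([-5.38, -3.70])

    def test_unicode_minus_normalized(self):
        record = parse_species_log(SAMPLE_LOG.replace("-5.38", "−5.38"))
        assert record.levels[0].energy == pytest.approx(-5.38)


class TestOrbitalLevel:
    @pytest.mark.parametrize("occ", [-1, 3])
    def test_invalid_occupancy_rejected(self, occ):
        with pytest.raises(ValueError):
            OrbitalLevel(-5.0, occ)

    def test_nonfinite_energy_rejected(self):
        with pytest.raises(ValueError):
            OrbitalLevel(math.nan, 2)


class TestBCPTable:
    def test_tabulated_row(self):
        text = "pair_label,rho,g,v,lap\nBC59@Acetone,0.099,0.158,0.054,-0.103\n"
        (rec,) = parse_bcp_table(text)
        assert (rec.rho, rec.g, rec.v, rec.lap) == (0.099, 0.158, 0.054, -0.103)

    def test_empty_body_gives_empty_list(self):
        assert parse_bcp_table("pair_label,rho,g,v,lap\n") == []

    def test_nonpositive_rho_row_rejected_with_diagnostic(self):
        text = ("pair_label,rho,g,v,lap\n"
                "good,0.01,0.002,-0.001,-0.003\n"
                "bad,-1,0.1,0.1,0.1\n")
        with pytest.warns(QcIoWarning, match="bad"):
            records = parse_bcp_table(text)
        assert [r.pair_label for r in records] == ["good"]

    def test_missing_column_is_an_error(self):
        with pytest.raises(LogParseError, match="lap"):
            parse_bcp_table("pair_label,rho,g,v\nx,0.1,0.1,0.1\n")

    def test_round_trip(self, rng):
        records = [BCPRecord(f"p{i}", float(rng.uniform(0.001, 0.2)),
                             float(rng.uniform(0, 0.3)),
                             float(rng.normal(0, 0.1)),
                             float(rng.normal(0, 0.1))) for i in range(8)]
        back = parse_bcp_table(render_bcp_table(records))
        assert back == records


class TestNBOTable:
    HEADER = "donor type acceptor type E2[kJ/mol] dE(a.u.) F(a.u.)\n"

    def test_typed_row(self):
        text = self.HEADER + "C1-C2 σ C1-C6 σ* 2.61 1.09 0.048\n"
        (rec,) = parse_nbo_table(text)
        assert rec.donor == "C1-C2" and rec.acceptor == "C1-C6"
        assert rec.donor_type == "σ" and rec.acceptor_type == "σ*"
        assert (rec.e2, rec.delta_e, rec.f) == (2.61, 1.09, 0.048)
        assert rec.e2_unit == "kJ/mol"  # header tag preserved verbatim

    def test_zero_delta_e_row_rejected(self):
        text = self.HEADER + "A σ B σ* 1.0 0.0 0.05\n"
        with pytest.warns(QcIoWarning):
            assert parse_nbo_table(text) == []

    def test_three_rows_order_preserved(self):
        text = self.HEADER + ("A pi B pi* 1.0 0.5 0.01\n"
                              "C LP D pi* 2.0 0.4 0.02\n"
                              "E sigma F sigma* 3.0 0.3 0.03\n")
        records = parse_nbo_table(text)
        assert [r.donor for r in records] == ["A", "C", "E"]
        assert [r.donor_type for r in records] == ["π", "LP", "σ"]

    def test_unknown_type_token_named_in_error(self):
        text = self.HEADER + "A delta B pi* 1.0 0.5 0.01\n"
        with pytest.raises(LogParseError, match="delta"):
            parse_nbo_table(text)

    def test_round_trip(self):
        records = [NBOInteraction("C1-C2", "σ", "C1-C6", "σ*", 2.61, 1.09,
                                  0.048, q=1.9, e2_unit="kcal/mol")]
        assert parse_nbo_table(render_nbo_table(records)) == records
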