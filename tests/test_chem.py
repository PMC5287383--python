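"""Mass calculus, composition and adduct grammar."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nglyco.chem import (
    DEFAULT_TABLE,
    AdductSpec,
    GlycanComposition,
    Peak,
    format_composition,
    ion_mz,
    neutral_monoisotopic_mass,
    parse_adduct_label,
    parse_composition,
    ppm_error,
)
from nglyco.errors import AdductError, CompositionError, GlycoParseError

# hex >= 1 keeps every draw a valid composition (at least one non-sulfate residue)
compositions = st.builds(
    GlycanComposition,
    hex=st.integers(1, 12),
    hexnac=st.integers(0, 8),
    fuc=st.integers(0, 4),
    neu5ac=st.integers(0, 4),
    neu5gc=st.integers(0, 3),
    sulfate=st.integers(0, 2),
)

adducts = st.sampled_from(
    [
        AdductSpec(h_added=1),
        AdductSpec(na=1),
        AdductSpec(k=1),
        AdductSpec(na=2),
        AdductSpec(h_removed=1),
        AdductSpec(h_removed=2),
        AdductSpec(h_removed=2, na=1),
        AdductSpec(h_removed=3, na=2),
        AdductSpec(h_removed=4, na=2),
    ]
)


class TestNeutralMass:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("(Hex)5(HexNAc)2", 1234.4334),
            ("(Hex)1", 180.0634),  # free hexose
            ("(Hex)3(HexNAc)5(Fuc)1(Neu5Ac)1", 1956.7193),
        ],
    )
    def test_reference_masses(self, text, expected):
        assert neutral_monoisotopic_mass(parse_composition(text)) == pytest.approx(expected, abs=1e-3)

    @given(a=compositions, b=compositions)
    @settings(max_examples=200, deadline=None)
    def test_mass_additivity(self, a, b):
        """Joining compositions adds residue masses and removes one water."""
        lhs = neutral_monoisotopic_mass(a + b)
        rhs = neutral_monoisotopic_mass(a) + neutral_monoisotopic_mass(b) - DEFAULT_TABLE.water
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_empty_composition_rejected(self):
        with pytest.raises(CompositionError):
            GlycanComposition()
        with pytest.raises(CompositionError):
            GlycanComposition(sulfate=1)  # sulfate alone is not a glycan


class TestIonMz:
    def test_sodiated_high_mannose_matches_printed_mass(self):
        mz = ion_mz(parse_composition("(Hex)5(HexNAc)2"), parse_adduct_label("[M+Na]+"))
        assert round(mz, 2) == 1257.42

    def test_deprotonation_shifts_by_one_proton(self):
        comp = parse_composition("(Hex)4(HexNAc)2")
        m = neutral_monoisotopic_mass(comp)
        assert ion_mz(comp, parse_adduct_label("[M-H]-")) == pytest.approx(m - DEFAULT_TABLE.proton)

    def test_doubly_deprotonated_mass(self):
        # the printed observed 1126.17 deviates ~0.21 Da from theory;
        # the theoretical value is asserted here
        mz = ion_mz(parse_composition("(Hex)5(HexNAc)4(Neu5Gc)2"), parse_adduct_label("[M-2H]2-"))
        assert mz == pytest.approx(1126.379, abs=2e-3)

    @given(comp=compositions, adduct=adducts)
    @settings(max_examples=200, deadline=None)
    def test_charge_consistency(self, comp, adduct):
        """m/z times |z| minus the carrier masses recovers the neutral mass."""
        t = DEFAULT_TABLE
        mz = ion_mz(comp, adduct)
        back = mz * abs(adduct.charge) - adduct.na * t.sodium - adduct.k * t.potassium
        back -= (adduct.h_added - adduct.h_removed) * t.proton
        assert back == pytest.approx(neutral_monoisotopic_mass(comp), abs=1e-9)

    def test_zero_charge_is_invalid(self):
        with pytest.raises(AdductError):
            AdductSpec(h_removed=1, h_added=1)


class TestPpmError:
    @pytest.mark.parametrize(
        "observed, theoretical, expected",
        [(1000.010, 1000.000, 10.0), (1500.0, 1500.0, 0.0), (999.995, 1000.000, -5.0)],
    )
    def test_definition(self, observed, theoretical, expected):
        assert ppm_error(observed, theoretical) == pytest.approx(expected)

    def test_nonpositive_theoretical_rejected(self):
        with pytest.raises(GlycoParseError):
            ppm_error(1000.0, 0.0)


class TestCompositionGrammar:
    @pytest.mark.parametrize(
        "text, counts",
        [
            ("(Hex)2(HexNAc)4", {"hex": 2, "hexnac": 4}),
            ("(Hex)3(HexNAc)6S1", {"hex": 3, "hexnac": 6, "sulfate": 1}),
            ("(Hex)3(HexNAc)6(NeuAc)1", {"hex": 3, "hexnac": 6, "neu5ac": 1}),
            ("(Fuc)2(Neu5Ac)1(HexNAc)2", {"hexnac": 2, "fuc": 2, "neu5ac": 1}),
        ],
    )
    def test_parses(self, text, counts):
        comp = parse_composition(text)
        for name, value in counts.items():
            assert getattr(comp, name) == value

    @pytest.mark.parametrize("bad", ["", "(Hex)0", "(Pent)2", "(Hex)2(Hex)1", "Hex2x"])
    def test_rejects(self, bad):
        with pytest.raises(GlycoParseError):
            parse_composition(bad)

    @given(comp=compositions)
    @settings(max_examples=200, deadline=None)
    def test_roundtrip(self, comp):
        assert parse_composition(format_composition(comp)) == comp

    def test_all_printed_compositions_roundtrip(self, all_fixture_rows):
        for _, row in all_fixture_rows:
            comp = parse_composition(row["composition"])
            assert parse_composition(format_composition(comp)) == comp


class TestAdductGrammar:
    @pytest.mark.parametrize(
        "label, spec",
        [
            ("[M+H]+", AdductSpec(h_added=1)),
            ("[M+Na]+", AdductSpec(na=1)),
            ("[M+2Na]2+", AdductSpec(na=2)),
            ("[M-H]-", AdductSpec(h_removed=1)),
            ("[M-2H]2-", AdductSpec(h_removed=2)),
            ("[M-2H+Na]-", AdductSpec(h_removed=2, na=1)),
            ("[M-3H+2Na]-", AdductSpec(h_removed=3, na=2)),
            ("[M-4H+2Na]2-", AdductSpec(h_removed=4, na=2)),
        ],
    )
    def test_parse_and_format(self, label, spec):
        assert parse_adduct_label(label) == spec
        assert spec.label() == label
        assert parse_adduct_label(spec.label()) == spec

    @pytest.mark.parametrize("bad", ["[M]0", "[M+H]-", "[M-Na]-", "M+Na+", "[M+3Na]3+"])
    def test_rejects(self, bad):
        with pytest.raises(GlycoParseError):
            parse_adduct_label(bad)

    def test_all_printed_adducts_roundtrip(self, all_fixture_rows):
        for _, row in all_fixture_rows:
            spec = parse_adduct_label(row["adduct"])
            assert parse_adduct_label(spec.label()) == spec


class TestPeak:
    def test_invalid_peaks_rejected(self):
        with pytest.raises(GlycoParseError):
            Peak(mz=-1.0, intensity=1.0, mode="positive")
        with pytest.raises(GlycoParseError):
            Peak(mz=100.0, intensity=1.0, mode="up")
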