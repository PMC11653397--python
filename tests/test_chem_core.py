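"""Formula arithmetic, exact anion masses, and the rule engine."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pcbscreen.chem_core import (ELECTRON_MASS, PCB95, ElementalFormula,
                                 IonSpecies, apply_rule, default_rules,
                                 enumerate_suspects, expected_losses, ion_mz,
                                 monoisotopic_mass, ppm_error,
                                 read_suspects_csv, write_suspects_csv)

# The nine distinct anion compositions a pentachlorobiphenyl metabolite
# screen distinguishes, with their exact [M-H]- m/z values (5 decimals).
REFERENCE_ANIONS = {
    "C12H5Cl5O": 338.87103,    # OH-PCB95
    "C12H5Cl5O4S": 418.82784,  # PCB95 sulfate
    "C12H5Cl5O5S": 434.82276,  # OH-PCB95 sulfate
    "C13H7Cl5O2": 368.88159,   # MeO-OH-PCB95
    "C13H7Cl5O3": 384.87651,   # MeO-diOH-PCB95
    "C12H5Cl5O3S": 402.83293,  # PCB95 sulfonate
    "C12H7Cl3O": 270.94897,    # OH-tri-CB
    "C12H6Cl4O": 304.91000,    # OH-tetra-CB
    "C12H7Cl3O2": 286.94389,   # diOH-tri-CB
}


class TestFormula:
    def test_parse_and_hill(self):
        f = ElementalFormula.parse("C12H5Cl5")
        assert f["C"] == 12 and f["H"] == 5 and f["Cl"] == 5
        assert f["O"] == 0
        assert f.hill() == "C12H5Cl5"

    def test_equality_is_countwise(self):
        assert ElementalFormula({"Cl": 5, "C": 12, "H": 5}) == PCB95

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            PCB95.add({"O": -1})

    def test_removing_to_zero_drops_element(self):
        f = ElementalFormula.parse("CH4").remove({"C": 1})
        assert "C" not in f and f.hill() == "H4"


class TestMasses:
    def test_carbon_12_definition(self):
        assert monoisotopic_mass(ElementalFormula.parse("C")) == 12.0

    def test_pcb95_neutral_hand_sum(self):
        # 12*12 + 5*1.00782503 + 5*34.96885268
        assert monoisotopic_mass(PCB95) == pytest.approx(323.88339, abs=1e-5)

    def test_empty_formula_is_zero(self):
        assert monoisotopic_mass(ElementalFormula()) == 0.0

    def test_unknown_element_named_in_error(self):
        with pytest.raises(ValueError, match="Xx"):
            monoisotopic_mass({"Xx": 1})

    @pytest.mark.parametrize("formula,mz", sorted(REFERENCE_ANIONS.items()))
    def test_anion_mz_to_five_decimals(self, formula, mz):
        assert ion_mz(ElementalFormula.parse(formula), -1) == pytest.approx(
            mz, abs=2e-5)

    def test_electron_mass_term_is_required(self):
        """Dropping the electron mass shifts every anion by ~ -0.55 mDa."""
        without = monoisotopic_mass(
            ElementalFormula.parse("C12H5Cl5O").remove({"H": 1}))
        assert ion_mz(ElementalFormula.parse("C12H5Cl5O")) - without == pytest.approx(
            ELECTRON_MASS, abs=1e-9)
        assert abs(without - 338.87103) > 4e-4  # would fail the reference check

    def test_deprotonation_requires_hydrogen(self):
        with pytest.raises(ValueError):
            ion_mz(ElementalFormula.parse("CCl4"), -1)
        with pytest.raises(ValueError):
            ion_mz(PCB95, 0)


class TestPpmError:
    def test_identical_masses(self):
        assert ppm_error(338.87103, 338.87103) == 0.0

    def test_signed_values(self):
        assert ppm_error(338.87104, 338.87103) == pytest.approx(0.0295, abs=1e-3)
        assert ppm_error(418.82768, 418.82784) == pytest.approx(-0.382, abs=1e-3)

    def test_nonpositive_theoretical_rejected(self):
        with pytest.raises(ValueError):
            ppm_error(100.0, 0.0)

    @given(st.floats(100.0, 1000.0), st.floats(100.0, 1000.0))
    def test_antisymmetric_up_to_denominator(self, a, b):
        assert ppm_error(a, b) / 1e6 * b == pytest.approx(-(ppm_error(b, a) / 1e6 * a))


class TestRules:
    def test_hydroxylation(self):
        rules = default_rules()
        assert apply_rule(PCB95, rules["OX"]) == ElementalFormula.parse("C12H5Cl5O")

    def test_dechlorination(self):
        rules = default_rules()
        oh = ElementalFormula.parse("C12H5Cl5O")
        assert apply_rule(oh, rules["DECHLOR"]) == ElementalFormula.parse("C12H6Cl4O")

    def test_application_cap_enforced(self):
        rules = default_rules()
        with pytest.raises(ValueError, match="DECHLOR"):
            apply_rule(PCB95, rules["DECHLOR"], applied={"DECHLOR": 2})

    def test_methylation_requires_diol_provenance(self):
        rules = default_rules()
        with pytest.raises(ValueError, match="METH"):
            apply_rule(ElementalFormula.parse("C12H5Cl5O"), rules["METH"],
                       applied={"OX": 1})

    def test_rule_then_inverse_restores_formula(self):
        rules = default_rules()
        for rule in rules.values():
            applied = {"OX": 2}  # satisfies every constraint except SULFON-C
            if rule.name == "SULFON-C":
                applied = {}
            after = apply_rule(PCB95.add({"O": 2}) if applied else PCB95,
                               rule, applied=applied)
            start = PCB95.add({"O": 2}) if applied else PCB95
            assert after.remove(rule.delta) == start


class TestEnumeration:
    def test_all_reference_ions_generated(self, suspects):
        ions = {c.ion.ion_formula.hill() for c in suspects}
        expect = {ElementalFormula.parse(f).remove({"H": 1}).hill()
                  for f in REFERENCE_ANIONS}
        assert expect <= ions

    def test_class_labels_cover_all_eight(self, suspects):
        ids = {c.class_id for c in suspects}
        assert {"1.1", "1.2", "2", "3", "4", "5", "6", "7", "8"} <= ids

    def test_single_rule_depth_one(self):
        rules = {"OX": default_rules()["OX"]}
        cands = enumerate_suspects(PCB95, rules, max_depth=1, include_parent=False)
        assert len(cands) == 1
        assert cands[0].theoretical_mz == pytest.approx(338.87103, abs=2e-5)

    def test_methylation_chain_reaches_meo_oh(self):
        cands = enumerate_suspects()
        meo = [c for c in cands if c.class_id == "3"]
        assert meo and meo[0].ion.ion_formula.hill() == "C13H6Cl5O2"
        assert meo[0].theoretical_mz == pytest.approx(368.88159, abs=2e-5)

    def test_no_rules_yields_parent_only(self):
        cands = enumerate_suspects(PCB95, rules={}, max_depth=3)
        assert len(cands) == 1 and cands[0].class_id == "parent"

    def test_output_independent_of_rule_listing_order(self):
        rules = default_rules()
        reversed_rules = dict(reversed(list(rules.items())))
        a = {c.key for c in enumerate_suspects(PCB95, rules)}
        b = {c.key for c in enumerate_suspects(PCB95, reversed_rules)}
        assert a == b

    def test_csv_round_trip(self, suspects, tmp_path):
        path = tmp_path / "suspects.csv"
        write_suspects_csv(suspects, path)
        back = read_suspects_csv(path)
        assert {c.key for c in back} == {c.key for c in suspects}
        assert all(abs(x.theoretical_mz - y.theoretical_mz) < 1e-9
                   for x, y in zip(sorted(back, key=lambda c: c.key),
                                   sorted(suspects, key=lambda c: c.key)))


class TestExpectedLosses:
    def test_phenol_loses_hcl(self):
        (label, mass), = expected_losses(("OX",))
        assert label == "HCl"
        assert mass == pytest.approx(35.97668, abs=1e-5)
        # consistent with fragment 302.89438 = 338.87104 - loss (within 0.1 mDa)
        assert 338.87104 - mass == pytest.approx(302.89438, abs=1e-4)

    def test_sulfate_loses_so3(self):
        (label, mass), = expected_losses(("OX", "SULF-O"))
        assert label == "SO3"
        assert mass == pytest.approx(79.95682, abs=1e-5)

    def test_methylated_loses_methyl(self):
        (label, mass), = expected_losses(("OX", "OX", "METH"))
        assert label == "CH3"
        assert mass == pytest.approx(15.02348, abs=1e-5)

    def test_ring_sulfonate_has_no_loss(self):
        assert expected_losses(("SULFON-C",)) == ()
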