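"""Virtual 3-component synthesis: ring opening, acylation, masses, degradation."""

import pytest

import dblipid as dl
from dblipid import chem
from dblipid.enumerator import make_name, parse_formula

# Independent element-bookkeeping oracle: formula maps summed by hand.
AMINE1 = {"C": 5, "H": 14, "N": 2}  # 3-(dimethylamino)-1-propylamine
EPOXIDE_C10 = {"C": 10, "H": 20, "O": 1}
ACYL_C8 = {"C": 8, "H": 15, "Cl": 1, "O": 1}
HCL = {"H": 1, "Cl": 1}

# Monoisotopic isotope masses, restated here as the independent oracle.
MASS = {"H": 1.0078250319, "C": 12.0, "N": 14.0030740052, "O": 15.9949146221}


def hand_mass(formula):
    return sum(MASS[el] * n for el, n in formula.items())


class TestRingOpening:
    def test_aminoalcohol_formula_by_element_bookkeeping(self, registry):
        """amine-1 + 2x C10 epoxide = C25H54N2O2 (no atoms lost)."""
        aa = dl.open_epoxide(registry.get("amine-1"), registry.get("epoxide-10"), 2)
        expected = chem.add_formulas(AMINE1, chem.scale_formula(EPOXIDE_C10, 2))
        assert aa.formula == expected == {"C": 25, "H": 54, "N": 2, "O": 2}
        assert aa.stage == "aminoalcohol"
        assert chem.count_hydroxyls(aa.mol) == 2
        assert chem.count_esters(aa.mol) == 0

    def test_count_zero_returns_amine_unchanged(self, registry):
        amine = registry.get("amine-1")
        out = dl.open_epoxide(amine, registry.get("epoxide-10"), 0)
        assert out.structure == amine.structure

    def test_di_secondary_diamine_gets_one_tail_per_nitrogen(self, registry):
        """Each secondary N contributes one N-H, so tails distribute 1+1."""
        amine = registry.get("amine-16")  # CNCCNC
        aa = dl.open_epoxide(amine, registry.get("epoxide-10"), 2)
        assert chem.count_hydroxyls(aa.mol) == 2
        # both nitrogens now tertiary: no substitutable N-H left
        assert chem.total_substitutable_nh(aa.mol) == 0

    def test_insufficient_nh_raises(self, registry):
        # after two ring openings on a primary monoamine, no N-H remains
        aa = dl.open_epoxide(registry.get("amine-2"), registry.get("epoxide-10"), 2)
        assert chem.total_substitutable_nh(aa.mol) == 0
        with pytest.raises(dl.ReactionError, match="body tails"):
            dl.open_epoxide(
                dl.BuildingBlock.create("amine-t", "amine", "CN(C)C", 3, label="t"),
                registry.get("epoxide-10"),
                1,
            )

    def test_non_terminal_epoxide_rejected(self, registry):
        internal = dl.BuildingBlock.create("epoxide-int", "epoxide", "CCC1OC1C", 6)
        with pytest.raises(dl.ReactionError, match="terminal"):
            dl.open_epoxide(registry.get("amine-1"), internal, 2)

    def test_secondary_alcohol_regiochemistry(self, registry):
        """N attacks the terminal CH2: the alcohol carbon keeps the alkyl chain."""
        aa = dl.open_epoxide(registry.get("amine-2"), registry.get("epoxide-6"), 1)
        # product contains N-CH2-CH(OH)-C4H9: a secondary, not primary, alcohol
        assert aa.mol.HasSubstructMatch(chem.mol_from_smiles("CCCCC(O)CN"))


class TestAcylation:
    def test_lead_product_matches_printed_formula(self, lead):
        """11-10-8 = C42H82N2O4, the published MS characterization."""
        assert lead.formula == {"C": 42, "H": 82, "N": 2, "O": 4}
        assert round(lead.monoisotopic_mass, 2) == 678.63
        assert lead.stage == "two_branch"
        assert chem.count_esters(lead.mol) == 2

    def test_one_branch_intermediate(self, registry):
        aa = dl.open_epoxide(registry.get("amine-1"), registry.get("epoxide-10"), 2)
        one = dl.acylate(aa, registry.get("acyl-8"), 1)
        assert one.stage == "one_branch"
        assert chem.count_esters(one.mol) == 1
        assert chem.count_hydroxyls(one.mol) == 1

    def test_count_zero_identity(self, registry):
        aa = dl.open_epoxide(registry.get("amine-1"), registry.get("epoxide-10"), 2)
        assert dl.acylate(aa, registry.get("acyl-8"), 0).structure == aa.structure

    def test_count_exceeding_hydroxyls_raises(self, registry):
        aa = dl.open_epoxide(registry.get("amine-1"), registry.get("epoxide-10"), 2)
        one = dl.acylate(aa, registry.get("acyl-8"), 1)
        with pytest.raises(dl.ReactionError, match="branch tails"):
            dl.acylate(one, registry.get("acyl-8"), 2)

    def test_hydrogen_count_consistent_with_nmr_integrals(self, lead):
        """Total H of 11-10-8 equals the published NMR integral sum."""
        nmr_integrals = [2, 2, 2, 2, 2, 4, 4, 8, 44, 12]
        assert sum(nmr_integrals) == 82
        assert lead.formula["H"] == 82


class TestMasses:
    def test_monoisotopic_from_formula_string(self):
        assert round(dl.monoisotopic_mass("C42H82N2O4"), 2) == 678.63

    def test_water_textbook_value(self):
        assert round(dl.monoisotopic_mass({"H": 2, "O": 1}), 2) == 18.01

    def test_hand_summed_oracle_for_1_10_8_analogue(self):
        """C41H82N2O4 against an independently restated isotope table."""
        formula = {"C": 41, "H": 82, "N": 2, "O": 4}
        assert dl.monoisotopic_mass(formula) == pytest.approx(
            hand_mass(formula), abs=1e-6
        )

    def test_protonated_mass_is_MH_plus(self, lead):
        # formula-table mass vs the toolkit's exact weight: equal to ~1e-6 Da
        assert dl.protonated_mass(lead) == pytest.approx(
            lead.monoisotopic_mass + 1.007276466, abs=1e-6
        )
        # printed found [M + H]+ for the lead is 679.62-679.63
        assert round(dl.protonated_mass(lead), 1) == 679.6

    def test_unknown_element_rejected(self):
        with pytest.raises(dl.ValidationError, match="unknown element"):
            dl.monoisotopic_mass({"Xx": 1})

    def test_empty_formula_rejected(self):
        with pytest.raises(dl.ValidationError):
            dl.monoisotopic_mass({})

    def test_parse_formula(self):
        assert parse_formula("C42H82N2O4") == {"C": 42, "H": 82, "N": 2, "O": 4}
        with pytest.raises(dl.ValidationError):
            parse_formula("42C")


class TestEnumeration:
    def test_library_1_has_25_products(self, library1):
        assert len(library1) == 25
        assert all(l.stage == "two_branch" for l in library1)

    def test_full_factorial_has_500_products(self, registry):
        design = dl.LibraryDesign.of(
            [b.id for b in registry.amines],
            [b.id for b in registry.epoxides],
            [b.id for b in registry.acyl_chlorides],
        )
        assert len(dl.enumerate_library(registry, design)) == 500

    def test_singleton_design(self, registry):
        design = dl.LibraryDesign.of(["amine-1"], ["epoxide-10"], ["acyl-8"])
        out = dl.enumerate_library(registry, design)
        assert len(out) == 1
        assert out[0].name == "1-10-8"

    def test_empty_design_is_empty_not_error(self, registry):
        assert dl.enumerate_library(registry, dl.LibraryDesign.of([], [], [])) == []

    def test_deterministic_ordering(self, library1):
        names = [l.xmn for l in library1]
        assert names == sorted(names)

    def test_naming_bijective(self, library1):
        for lip in library1:
            x, m, n = lip.xmn
            assert make_name(x, m, n) == lip.name

    def test_amine_without_two_tails_skipped_with_warning(self, registry):
        tert = dl.BuildingBlock.create("amine-90", "amine", "CCN(C)C", 4)
        reg = dl.Registry(
            amines=[tert],
            epoxides=registry.epoxides[:1],
            acyl_chlorides=registry.acyl_chlorides[:1],
        )
        design = dl.LibraryDesign.of(
            ["amine-90"], [reg.epoxides[0].id], [reg.acyl_chlorides[0].id]
        )
        with pytest.warns(UserWarning, match="two body tails"):
            assert dl.enumerate_library(reg, design) == []


class TestConservation:
    def test_element_balance_across_library_1(self, registry, library1):
        """amine + 2 epoxide + 2 acyl chloride = product + 2 HCl, per product."""
        for lip in library1:
            lhs = chem.add_formulas(
                chem.formula_map(registry.get(lip.amine_id).mol),
                chem.scale_formula(
                    chem.formula_map(registry.get(lip.epoxide_id).mol), 2
                ),
                chem.scale_formula(chem.formula_map(registry.get(lip.acyl_id).mol), 2),
            )
            rhs = chem.add_formulas(lip.formula, chem.scale_formula(HCL, 2))
            assert lhs == rhs, lip.name


class TestDegradation:
    def test_full_cleavage_returns_aminoalcohol_plus_octanoic_acid(
        self, registry, lead
    ):
        mets = dl.degrade(lead, 2)
        aa = dl.open_epoxide(registry.get("amine-11"), registry.get("epoxide-10"), 2)
        assert mets.aminoalcohol.structure == aa.structure
        assert len(mets.fatty_acids) == 2
        for acid in mets.fatty_acids:
            assert acid.formula == {"C": 8, "H": 16, "O": 2}  # octanoic acid

    def test_element_conservation_with_water(self, lead):
        """lipidoid + 2 H2O = aminoalcohol + 2 fatty acid."""
        mets = dl.degrade(lead, 2)
        water2 = {"H": 4, "O": 2}
        lhs = chem.add_formulas(lead.formula, water2)
        rhs = chem.add_formulas(
            mets.aminoalcohol.formula, *[a.formula for a in mets.fatty_acids]
        )
        assert lhs == rhs

    def test_zero_cleavage_identity(self, lead):
        mets = dl.degrade(lead, 0)
        assert mets.intermediate.structure == lead.structure
        assert mets.fatty_acids == []

    def test_single_cleavage_equals_single_acylation(self, registry, lead):
        """degrade(·, 1) lands on the same one-branch intermediate as acylate(·, 1)."""
        mets = dl.degrade(lead, 1)
        aa = dl.open_epoxide(registry.get("amine-11"), registry.get("epoxide-10"), 2)
        one = dl.acylate(aa, registry.get("acyl-8"), 1)
        assert mets.intermediate.structure == one.structure
        assert mets.intermediate.stage == "one_branch"

    def test_overcleaving_raises(self, lead):
        with pytest.raises(dl.ReactionError, match="cleave"):
            dl.degrade(lead, 3)

    @pytest.mark.parametrize("k", [1, 2])
    def test_degrade_inverts_acylate(self, registry, k):
        """degrade(acylate(a, c, k), k) recovers the aminoalcohol a."""
        aa = dl.open_epoxide(registry.get("amine-7"), registry.get("epoxide-8"), 2)
        product = dl.acylate(aa, registry.get("acyl-12"), k)
        mets = dl.degrade(product, k)
        assert mets.aminoalcohol.structure == aa.structure


class TestTabularOutput:
    def test_library_csv_and_sdf(self, tmp_path, library1):
        df = dl.enumerator.library_to_dataframe(library1)
        assert list(df.columns) == [
            "name", "x", "m", "n", "formula",
            "monoisotopic_mass", "average_mass", "smiles",
        ]
        assert len(df) == 25
        csv_path = dl.enumerator.write_library_csv(library1, tmp_path / "lib.csv")
        assert csv_path.exists()
        sdf_path = dl.enumerator.write_library_sdf(library1[:3], tmp_path / "lib.sdf")
        assert sdf_path.read_text().count("$$$$") == 3
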