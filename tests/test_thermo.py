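import math

import pytest
from hypothesis import given, settings, strategies as st

from anacat.composition import parse_formula
from anacat.thermo import (
    ConversionStoichiometry,
    FormationEnergyTable,
    ThermoConditions,
    atp_production_efficiency,
    battley_formation_energy,
    concentration_correction,
    legendre_transform,
    standard_reaction_energy,
)

GLUCOSE_COMBUSTION = ConversionStoichiometry(
    {"glc": -1, "o2": -6, "co2": 6, "h2o": 6}, basis="per_mol", label="combustion"
)


class TestStandardReactionEnergy:
    def test_empty_is_zero(self, table):
        assert standard_reaction_energy(ConversionStoichiometry({}), table) == 0.0

    def test_glucose_combustion(self, table):
        dg = standard_reaction_energy(GLUCOSE_COMBUSTION, table)
        # group-contribution reference value with its stated uncertainty
        assert dg == pytest.approx(-2927.8, abs=49.5)

    def test_antisymmetry(self, table):
        dg = standard_reaction_energy(GLUCOSE_COMBUSTION, table)
        assert standard_reaction_energy(GLUCOSE_COMBUSTION.reversed(), table) == pytest.approx(-dg)

    def test_missing_compound_listed(self, table):
        with pytest.raises(KeyError, match="unobtainium"):
            standard_reaction_energy(
                ConversionStoichiometry({"glc": -1, "unobtainium": 1}), table
            )

    def test_additive_over_conversions(self, table):
        ferm = ConversionStoichiometry({"glc": -1, "etoh": 2, "co2": 2})
        resp_of_etoh = ConversionStoichiometry({"etoh": -2, "o2": -6, "co2": 4, "h2o": 6})
        lhs = standard_reaction_energy(ferm + resp_of_etoh, table)
        rhs = standard_reaction_energy(ferm, table) + standard_reaction_energy(resp_of_etoh, table)
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_per_cmol_basis_consistency(self, table):
        per_mol = standard_reaction_energy(GLUCOSE_COMBUSTION, table)
        per_cmol = standard_reaction_energy(GLUCOSE_COMBUSTION.scaled(1 / 6), table)
        assert per_cmol * 6 == pytest.approx(per_mol, abs=1e-9)
        assert per_cmol == pytest.approx(-488, abs=10)

    def test_tsv_round_trip(self, table, tmp_path):
        path = tmp_path / "t.tsv"
        table.to_tsv(path, tmp_path / "t.conditions.json")
        back = FormationEnergyTable.from_tsv(path, tmp_path / "t.conditions.json")
        assert back.energies == pytest.approx(table.energies)
        assert back.conditions == table.conditions


class TestConcentrationCorrection:
    def test_standard_concentrations_vanish(self):
        conc = {c: 1.0 for c in GLUCOSE_COMBUSTION.coefficients}
        assert concentration_correction(GLUCOSE_COMBUSTION, conc) == 0.0

    def test_ten_molar_product_is_rt_ln10(self):
        stoich = ConversionStoichiometry({"p": 1})
        val = concentration_correction(stoich, {"p": 10.0})
        assert round(val, 1) == 5.7

    def test_glucose_combustion_medium(self):
        # substrate-rich aerobic medium: 0.16 M glucose, 250 uM O2, 13 uM CO2
        val = concentration_correction(
            GLUCOSE_COMBUSTION,
            {"glc": 0.16, "o2": 250e-6, "co2": 13e-6},
        )
        assert round(val, 1) == -39.4

    def test_water_activity_ignored(self):
        with_water = concentration_correction(GLUCOSE_COMBUSTION,
                                              {"glc": 0.16, "o2": 250e-6, "co2": 13e-6, "h2o": 55.5})
        without = concentration_correction(GLUCOSE_COMBUSTION,
                                           {"glc": 0.16, "o2": 250e-6, "co2": 13e-6})
        assert with_water == without

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            concentration_correction(ConversionStoichiometry({"p": 1}), {"p": 0.0})

    @settings(derandomize=True, max_examples=30)
    @given(nu=st.floats(-3, 3).filter(lambda x: abs(x) > 1e-3), c=st.floats(1e-6, 10))
    def test_decade_scaling(self, nu, c):
        stoich = ConversionStoichiometry({"s": nu})
        diff = (concentration_correction(stoich, {"s": 10 * c})
                - concentration_correction(stoich, {"s": c}))
        rt_ln10 = 8.314462618e-3 * 298.15 * math.log(10)
        assert diff == pytest.approx(nu * rt_ln10, rel=1e-9)


class TestBattleyFormationEnergy:
    @pytest.mark.parametrize(
        "formula, expected",
        [
            ("CH1.79O0.57N0.15", -104.9),
            ("CH1.811O0.503N0.258P0.022S0.006-0.018", -101.10),
            ("CH1.8243O0.6589N0.1557P0.0055S0.0022", -128.76),
        ],
    )
    def test_published_anchors(self, formula, expected):
        assert battley_formation_energy(parse_formula(formula)) == pytest.approx(expected, abs=1.0)

    def test_requires_cmol_normalization(self):
        with pytest.raises(ValueError):
            battley_formation_energy(parse_formula("C6H12O6"))

    def test_transformed_convention(self, yeast_biomass, table):
        chem = battley_formation_energy(yeast_biomass)
        trans = battley_formation_energy(yeast_biomass, table.conditions)
        expected = legendre_transform(chem, yeast_biomass["H"], 0.0, table.conditions)
        assert trans == pytest.approx(expected, abs=1e-9)


class TestAtpProductionEfficiency:
    def test_full_respiration_efficiency(self):
        # 2.92 mol ATP per C-mol against a -488 kJ/C-mol gradient -> 28 %
        eta = atp_production_efficiency(2.92, -488.0)
        assert round(100 * eta) == 28

    def test_zero_yield(self):
        assert atp_production_efficiency(0.0, -123.4) == 0.0

    def test_lactate_fermentation_efficiency(self, table):
        # 2 ATP/glucose against the vendored glucose -> 2 lactate energy
        ferm = ConversionStoichiometry({"glc": -1 / 6, "lac": 1 / 3}, basis="per_cmol_substrate")
        dg = standard_reaction_energy(ferm, table)
        eta = atp_production_efficiency(1 / 3, dg)
        # ~43 % in the reference estimate; the vendored table's formation
        # energies put it a couple of points higher
        assert 0.38 <= eta <= 0.50

    def test_positive_gradient_rejected(self):
        with pytest.raises(ValueError):
            atp_production_efficiency(1.0, 10.0)

    def test_second_law_violation_warns(self):
        with pytest.warns(UserWarning, match="second law"):
            atp_production_efficiency(10.0, -46.5)


def test_conditions_default_reference_state():
    cond = ThermoConditions()
    assert (cond.temperature, cond.pH, cond.pMg, cond.ionic_strength) == (298.15, 7.4, 3.0, 0.25)
    with pytest.raises(ValueError):
        ThermoConditions(temperature=-1)
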