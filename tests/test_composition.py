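import pytest
from hypothesis import given, settings, strategies as st

from anacat.composition import (
    ElementalComposition,
    FormulaError,
    degree_of_reduction,
    ideal_anabolic_stoichiometry,
    max_theoretical_yield,
    parse_formula,
    read_compound_registry,
    write_compound_registry,
)
from oracles import combustion_oxygen_demand

ECOLI_BIOMASS = "CH1.811O0.503N0.258P0.022S0.006-0.018"
YEAST_BIOMASS = "CH1.8243O0.6589N0.1557P0.0055S0.0022"


class TestParseFormula:
    @pytest.mark.parametrize(
        "text, counts, charge",
        [
            ("CH2O", {"C": 1, "H": 2, "O": 1}, 0.0),
            ("CH1.79O0.57N0.15", {"C": 1, "H": 1.79, "O": 0.57, "N": 0.15}, 0.0),
            ("C6H12O6", {"C": 6, "H": 12, "O": 6}, 0.0),
            ("HPO4-2", {"H": 1, "P": 1, "O": 4}, -2.0),
            ("SO4-2", {"S": 1, "O": 4}, -2.0),
            ("SO4^2-", {"S": 1, "O": 4}, -2.0),
            ("NH4+", {"N": 1, "H": 4}, 1.0),
            (ECOLI_BIOMASS, {"C": 1, "H": 1.811, "O": 0.503, "N": 0.258, "P": 0.022, "S": 0.006}, -0.018),
        ],
    )
    def test_grammar(self, text, counts, charge):
        comp = parse_formula(text)
        assert comp.counts == pytest.approx(counts)
        assert comp.charge == pytest.approx(charge)

    @pytest.mark.parametrize("bad", ["", "Xe2O", "CH1..2", "C6H12O6junk?", "2CO"])
    def test_malformed(self, bad):
        with pytest.raises(FormulaError):
            parse_formula(bad)

    def test_normalize_per_cmol(self):
        glc = parse_formula("C6H12O6").normalize_per_cmol()
        assert glc.counts == pytest.approx({"C": 1, "H": 2, "O": 1})
        assert glc.is_cmol_normalized
        with pytest.raises(FormulaError):
            parse_formula("H2O").normalize_per_cmol()

    def test_formula_round_trip(self):
        for text in ["CH2O", YEAST_BIOMASS, ECOLI_BIOMASS]:
            comp = parse_formula(text)
            again = parse_formula(comp.formula())
            assert again.counts == pytest.approx(comp.counts, abs=1e-9)
            assert again.charge == pytest.approx(comp.charge)

    def test_registry_round_trip(self, tmp_path):
        reg = {"glc": parse_formula("C6H12O6", label="glucose"),
               "bio": parse_formula(ECOLI_BIOMASS, label="biomass")}
        path = tmp_path / "compounds.tsv"
        write_compound_registry(reg, path)
        back = read_compound_registry(path)
        assert set(back) == set(reg)
        for cid in reg:
            assert back[cid].counts == pytest.approx(reg[cid].counts)
            assert back[cid].charge == pytest.approx(reg[cid].charge)


class TestDegreeOfReduction:
    def test_reference_compounds(self):
        assert degree_of_reduction(parse_formula("CO2")) == pytest.approx(0.0)
        assert degree_of_reduction(parse_formula("CH2O")) == pytest.approx(4.0)

    def test_yeast_genome_scale_biomass(self):
        gamma = degree_of_reduction(parse_formula(YEAST_BIOMASS))
        assert round(gamma, 3) == 4.080

    def test_ecoli_genome_scale_biomass(self):
        # the published rounding of the same composition is 4.193
        gamma = degree_of_reduction(parse_formula(ECOLI_BIOMASS))
        assert abs(gamma - 4.193) <= 0.005

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            degree_of_reduction(parse_formula("C6H12O6"))

    @pytest.mark.parametrize("formula", ["CH2O", "CH3O0.5", "CH1.79O0.57N0.15", "CH4"])
    def test_matches_combustion_electron_balance(self, formula):
        """gamma/4 must equal the O2 demand of combustion (element balances)."""
        comp = parse_formula(formula)
        assert degree_of_reduction(comp) == pytest.approx(
            4.0 * combustion_oxygen_demand(comp), abs=1e-12
        )

    @settings(derandomize=True, max_examples=50)
    @given(
        h=st.floats(0, 3), o=st.floats(0, 2), n=st.floats(0, 0.5),
        el=st.sampled_from(["H", "O", "N", "P", "S"]), delta=st.floats(0.01, 0.5),
    )
    def test_linear_in_each_element(self, h, o, n, el, delta):
        from anacat.composition import REDUCTION_DEGREE_WEIGHTS

        base = ElementalComposition({"C": 1, "H": h, "O": o, "N": n})
        bumped = ElementalComposition(dict(base.counts) | {el: base[el] + delta})
        diff = degree_of_reduction(bumped) - degree_of_reduction(base)
        assert diff == pytest.approx(REDUCTION_DEGREE_WEIGHTS[el] * delta, abs=1e-9)


class TestMaxTheoreticalYield:
    # all eight organism x substrate pairs of the published comparison
    @pytest.mark.parametrize(
        "substrate_formula, biomass_formula, expected",
        [
            ("C6H12O6", ECOLI_BIOMASS, 0.954),
            ("C5H10O5", ECOLI_BIOMASS, 0.954),
            ("C5H6O5", ECOLI_BIOMASS, 0.763),
            ("C3H4O3", ECOLI_BIOMASS, 0.795),
            ("C6H12O6", YEAST_BIOMASS, 0.980),
            ("C5H10O5", YEAST_BIOMASS, 0.980),
            ("C5H6O5", YEAST_BIOMASS, 0.784),
            ("C3H4O3", YEAST_BIOMASS, 0.817),
        ],
    )
    def test_organism_substrate_pairs(self, substrate_formula, biomass_formula, expected):
        gs = degree_of_reduction(parse_formula(substrate_formula).normalize_per_cmol())
        gx = degree_of_reduction(parse_formula(biomass_formula))
        assert round(max_theoretical_yield(gs, gx), 3) == expected

    def test_boundary_and_cap(self):
        assert max_theoretical_yield(4.2, 4.2) == 1.0
        assert max_theoretical_yield(5.0, 4.2) == 1.0

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            max_theoretical_yield(0.0, 4.2)

    @settings(derandomize=True, max_examples=50)
    @given(gs=st.floats(0.5, 6), gx1=st.floats(0.5, 8), gx2=st.floats(0.5, 8))
    def test_bounded_and_monotone(self, gs, gx1, gx2):
        y1, y2 = max_theoretical_yield(gs, gx1), max_theoretical_yield(gs, gx2)
        assert y1 <= 1.0 and y2 <= 1.0
        if gs < gx1 < gx2:
            assert y1 > y2


class TestIdealAnabolicStoichiometry:
    def test_yeast_on_glucose(self, glucose_cmol, yeast_biomass):
        ana = ideal_anabolic_stoichiometry(glucose_cmol, yeast_biomass)
        assert ana.b1 == pytest.approx(1.05)
        assert ana.b2 == pytest.approx(0.15)
        assert ana.b3 == pytest.approx(0.05)
        assert ana.b4 == pytest.approx(0.38)
        residuals = ana.element_residuals()
        assert all(abs(r) < 1e-9 for r in residuals.values())

    def test_substrate_equals_biomass(self, glucose_cmol):
        ana = ideal_anabolic_stoichiometry(glucose_cmol, glucose_cmol)
        assert (ana.b1, ana.b2, ana.b3) == pytest.approx((1.0, 0.0, 0.0))

    def test_genome_scale_biomass_via_yield(self, glucose_cmol):
        # P/S enter through the degree of reduction only: b1 = 1/Y_max
        ana = ideal_anabolic_stoichiometry(glucose_cmol, parse_formula(YEAST_BIOMASS))
        assert ana.b1 == pytest.approx(1.020, abs=5e-4)

    def test_redox_balance_restated(self, glucose_cmol, yeast_biomass):
        ana = ideal_anabolic_stoichiometry(glucose_cmol, yeast_biomass)
        gs = degree_of_reduction(glucose_cmol)
        gx = degree_of_reduction(yeast_biomass)
        assert ana.b1 * gs == pytest.approx(gx, abs=1e-9)

    def test_more_reduced_substrate_rejected(self, yeast_biomass):
        methanol_like = parse_formula("CH4O")  # gamma = 6 > gamma_X
        with pytest.raises(ValueError, match="more reduced"):
            ideal_anabolic_stoichiometry(methanol_like, yeast_biomass)

    @settings(derandomize=True, max_examples=50)
    @given(a=st.floats(1.5, 2.1), b=st.floats(0.35, 0.8), c=st.floats(0.0, 0.3))
    def test_balances_close_for_chon_biomass(self, glucose_cmol, a, b, c):
        biomass = ElementalComposition({"C": 1, "H": a, "O": b, "N": c})
        gx = degree_of_reduction(biomass)
        if gx < 4.0 or gx <= 0:
            return
        ana = ideal_anabolic_stoichiometry(glucose_cmol, biomass)
        assert all(abs(r) < 1e-9 for r in ana.element_residuals().values())
        assert min(ana.b1, ana.b2, ana.b3) >= 0
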