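"""Measurement-to-constraint pipeline: rates, normalization, carbon closure."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glymal.flux_solver import pfba
from glymal.rate_constraints import (
    ScenarioConstraints,
    SpecificRates,
    TimeCourse,
    biomass_carbon,
    build_scenario,
    builtin_table1_scenarios,
    carbon_closure,
    normalize_to_glycerol,
    specific_rates,
)
from glymal.stoich_model import Metabolite, Reaction, StoichModel


class TestSpecificRates:
    def test_flask_glycerol_uptake_hand_arithmetic(self):
        """13.06 -> 4.72 g/L over 24 h at mean 0.5 g CDW/L: -7.55 mmol/gCDW/h."""
        tc = TimeCourse(
            times=[0.0, 24.0],
            biomass=[0.4, 0.6],  # arithmetic mean 0.5
            concentrations={"glycerol": [13.06, 4.72]},
        )
        sr = specific_rates(tc, (0.0, 24.0))
        expect = -1000.0 * (13.06 - 4.72) / (92.09 * 24.0 * 0.5)
        assert sr.rates["glycerol"] == pytest.approx(expect)
        assert sr.rates["glycerol"] == pytest.approx(-7.55, abs=0.01)

    def test_constant_concentrations_give_zero_rates(self):
        tc = TimeCourse(
            times=[0.0, 24.0],
            biomass=[0.5, 0.5],
            concentrations={"glycerol": [10.0, 10.0], "malate": [2.0, 2.0]},
        )
        sr = specific_rates(tc, (0.0, 24.0))
        assert all(q == 0.0 for q in sr.rates.values())
        assert sr.growth_rate == 0.0

    def test_unsampled_interval_errors(self):
        tc = TimeCourse(times=[0.0, 24.0], biomass=[0.5, 0.5],
                        concentrations={"glycerol": [10.0, 5.0]})
        with pytest.raises(ValueError, match="not a sampled time"):
            specific_rates(tc, (0.0, 12.0))

    def test_zero_biomass_errors(self):
        tc = TimeCourse(times=[0.0, 24.0], biomass=[0.0, 0.5],
                        concentrations={"glycerol": [10.0, 5.0]})
        with pytest.raises(ValueError, match="biomass"):
            specific_rates(tc, (0.0, 24.0))

    def test_times_must_increase(self):
        with pytest.raises(ValueError):
            TimeCourse(times=[0.0, 0.0], biomass=[0.5, 0.5],
                       concentrations={"glycerol": [1.0, 1.0]})


class TestNormalization:
    def test_scaling_to_minus_twenty(self):
        sr = SpecificRates({"glycerol": -7.55, "malate": 4.00}, 0.1, (0, 24))
        out = normalize_to_glycerol(sr)
        assert out.rates["glycerol"] == -20.0
        assert out.rates["malate"] == pytest.approx(4.00 * 20 / 7.55)
        assert out.rates["malate"] == pytest.approx(10.60, abs=0.01)
        assert out.growth_rate == pytest.approx(0.1 * 20 / 7.55)

    def test_already_normalized_is_identity(self):
        sr = SpecificRates({"glycerol": -20.0, "malate": 0.0}, 0.2, (0, 24))
        out = normalize_to_glycerol(sr)
        assert out.rates == {"glycerol": -20.0, "malate": 0.0}
        assert out.growth_rate == pytest.approx(0.2)

    def test_zero_glycerol_rate_errors(self):
        sr = SpecificRates({"glycerol": 0.0}, 0.0, (0, 24))
        with pytest.raises(ValueError, match="zero"):
            normalize_to_glycerol(sr)

    @given(
        q_gly=st.floats(-50.0, -0.5),
        q_mal=st.floats(-5.0, 20.0),
        q_ac=st.floats(0.0, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_ratios_preserved(self, q_gly, q_mal, q_ac):
        sr = SpecificRates(
            {"glycerol": q_gly, "malate": q_mal, "acetate": q_ac}, 0.1, (0, 24)
        )
        out = normalize_to_glycerol(sr)
        assert out.rates["malate"] / out.rates["glycerol"] == pytest.approx(
            q_mal / q_gly, rel=1e-9, abs=1e-12
        )
        assert out.rates["acetate"] / out.rates["glycerol"] == pytest.approx(
            q_ac / q_gly, rel=1e-9, abs=1e-12
        )


class TestBiomassCarbon:
    def test_core_biomass_carbon_in_expected_band(self, core_model):
        bc = biomass_carbon(core_model)
        assert 40.0 <= bc <= 45.0

    def test_toy_biomass(self):
        model = StoichModel(
            [Metabolite("a_c", compartment="c", formula={"C": 1}),
             Metabolite("x_c", compartment="c", formula={})],
            [Reaction("BIOMASS_toy", {"a_c": -2.0, "x_c": 1.0},
                      lower_bound=0, upper_bound=10)],
        )
        assert biomass_carbon(model) == pytest.approx(2.0)

    def test_missing_biomass_reaction_errors(self):
        model = StoichModel(
            [Metabolite("a_c", compartment="c", formula={"C": 1})],
            [Reaction("EX_a_c", {"a_c": -1.0}, lower_bound=-10, upper_bound=0)],
        )
        with pytest.raises(ValueError, match="biomass"):
            biomass_carbon(model)


class TestCarbonClosure:
    def test_perfectly_closed_scenario(self):
        bal = carbon_closure(
            {"glycerol": -20.0, "malate": 15.0, "acetate": 0.0,
             "succinate": 0.0, "biomass": 0.0},
            biomass_c=42.6,
        )
        assert bal.c_in == pytest.approx(60.0)
        assert bal.c_out == pytest.approx(60.0)
        assert bal.closure == pytest.approx(1.0)
        assert bal.co2_compensation == pytest.approx(0.0)

    def test_optimized_scenario_net_co2_uptake(self, core_model):
        """Optimized strain: closure ~1.05, compensation a net CO2 uptake ~3."""
        bc = biomass_carbon(core_model)
        bal = carbon_closure(
            {"glycerol": -20.0, "malate": 12.79, "acetate": 2.29,
             "succinate": 0.21, "biomass": 0.15},
            biomass_c=bc,
        )
        assert bal.closure == pytest.approx(1.05, abs=0.05)
        assert bal.co2_compensation == pytest.approx(-3.13, abs=0.5)

    def test_parental_scenario_large_co2_outflow(self, core_model):
        bc = biomass_carbon(core_model)
        bal = carbon_closure(
            {"glycerol": -20.0, "malate": -0.11, "acetate": 1.49,
             "succinate": 3.10, "biomass": 0.48},
            biomass_c=bc,
        )
        assert bal.closure == pytest.approx(0.61, abs=0.05)
        assert bal.co2_compensation == pytest.approx(24.59, abs=1.0)
        # consumed malate counts as inflow carbon
        assert bal.c_in == pytest.approx(60.0 + 4 * 0.11)

    def test_compensation_restores_balance_exactly(self, core_model):
        bc = biomass_carbon(core_model)
        for sc in builtin_table1_scenarios():
            bal = carbon_closure(sc.fixed_fluxes, bc)
            assert (bal.c_out + bal.co2_compensation) / bal.c_in == pytest.approx(
                1.0, abs=1e-12
            )

    def test_missing_species_listed(self):
        with pytest.raises(KeyError, match="succinate"):
            carbon_closure({"glycerol": -20.0, "malate": 1.0, "acetate": 0.0,
                            "biomass": 0.1}, 42.0)


class TestBuildScenario:
    def test_all_builtin_scenarios_are_feasible(self, m4_model, table1_scenarios):
        for sc in table1_scenarios:
            state = pfba(build_scenario(m4_model, sc))
            assert state.optimal, sc.label

    def test_contradictory_constraints_report_infeasible(self, m4_model):
        sc = ScenarioConstraints(
            "impossible", "pure", "flask",
            {"glycerol": -20.0, "malate": 100.0, "acetate": 0.0,
             "succinate": 0.0, "biomass": 0.0},
        )
        state = pfba(build_scenario(m4_model, sc))
        assert state.status == "infeasible"

    def test_o2_left_free_by_default(self, m4_model, table1_scenarios):
        built = build_scenario(m4_model, table1_scenarios[0])
        rxn = built.reactions["EX_o2_e"]
        assert rxn.lower_bound == -1000.0 and rxn.upper_bound == 1000.0

    def test_fix_o2_mode(self, m4_model, table1_scenarios):
        built = build_scenario(m4_model, table1_scenarios[0], fix_o2=-35.5)
        rxn = built.reactions["EX_o2_e"]
        assert rxn.lower_bound == rxn.upper_bound == -35.5


class TestBuiltinScenarios:
    def test_five_published_scenarios(self, table1_scenarios):
        assert len(table1_scenarios) == 5
        labels = {(s.label, s.glycerol_grade, s.scale) for s in table1_scenarios}
        assert ("M4-iclR", "pure", "flask") in labels
        assert ("M4-iclR/pck-glpK", "crude", "bioreactor") in labels

    def test_every_scenario_normalized_to_minus_twenty(self, table1_scenarios):
        for sc in table1_scenarios:
            assert sc.fixed_fluxes["glycerol"] == -20.0

    def test_optimized_malate_flux(self, scenario_by_label):
        sc = scenario_by_label("M4-iclR/pck-glpK", "crude", "bioreactor")
        assert sc.fixed_fluxes["malate"] == 12.79
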