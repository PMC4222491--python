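"""Elasticities, control coefficients and the control theorems."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hiersd as hs
from hiersd.coefficients import local_gene_control


class TestDirectElasticity:
    @pytest.mark.parametrize(
        "process, variable, expected",
        [
            ("supply", "ADP", 1.0),     # first order in its substrate
            ("supply", "E", 1.0),       # proportional to the enzyme
            ("demand", "ADP", -1.0),    # -ADP/(C-ADP) along the moiety at ADP=C/2
            ("gene_E.degradation", "E", 0.5),  # k_b E/(k_b E + k_0) = 0.5
            ("gene_E.synthesis", "ADP", 1.0),
            ("gene_E.synthesis", "E", 0.0),    # synthesis independent of E
        ],
    )
    def test_atp_module_elasticities(self, atp, atp_ss, process, variable, expected):
        eps = hs.direct_elasticity(atp, atp_ss, process, variable)
        assert eps == pytest.approx(expected, abs=1e-8)

    def test_zero_variable_is_an_explicit_error(self, end_product, end_product_ss):
        with pytest.raises(hs.ModelError, match="undefined"):
            hs.direct_elasticity(end_product, end_product_ss, "demand", "P")

    def test_hill_inhibition_elasticity_matches_closed_form(self, end_product, end_product_ss):
        # d ln(1/(1+x^h))/d ln x = -h x^h/(1+x^h)
        x3 = end_product_ss.state["x3"]
        expected = -2.0 * x3**2 / (1.0 + x3**2)
        eps = hs.direct_elasticity(end_product, end_product_ss, "r1", "x3")
        assert eps == pytest.approx(expected, abs=1e-8)


class TestOverallElasticity:
    def test_indirect_gene_route_adds_to_the_direct_term(self):
        # eps=1, eps_Es^s=1, eps_X^a=1, eps_E^b=0.5, eps_E^a=0 -> 1 + 1*(1/0.5)*1 = 3
        assert hs.overall_elasticity(1.0, 1.0, 1.0, 0.5, 0.0) == pytest.approx(3.0)

    def test_without_gene_expression_the_direct_term_survives(self):
        assert hs.overall_elasticity(-1.7, 1.0, 0.0, 0.5, 0.0) == -1.7

    def test_zero_order_degradation_flags_infinite_indirect_control(self):
        assert math.isinf(hs.overall_elasticity(1.0, 1.0, 1.0, 0.0, 0.0))
        assert math.isinf(local_gene_control(0.0, 0.0))
        assert local_gene_control(0.5) == pytest.approx(2.0)


class TestNumericControlCoefficients:
    def test_enzyme_tracks_demand_perfectly_under_zero_order_degradation(self, atp_integral):
        h = hs.control_coefficient_numeric(atp_integral, "E", "demand")
        assert h == pytest.approx(1.0, abs=1e-6)

    def test_adp_control_by_demand_matches_the_closed_form(self, atp):
        h = hs.control_coefficient_numeric(atp, "ADP", "demand")
        assert h == pytest.approx(0.25, abs=1e-6)

    def test_product_insensitive_first_step_has_full_local_flux_control(
            self, end_product, end_product_ss):
        c1 = hs.control_coefficient_numeric(end_product, "flux:r1", "r1",
                                            scope="local", block="supply",
                                            base=end_product_ss)
        c2 = hs.control_coefficient_numeric(end_product, "flux:r1", "r2",
                                            scope="local", block="supply",
                                            base=end_product_ss)
        assert c1 == pytest.approx(1.0, abs=1e-6)
        assert c2 == pytest.approx(0.0, abs=1e-6)

    def test_local_gene_block_control_of_enzyme_level(self, atp, atp_ss):
        # c_a^Es = 1/(eps_E^b - eps_E^a) = 1/0.5 = 2 with ADP clamped
        c = hs.control_coefficient_numeric(atp, "E", "gene_E.synthesis",
                                           scope="local", block={"a", "b"},
                                           base=atp_ss)
        assert c == pytest.approx(2.0, abs=1e-5)

    @pytest.mark.parametrize("fixture", ["atp", "end_product"])
    def test_summation_theorems_metabolic_scope(self, fixture, request):
        model = request.getfixturevalue(fixture)
        base = hs.find_steady_state(model)
        target_x = model.designations["controlled_variables"][0]
        procs = [r.id for r in model.reactions]
        cx = sum(hs.control_coefficient_numeric(model, target_x, p,
                                                scope="metabolic", base=base)
                 for p in procs)
        cj = sum(hs.control_coefficient_numeric(model, "flux:demand", p,
                                                scope="metabolic", base=base)
                 for p in procs)
        assert cx == pytest.approx(0.0, abs=1e-4)
        assert cj == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("fixture", ["atp", "end_product"])
    def test_hierarchical_concentration_control_sums_to_zero(self, fixture, request):
        model = request.getfixturevalue(fixture)
        base = hs.find_steady_state(model)
        target = model.designations["controlled_variables"][0]
        supply = "supply" if fixture == "atp" else "r1"
        h_s = hs.control_coefficient_numeric(model, target, supply, base=base)
        h_d = hs.control_coefficient_numeric(model, target, "demand", base=base)
        assert h_s + h_d == pytest.approx(0.0, abs=1e-4)

    @pytest.mark.parametrize("fixture", ["atp", "end_product", "initial_product"])
    def test_gene_expression_regulation_increases_robustness(self, fixture, request):
        # |H| with gene regulation active <= |C| with gene expression frozen
        model = request.getfixturevalue(fixture)
        base = hs.find_steady_state(model)
        target = model.designations["controlled_variables"][0]
        process = "demand" if fixture != "initial_product" else "src"
        h = hs.control_coefficient_numeric(model, target, process, base=base)
        frozen = model.copy()
        for sp in frozen.species:
            sp.initial_value = base.state[sp.id]
            if sp.role in ("enzyme", "mrna"):
                sp.clamped = True
        c = hs.control_coefficient_numeric(frozen, target, process)
        assert abs(h) <= abs(c) + 1e-6

    def test_fragility_monotone_in_first_order_degradation(self):
        # recalibrated ATP module: F non-decreasing in k_b, saturating below 0.5
        kbs = [0.0, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0]
        fs = []
        for kb in kbs:
            model = hs.make_atp_module(k_b=kb)
            fs.append(hs.control_coefficient_numeric(model, "ADP", "demand"))
        assert all(b >= a - 1e-6 for a, b in zip(fs, fs[1:]))
        assert all(f < 0.5 for f in fs)


class TestTheoremShortcuts:
    def test_supply_demand_coefficients_from_elasticities(self):
        out = hs.supply_demand_from_elasticities(-2.0, 1.0)
        assert out["C_s_x"] == pytest.approx(1.0 / 3.0)
        assert out["C_d_J"] == pytest.approx(2.0 / 3.0)

    def test_strong_feedback_puts_flux_control_on_the_demand(self):
        out = hs.supply_demand_from_elasticities(-1000.0, 1.0)
        assert out["C_d_J"] == pytest.approx(1.0, abs=2e-3)

    def test_singular_supply_demand_is_an_error(self):
        with pytest.raises(hs.ModelError, match="singular"):
            hs.supply_demand_from_elasticities(1.0, 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(eps_s=st.floats(-50.0, -0.01), eps_d=st.floats(0.01, 50.0))
    def test_summation_identities_hold_exactly(self, eps_s, eps_d):
        out = hs.supply_demand_from_elasticities(eps_s, eps_d)
        assert out["C_s_J"] + out["C_d_J"] == pytest.approx(1.0, abs=1e-12)
        assert out["C_s_x"] + out["C_d_x"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "pairs, expected",
        [
            ([(0.0, 1.0)], [1.0, 0.0]),      # product-insensitive first step
            ([(-1.0, 1.0)], [0.5, 0.5]),     # symmetric chain
        ],
    )
    def test_local_chain_flux_control_examples(self, pairs, expected):
        c = hs.local_chain_flux_control(pairs)
        assert np.allclose(c, expected, atol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-5.0, -0.1), st.floats(0.1, 5.0)),
                    min_size=1, max_size=5))
    def test_local_chain_coefficients_sum_to_one(self, pairs):
        c = hs.local_chain_flux_control(pairs)
        assert np.sum(c) == pytest.approx(1.0, abs=1e-10)

    def test_singular_chain_cites_the_condition_number(self):
        with pytest.raises(hs.ModelError, match="condition"):
            hs.local_chain_flux_control([(0.0, 0.0)])

    def test_hierarchical_coefficient_matches_the_atp_closed_form(self):
        # ATP orientation: eps_X^s=1, eps_X^d=-1, indirect term 1*1/0.5 = 2
        h_s, h_d = hs.hierarchical_supply_demand_coefficient(
            eps_x_s=1.0, eps_x_d=-1.0, eps_es_s=1.0, eps_x_a=1.0,
            eps_es_a=0.0, eps_es_b=0.5)
        assert h_d == pytest.approx(0.25)
        assert h_s == pytest.approx(-0.25)

    def test_zero_order_turnover_zeroes_the_hierarchical_control(self):
        h_s, h_d = hs.hierarchical_supply_demand_coefficient(
            eps_x_s=-1.0, eps_x_d=1.0, eps_es_s=1.0, eps_x_a=-1.0,
            eps_es_a=0.0, eps_es_b=0.0)
        assert h_s == 0.0 and h_d == 0.0

    def test_without_gene_terms_it_degenerates_to_the_metabolic_result(self):
        h_s, _ = hs.hierarchical_supply_demand_coefficient(
            eps_x_s=-2.0, eps_x_d=1.0, eps_es_s=1.0, eps_x_a=0.0,
            eps_es_a=0.0, eps_es_b=0.5)
        assert h_s == pytest.approx(hs.supply_demand_from_elasticities(-2.0, 1.0)["C_s_x"])


class TestRobustnessFragility:
    def test_zero_order_degradation_gives_zero_fragility_infinite_robustness(self, atp_integral):
        r, f = hs.robustness_and_fragility(atp_integral, "ADP", "demand")
        assert abs(f) < 1e-8
        assert math.isinf(r)

    def test_canonical_set_quarter_fragility_fourfold_robustness(self, atp):
        r, f = hs.robustness_and_fragility(atp, "ADP", "demand")
        assert f == pytest.approx(0.25, abs=1e-6)
        assert r == pytest.approx(4.0, rel=1e-5)
        assert f * r == pytest.approx(1.0, rel=1e-9)
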