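"""Integration, steady-state solving and step-perturbation experiments."""

import numpy as np
import pytest

import hiersd as hs
from hiersd.model_core import (
    GeneExpressionUnit,
    PathwayModel,
    RateLaw,
    Reaction,
    Species,
)


class TestSimulate:
    def test_fixed_point_stays_constant(self, atp, atp_ss):
        traj = hs.simulate(atp, initial_state=atp_ss, t_end=50.0)
        rel = np.abs(traj.states - traj.states[0]) / np.maximum(np.abs(traj.states[0]), 1e-30)
        assert np.max(rel) < 1e-8

    def test_moiety_total_conserved_along_trajectory(self, atp):
        y0 = {"ADP": 0.9, "ATP": 0.1, "E": 0.3}
        traj = hs.simulate(atp, initial_state=y0, t_end=80.0)
        i = traj.species_ids.index("ADP")
        j = traj.species_ids.index("ATP")
        total = traj.states[:, i] + traj.states[:, j]
        assert np.max(np.abs(total - 1.0)) < 1e-8

    def test_event_produces_a_post_step_transient(self, end_product):
        traj = hs.simulate(end_product, t_end=150.0,
                           events=[(50.0, "reactions.demand.activity", 0.2)])
        assert traj.event_times == [50.0]
        k = traj.species_ids.index("x3")
        pre = traj.states[traj.times <= 50.0, k]
        post = traj.states[traj.times > 55.0, k]
        assert np.max(np.abs(pre - pre[0])) < 1e-6   # sat at steady state
        assert abs(post[-1] - pre[0]) > 1e-3         # settled elsewhere

    def test_ideal_integral_system_returns_to_pre_event_values(self, end_product_integral):
        traj = hs.simulate(end_product_integral, t_end=400.0,
                           events=[(50.0, "reactions.demand.activity", 0.2)])
        for sid in ("x3", "mR"):
            k = traj.species_ids.index(sid)
            assert traj.states[-1, k] == pytest.approx(traj.states[0, k], rel=1e-6)

    def test_invalid_inputs_rejected(self, atp):
        with pytest.raises(ValueError):
            hs.simulate(atp, t_end=-1.0)
        with pytest.raises(ValueError):
            hs.simulate(atp, initial_state={"ADP": -0.5, "ATP": 0.5, "E": 1.0}, t_end=1.0)


class TestFindSteadyState:
    def test_atp_canonical_steady_state(self, atp_ss):
        assert atp_ss.state["ADP"] == pytest.approx(0.5, abs=1e-9)
        assert atp_ss.state["E"] == pytest.approx(1.0, abs=1e-9)
        assert atp_ss.stable
        assert atp_ss.fluxes["supply"] == pytest.approx(atp_ss.fluxes["demand"], abs=1e-9)

    def test_zero_order_degradation_pins_the_controlled_variable(self):
        # k_b=0, k_0=0.5: enzyme balance k_a*ADP = k_0 pins ADP = 0.5 exactly
        model = hs.make_atp_module(k_b=0.0)
        ss = hs.find_steady_state(model, guess={"ADP": 0.8, "ATP": 0.2, "E": 0.4})
        assert ss.state["ADP"] == pytest.approx(0.5, abs=1e-9)
        assert ss.state["E"] == pytest.approx(1.0, abs=1e-9)

    def test_clamped_everything_returns_the_clamped_state(self):
        model = PathwayModel(
            species=[Species("A", "metabolite", 1.0, clamped=True),
                     Species("B", "metabolite", 2.0, clamped=True)],
            reactions=[Reaction("r", RateLaw("mass_action", {"k": 1.0}),
                                substrates=[("A", 1.0)], products=[("B", 1.0)])],
            partition={"r": "supply"},
        )
        ss = hs.find_steady_state(model)
        assert ss.residual_norm == 0.0
        assert ss.state == {"A": 1.0, "B": 2.0}

    def test_relaxation_and_newton_routes_agree(self, atp):
        guess = {"ADP": 0.7, "ATP": 0.3, "E": 0.5}
        ss_relax = hs.find_steady_state(atp, guess=guess, method="relax",
                                        relax_tol=1e-11)
        ss_newton = hs.find_steady_state(atp, guess=guess, method="newton")
        for sid in ("ADP", "E"):
            assert ss_relax.state[sid] == pytest.approx(ss_newton.state[sid], rel=1e-8)

    def test_divergent_model_reports_divergence(self):
        # constant production with no consumption grows without bound
        model = PathwayModel(
            species=[Species("SRC", "metabolite", 1.0, clamped=True),
                     Species("A", "metabolite", 1.0)],
            reactions=[Reaction("feed", RateLaw("mass_action", {"k": 1.0}),
                                substrates=[("SRC", 1.0)], products=[("A", 1.0)])],
            partition={"feed": "supply"},
        )
        with pytest.raises((hs.DivergenceError, hs.ConvergenceError)):
            hs.find_steady_state(model, t_budget=1e4)


class TestEndProductIntersection:
    def test_intersection_matches_full_steady_state(self):
        model = hs.make_end_product_operon(k_ED=0.2, explicit_mrna=False,
                                           k_proteolysis0=0.0)
        ss = hs.find_steady_state(model)
        x = hs.solve_end_product_intersection(model)
        assert x == pytest.approx(ss.state["x3"], abs=1e-8)

    def test_linear_case_recovers_the_closed_form(self):
        # f1 = k1*S (product-insensitive), g = const, linear demand:
        # x = k_g*k1*S / (k_ED * k_dem)
        k1, k_g, k_ed, k_dem = 0.8, 0.3, 0.2, 2.0
        model = PathwayModel(
            species=[Species("S", "metabolite", 1.0, clamped=True),
                     Species("x", "metabolite", 0.5),
                     Species("P", "metabolite", 0.0, clamped=True),
                     Species("E1", "enzyme", 1.0)],
            reactions=[
                Reaction("r1", RateLaw("mass_action", {"k": k1}),
                         substrates=[("S", 1.0)], products=[("x", 1.0)],
                         enzyme="E1"),
                Reaction("demand", RateLaw("linear_demand", {"k": k_dem}),
                         substrates=[("x", 1.0)], products=[("P", 1.0)]),
            ],
            gene_units=[GeneExpressionUnit(
                id="g1", enzyme_targets=["E1"],
                transcription=RateLaw("constant", {"k": k_g}),
                regulator="x", k_proteolysis1=k_ed)],
            partition={"r1": "supply", "demand": "demand",
                       "g1.synthesis": "a", "g1.degradation": "b"},
        )
        x = hs.solve_end_product_intersection(model)
        assert x == pytest.approx(k_g * k1 * 1.0 / (k_ed * k_dem), abs=1e-10)

    def test_root_is_unique_across_brackets(self):
        model = hs.make_end_product_operon(k_ED=0.2, explicit_mrna=False,
                                           k_proteolysis0=0.0)
        x1 = hs.solve_end_product_intersection(model, bracket=(1e-6, 5.0))
        x2 = hs.solve_end_product_intersection(model, bracket=(0.5, 50.0))
        assert x1 == pytest.approx(x2, abs=1e-10)

    def test_template_mismatch_is_rejected(self, atp):
        with pytest.raises(hs.ModelError, match="template"):
            hs.solve_end_product_intersection(atp)


class TestIntermediateEnzymeIndependence:
    def test_end_metabolite_independent_of_middle_reaction_kinetics(self, end_product):
        # product-insensitive first step: x3 and J depend only on the first
        # and last steps, not on the intermediate conversions
        base = hs.find_steady_state(end_product)
        fast = end_product.copy()
        fast.get_reaction("r2").rate_law.parameters["k"] *= 2.0
        ss2 = hs.find_steady_state(fast)
        assert ss2.state["x3"] == pytest.approx(base.state["x3"], rel=1e-8)
        assert ss2.fluxes["demand"] == pytest.approx(base.fluxes["demand"], rel=1e-8)


class TestStepPerturbation:
    def test_zero_order_variant_adapts_perfectly_and_enzyme_tracks(self):
        model = hs.make_atp_module(k_b=0.0)
        res = hs.apply_step_perturbation(model, "reactions.demand.k", 0.2,
                                         include_trajectory=False)
        assert abs(res.deviations["ADP"]) < 1e-6
        assert res.deviations["E"] == pytest.approx(0.2, abs=1e-6)

    def test_leaky_integration_attenuates_but_does_not_cancel(self, atp):
        res = hs.apply_step_perturbation(atp, "reactions.demand.k", 0.2,
                                         include_trajectory=False)
        frozen = atp.copy()
        for sp in frozen.species:
            if sp.role in ("enzyme", "mrna"):
                sp.clamped = True
        res_frozen = hs.apply_step_perturbation(frozen, "reactions.demand.k", 0.2,
                                                include_trajectory=False)
        dev = res.deviations["ADP"]
        assert 0.0 < dev < res_frozen.deviations["ADP"]

    def test_zero_relative_change_gives_zero_deviations(self, atp):
        res = hs.apply_step_perturbation(atp, "reactions.demand.k", 0.0,
                                         include_trajectory=False)
        assert all(abs(d) < 1e-9 for d in res.deviations.values())

    def test_total_removal_of_a_rate_is_rejected(self, atp):
        with pytest.raises(ValueError):
            hs.apply_step_perturbation(atp, "reactions.demand.k", -1.0)
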