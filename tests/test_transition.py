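"""Trade-off frontiers, trajectory classification, transition experiments."""

import pytest
from hypothesis import given, settings, strategies as st

from cyanoflux import (ClassificationRules, FluxRange, MetabolicModel,
                       Metabolite, Reaction, TransitionTrajectory,
                       category_counts, classify_trajectory, run_fva, solve_fba,
                       tradeoff_scan, transition_experiment)
from cyanoflux.exceptions import ScenarioError


def traj(growth: FluxRange, production: FluxRange) -> TransitionTrajectory:
    return TransitionTrajectory("R", (1.0, 0.0), (growth, production))


def point(x: float) -> FluxRange:
    return FluxRange(x, x)


class TestClassification:
    @pytest.mark.parametrize("a,b,expected", [
        (point(0.5), point(0.5), "no_change"),
        (point(0.5), point(0.51), "no_change"),          # 2% change
        (point(0.0), point(0.3), "increase_from_zero"),
        (point(0.2), point(0.3), "increase_from_flux"),
        (point(0.3), point(0.2), "decrease_to_flux"),
        (point(0.3), point(0.0), "decrease_to_zero"),
        (point(0.3), point(5e-5), "decrease_to_zero"),   # below product focus
        (point(0.0), point(5e-5), "below_focus"),
        (FluxRange(-2, -1), FluxRange(1, 2), "sign_change"),
        (FluxRange(-1, 2), FluxRange(1, 2), "sign_change"),  # min product < 0
        (point(-0.3), point(-0.2), "decrease_to_flux"),  # magnitudes, not signs
    ])
    def test_rule_table(self, a, b, expected):
        assert classify_trajectory(traj(a, b)) == expected

    def test_sign_change_takes_precedence_over_magnitude(self):
        assert classify_trajectory(
            traj(FluxRange(-1.0, -0.5), FluxRange(0.5, 1.0))) == "sign_change"

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(-5, 5), st.floats(0, 1), st.floats(-5, 5), st.floats(0, 1))
    def test_sign_flip_maps_categories_consistently(self, a, wa, b, wb):
        """Flipping a reversible reaction's direction convention must not change
        the increase/decrease/no-change/sign-change structure."""
        growth, production = FluxRange(a, a + wa), FluxRange(b, b + wb)
        flipped = traj(FluxRange(-(a + wa), -a), FluxRange(-(b + wb), -b))
        assert classify_trajectory(traj(growth, production)) == \
               classify_trajectory(flipped)

    def test_every_trajectory_gets_exactly_one_label(self):
        grid = [point(x) for x in (-1.0, -1e-5, 0.0, 1e-5, 0.2, 1.0)]
        labels = {classify_trajectory(traj(a, b)) for a in grid for b in grid}
        valid = {"sign_change", "increase_from_flux", "increase_from_zero",
                 "decrease_to_flux", "decrease_to_zero", "no_change",
                 "below_focus"}
        assert labels <= valid

    def test_rules_validation(self):
        with pytest.raises(ValueError):
            ClassificationRules(focus_threshold_biomass=0.0)
        with pytest.raises(ValueError):
            ClassificationRules(relative_change_cutoff=1.5)


def seven_reaction_toy() -> MetabolicModel:
    """Hand-enumerable transition toy.

    Uptake 10 of S; two capacity-6 routes to A and B; a reversible shuttle
    A<=>B; growth drains A, production drains B.  At 100% growth the shuttle
    must carry 4 units B->A, at 100% production 4 units A->B: a sign change.
    """
    m = MetabolicModel("toy7")
    for mid in ("s_c", "a_c", "b_c", "p_c"):
        m.add_metabolite(Metabolite(mid, formula={}))
    m.add_reaction(Reaction("EX_s", stoichiometry={"s_c": -1},
                            lower_bound=-10, upper_bound=0, is_exchange=True))
    m.add_reaction(Reaction("R1", stoichiometry={"s_c": -1, "a_c": 1},
                            upper_bound=6))
    m.add_reaction(Reaction("R2", stoichiometry={"s_c": -1, "b_c": 1},
                            upper_bound=6))
    m.add_reaction(Reaction("SH", stoichiometry={"a_c": -1, "b_c": 1},
                            lower_bound=-1000, upper_bound=1000))
    m.add_reaction(Reaction("BIO", stoichiometry={"a_c": -1},
                            upper_bound=1000, pseudo=True))
    m.add_reaction(Reaction("PROD", stoichiometry={"b_c": -1, "p_c": 1}))
    m.add_reaction(Reaction("EX_p", stoichiometry={"p_c": -1},
                            lower_bound=0, upper_bound=1000, is_exchange=True))
    return m


class TestHandEnumeratedToy:
    def endpoint_ranges(self, m, growth_floor):
        step = m.copy()
        step.set_bounds("BIO", growth_floor, 1000.0)
        sol = solve_fba(step, "EX_p", "max")
        return run_fva(step, fixed=[("EX_p", sol.objective_value)])

    def test_category_counts_match_hand_enumeration(self):
        m = seven_reaction_toy()
        mu_max = solve_fba(m, "BIO", "max").objective_value
        assert mu_max == pytest.approx(10.0)
        growth = self.endpoint_ranges(m, mu_max - 1e-9)
        production = self.endpoint_ranges(m, 0.0)
        trajectories = []
        for rid in m.reaction_ids:
            t = TransitionTrajectory(rid, (1.0, 0.0),
                                     (growth[rid], production[rid]))
            t.category = classify_trajectory(t)
            trajectories.append(t)
        by_id = {t.reaction_id: t.category for t in trajectories}
        assert by_id == {
            "EX_s": "no_change", "R1": "no_change", "R2": "no_change",
            "SH": "sign_change", "BIO": "decrease_to_zero",
            "PROD": "increase_from_zero", "EX_p": "increase_from_zero",
        }
        counts = category_counts(trajectories)
        assert counts.as_row() == {
            "sign_change": 1, "increase_from_flux": 0, "increase_from_zero": 2,
            "decrease_to_flux": 0, "decrease_to_zero": 1, "no_change": 3}
        assert counts.total == 7

    def test_shuttle_endpoint_ranges_match_hand_computation(self):
        m = seven_reaction_toy()
        growth = self.endpoint_ranges(m, 10.0 - 1e-9)["SH"]
        production = self.endpoint_ranges(m, 0.0)["SH"]
        assert (growth.min, growth.max) == (pytest.approx(-6), pytest.approx(-4))
        assert (production.min, production.max) == (pytest.approx(4),
                                                    pytest.approx(6))


class TestTradeoffScan:
    def test_endpoints_and_shape(self, ethanol_growth_model):
        frontier = tradeoff_scan(ethanol_growth_model, "ethanol", n_steps=11)
        fractions = [f for f, _ in frontier]
        fluxes = [v for _, v in frontier]
        assert fractions[0] == 1.0 and fractions[-1] == 0.0
        assert fluxes[0] == pytest.approx(0.0, abs=1e-6)   # all resources in growth
        assert fluxes[-1] > 0.5                            # maximal-yield endpoint
        # monotone non-increasing in growth fraction
        assert all(b >= a - 1e-9 for a, b in zip(fluxes, fluxes[1:]))
        # concavity: the frontier lies on/above the endpoint chord everywhere
        v1, v0 = fluxes[0], fluxes[-1]
        for f, v in frontier:
            chord = v0 + f * (v1 - v0)
            assert v >= chord - 1e-9

    def test_single_step_rejected(self, ethanol_growth_model):
        with pytest.raises(ScenarioError):
            tradeoff_scan(ethanol_growth_model, "ethanol", n_steps=1)


@pytest.fixture(scope="module")
def ethanol_trajectories(ethanol_growth_model):
    return transition_experiment(ethanol_growth_model, "ethanol", n_steps=3)


class TestTransitionExperiment:
    def test_partition_property(self, ethanol_trajectories):
        """Every reaction receives exactly one label; focus reactions tally."""
        labels = [t.category for t in ethanol_trajectories]
        assert all(l is not None for l in labels)
        counts = category_counts(ethanol_trajectories)
        n_focus = sum(1 for l in labels if l != "below_focus")
        assert counts.total == n_focus

    def test_heterologous_steps_increase_from_zero(self, ethanol_trajectories):
        by_id = {t.reaction_id: t for t in ethanol_trajectories}
        assert by_id["Bi0001"].category == "increase_from_zero"
        assert by_id["ADH_etoh"].category == "increase_from_zero"
        assert by_id["BIOMASS"].category == "decrease_to_zero"

    def test_atp_wasting_increases_toward_production(self, ethanol_trajectories):
        """Excess ATP must be hydrolyzed in the production-only phenotype."""
        maint = {t.reaction_id: t for t in ethanol_trajectories}["MAINT"]
        assert maint.production_range.midpoint > maint.growth_range.midpoint
        assert maint.category.startswith("increase")

    def test_counts_independent_of_grid_density(self, ethanol_growth_model,
                                                ethanol_trajectories):
        """Classification is endpoint-determined: a denser grid cannot move
        reactions between categories."""
        finer = transition_experiment(ethanol_growth_model, "ethanol", n_steps=4)
        assert category_counts(finer).as_row() == \
               category_counts(ethanol_trajectories).as_row()

    def test_production_endpoint_contains_scenario_optimum(
            self, ethanol_growth_model, ethanol_trajectories):
        from cyanoflux.scenarios import apply_scenario, transition_scenario

        constrained, extra = apply_scenario(ethanol_growth_model,
                                            transition_scenario())
        sol = solve_fba(constrained, "EX_etoh", "max", extra_constraints=extra)
        export = {t.reaction_id: t for t in ethanol_trajectories}["EX_etoh"]
        assert export.production_range.contains(sol.objective_value, tol=1e-6)
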