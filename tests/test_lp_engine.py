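"""FBA/FVA/minimal-active-set behaviour on models small enough to solve by hand."""

import numpy as np
import pytest

from cyanoflux import (LinearConstraint, MetabolicModel, Metabolite, Reaction,
                       build_stoich_matrix, minimal_active_set, run_fva,
                       solve_fba)
from cyanoflux.exceptions import InfeasibleProblem, UnboundedProblem

from conftest import chain_model


def branch_model():
    """Uptake 6 of S; path1 S->P (yield 1), path2 2 S->P (yield 0.5)."""
    m = MetabolicModel("branch")
    m.add_metabolite(Metabolite("s_c", formula={}))
    m.add_metabolite(Metabolite("p_c", formula={}))
    m.add_reaction(Reaction("EX_s", stoichiometry={"s_c": -1},
                            lower_bound=-6, upper_bound=0, is_exchange=True))
    m.add_reaction(Reaction("P1", stoichiometry={"s_c": -1, "p_c": 1}))
    m.add_reaction(Reaction("P2", stoichiometry={"s_c": -2, "p_c": 1}))
    m.add_reaction(Reaction("EX_p", stoichiometry={"p_c": -1},
                            lower_bound=0, upper_bound=1000, is_exchange=True))
    return m


class TestSolveFba:
    def test_bound_limited_chain(self, toy_chain):
        sol = solve_fba(toy_chain, "EX_p", "max")
        assert sol.objective_value == pytest.approx(5.0)
        assert sol["R2"] == pytest.approx(5.0)

    def test_branch_matches_pathway_enumeration(self):
        """The LP optimum equals brute force over the two extreme pathways."""
        m = branch_model()
        # enumerate: route all 6 substrate through each pure pathway
        brute = max(6 / 1, 6 / 2)
        sol = solve_fba(m, "EX_p", "max")
        assert sol.objective_value == pytest.approx(brute)
        assert sol["P1"] == pytest.approx(6.0)
        assert sol["P2"] == pytest.approx(0.0)

    def test_steady_state_residual_tiny(self, ethanol_model):
        from cyanoflux.scenarios import apply_scenario, yield_scenario

        constrained, extra = apply_scenario(ethanol_model, yield_scenario())
        sol = solve_fba(constrained, "EX_etoh", "max", extra_constraints=extra)
        S = build_stoich_matrix(constrained).toarray()
        v = np.array([sol[r.id] for r in constrained.reactions])
        assert np.abs(S @ v).max() <= 1e-9 * max(1.0, np.abs(v).max())

    def test_infeasible_is_raised_not_zeroed(self, toy_chain):
        toy_chain.set_bounds("R1", 6.0, 10.0)  # demands more than uptake allows
        with pytest.raises(InfeasibleProblem):
            solve_fba(toy_chain, "EX_p", "max")

    def test_unbounded_is_raised(self):
        m = MetabolicModel("ub")
        m.add_metabolite(Metabolite("a_c", formula={}))
        m.add_reaction(Reaction("in_", stoichiometry={"a_c": 1},
                                lower_bound=0, upper_bound=np.inf))
        m.add_reaction(Reaction("out", stoichiometry={"a_c": -1},
                                lower_bound=0, upper_bound=np.inf))
        with pytest.raises(UnboundedProblem):
            solve_fba(m, "out", "max")

    def test_extra_constraint_restricts_optimum(self, toy_chain):
        sol = solve_fba(toy_chain, "EX_p", "max",
                        extra_constraints=[LinearConstraint({"R1": 1.0}, "<=", 2.0)])
        assert sol.objective_value == pytest.approx(2.0)

    def test_agrees_with_cobra_glpk(self, ethanol_model):
        """Independent cross-check of the ethanol optimum with cobrapy/GLPK."""
        from cyanoflux.io import _to_cobra
        from cyanoflux.scenarios import apply_scenario, yield_scenario

        constrained, extra = apply_scenario(ethanol_model, yield_scenario())
        assert not extra  # yield mode has no coupling rows
        ours = solve_fba(constrained, "EX_etoh", "max").objective_value
        cm = _to_cobra(constrained)
        cm.objective = cm.reactions.EX_etoh
        theirs = cm.optimize().objective_value
        assert ours == pytest.approx(theirs, rel=1e-6)


class TestRunFva:
    def test_fully_determined_chain_has_point_ranges(self, toy_chain):
        sol = solve_fba(toy_chain, "EX_p", "max")
        ranges = run_fva(toy_chain, fixed=[("EX_p", sol.objective_value)])
        for rng in ranges.values():
            assert rng.max - rng.min <= 1e-6

    def test_parallel_identical_routes_share_total_flux(self):
        m = MetabolicModel("par")
        m.add_metabolite(Metabolite("s_c", formula={}))
        m.add_metabolite(Metabolite("p_c", formula={}))
        m.add_reaction(Reaction("EX_s", stoichiometry={"s_c": -1},
                                lower_bound=-10, upper_bound=0, is_exchange=True))
        for rid in ("Ra", "Rb"):
            m.add_reaction(Reaction(rid, stoichiometry={"s_c": -1, "p_c": 1}))
        m.add_reaction(Reaction("EX_p", stoichiometry={"p_c": -1},
                                lower_bound=0, upper_bound=1000, is_exchange=True))
        sol = solve_fba(m, "EX_p", "max")
        ranges = run_fva(m, fixed=[("EX_p", sol.objective_value)],
                         targets=["Ra", "Rb"])
        for rid in ("Ra", "Rb"):
            assert ranges[rid].min == pytest.approx(0.0, abs=1e-6)
            assert ranges[rid].max == pytest.approx(10.0, abs=1e-6)

    def test_ranges_contain_fba_flux(self, ethanol_model):
        from cyanoflux.scenarios import apply_scenario, yield_scenario

        constrained, _ = apply_scenario(ethanol_model, yield_scenario())
        sol = solve_fba(constrained, "EX_etoh", "max")
        targets = ["ATPS", "FNR", "RBC_carb", "PYK", "LEAK", "CEF"]
        ranges = run_fva(constrained, fixed=[("EX_etoh", sol.objective_value)],
                         targets=targets)
        for rid in targets:
            assert ranges[rid].contains(sol[rid])

    def test_ranges_shrink_under_added_constraints(self, ethanol_model):
        from cyanoflux.scenarios import apply_scenario, yield_scenario

        constrained, _ = apply_scenario(ethanol_model, yield_scenario())
        sol = solve_fba(constrained, "EX_etoh", "max")
        targets = ["ATPS", "PYK", "PPS"]
        loose = run_fva(constrained, fixed=[("EX_etoh", sol.objective_value)],
                        targets=targets)
        tight = run_fva(constrained, fixed=[("EX_etoh", sol.objective_value)],
                        targets=targets,
                        extra_constraints=[LinearConstraint({"PPS": 1.0}, "<=", 0.1)])
        for rid in targets:
            assert tight[rid].min >= loose[rid].min - 1e-6
            assert tight[rid].max <= loose[rid].max + 1e-6

    def test_infeasible_fixing_names_constraint(self, toy_chain):
        with pytest.raises(InfeasibleProblem, match="EX_p"):
            run_fva(toy_chain, fixed=[("EX_p", 50.0)], targets=["R1"])


class TestMinimalActiveSet:
    def test_single_chain_counts_chain_length(self, toy_chain):
        sol = solve_fba(toy_chain, "EX_p", "max")
        count, _ = minimal_active_set(toy_chain, "EX_p", sol.objective_value)
        assert count == 5  # uptake + three chain steps + export

    def test_futile_cycle_silenced(self):
        m = branch_model()
        # a two-reaction cycle that can carry arbitrary flux at the optimum
        m.add_reaction(Reaction("C1", stoichiometry={"s_c": -1, "p_c": 1}))
        m.add_reaction(Reaction("C2", stoichiometry={"p_c": -1, "s_c": 1}))
        sol = solve_fba(m, "EX_p", "max")
        count, psol = minimal_active_set(m, "EX_p", sol.objective_value)
        assert psol["C2"] == pytest.approx(0.0, abs=1e-9)
        assert count == 3  # EX_s, P1, EX_p

    def test_invariant_to_duplicating_inactive_reaction(self):
        m = branch_model()
        sol = solve_fba(m, "EX_p", "max")
        base_count, _ = minimal_active_set(m, "EX_p", sol.objective_value)
        m.add_reaction(Reaction("P2_dup", stoichiometry={"s_c": -2, "p_c": 1}))
        dup_count, _ = minimal_active_set(m, "EX_p", sol.objective_value)
        assert dup_count == base_count


class TestDuality:
    @pytest.mark.parametrize("direction", ["max", "min"])
    def test_duality_holds_on_core_solves(self, ethanol_model, direction):
        from cyanoflux.scenarios import apply_scenario, yield_scenario

        constrained, _ = apply_scenario(ethanol_model, yield_scenario())
        # check_duality=True (default) raises if the primal/dual gap > 1e-7
        solve_fba(constrained, "EX_etoh", direction, check_duality=True)
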