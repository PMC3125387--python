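"""Integer search: choice-set boundaries, enumeration, refinement, dispatch."""

import math

import pytest

import expoalloc as ea
from conftest import make_scenario


class TestChoiceSetBoundaries:
    def test_nd_max_single_subject_sublinear_occasions(self):
        # largest n with 2 + 10*sqrt(n) + 10n <= 500
        got = ea.nd_max_given_ns(1, ea.CostModel2(2, 10, 10, beta=0.5),
                                 ea.Budget(500))
        assert got == 43
        c = ea.CostModel2(2, 10, 10, beta=0.5)
        assert ea.cost2(ea.Allocation(1, 43), c) <= 500
        assert ea.cost2(ea.Allocation(1, 44), c) > 500

    def test_nd_max_case_d_reference(self):
        got = ea.nd_max_given_ns(5, ea.CostModel2(20, 1, 1, alpha=1.5, beta=1.5),
                                 ea.Budget(500))
        assert got == 12

    def test_nd_max_unaffordable_returns_none(self):
        got = ea.nd_max_given_ns(100, ea.CostModel2(20, 1, 1, alpha=1.5, beta=1.5),
                                 ea.Budget(500))
        assert got is None

    @pytest.mark.parametrize(
        "cost, alpha, expected",
        [((2, 10, 10), 0.5, 24), ((20, 1, 1), 0.5, 134), ((11, 5.5, 5.5), 1.0, 22)],
    )
    def test_ns_max_reference_values(self, cost, alpha, expected):
        got = ea.ns_max(ea.CostModel2(*cost, alpha=alpha), ea.Budget(500))
        assert got == expected

    def test_ns_max_infeasible_budget_rejected(self):
        with pytest.raises(ea.InfeasibleBudgetError):
            ea.ns_max(ea.CostModel2(20, 1, 1), ea.Budget(10))


class TestEnumerateOptimum:
    def test_case_d_reference_scenario(self):
        res = ea.enumerate_optimum(
            make_scenario((2, 10, 10), (20, 1, 1), alpha=1.5, beta=1.5))
        assert (res.allocation.n_s, res.allocation.n_d) == (5, 12)
        assert round(res.variance, 2) == 0.73

    def test_linear_reference_scenario(self):
        res = ea.enumerate_optimum(make_scenario((2, 10, 10), (20, 1, 1)))
        assert (res.allocation.n_s, res.allocation.n_d) == (13, 9)

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 1.5])
    @pytest.mark.parametrize("beta", [0.5, 1.0, 1.5])
    def test_dominant_between_subject_variance_yields_single_occasion(
            self, alpha, beta):
        res = ea.enumerate_optimum(
            make_scenario((20, 1, 1), (2, 10, 10), alpha=alpha, beta=beta))
        assert res.allocation.n_d == 1

    def test_zero_within_variance_short_circuits(self):
        res = ea.enumerate_optimum(make_scenario((5, 0, 0), (2, 10, 10)))
        assert res.allocation.n_d == 1
        assert res.allocation.n_s == ea.ns_max(ea.CostModel2(2, 10, 10),
                                               ea.Budget(500))


class TestIntegerRefine:
    def test_continuous_solution_refines_to_saturating_neighbour(self):
        scn = make_scenario((2, 10, 10), (20, 1, 1))
        cont = ea.case_a_interior(scn)
        assert cont.n_s_star == pytest.approx(12.5)
        res = ea.integer_refine(cont, scn)
        assert (res.allocation.n_s, res.allocation.n_d) == (13, 9)

    def test_integer_optimum_below_continuous_one(self):
        scn = make_scenario((2, 10, 10), (11, 5.5, 5.5), R=1000)
        cont = ea.case_a_interior(scn)
        assert math.floor(cont.n_s_star) == 21
        res = ea.integer_refine(cont, scn)
        assert (res.allocation.n_s, res.allocation.n_d) == (18, 4)

    def test_knife_edge_scenario_refines_to_boundary(self):
        scn = make_scenario((11, 5.5, 5.5), (11, 5.5, 5.5))
        res = ea.optimize(scn)
        assert (res.allocation.n_s, res.allocation.n_d) == (22, 1)

    def test_refinement_agrees_with_enumeration_on_linear_grid(self):
        for scn in ea.build_grid(500):
            if scn.cost2.alpha == 1 == scn.cost2.beta and not (
                    ea.case_a_upper_condition(scn)
                    or ea.case_a_lower_condition(scn)):
                cont = ea.case_a_interior(scn)
                assert ea.integer_refine(cont, scn).variance == pytest.approx(
                    ea.enumerate_optimum(scn).variance, rel=1e-12)


class TestOptimize:
    def test_infeasible_budget_raises(self):
        with pytest.raises(ea.InfeasibleBudgetError, match="budget insufficient"):
            ea.optimize(make_scenario((2, 10, 10), (2, 10, 10), R=10))

    def test_case_labels_follow_exponents(self):
        pairs = {(1.0, 1.0): "A", (1.0, 0.5): "B", (1.5, 1.0): "C",
                 (1.5, 0.5): "D"}
        for (a, b), label in pairs.items():
            res = ea.optimize(make_scenario((2, 10, 10), (20, 1, 1),
                                            alpha=a, beta=b))
            assert res.case_label.value == label

    def test_case_c_reference(self):
        res = ea.optimize(make_scenario((2, 10, 10), (20, 1, 1), alpha=1.5))
        assert (res.allocation.n_s, res.allocation.n_d) == (6, 17)

    def test_mixed_exponents_reference(self):
        res = ea.optimize(make_scenario((20, 1, 1), (20, 1, 1),
                                        alpha=1.5, beta=0.5))
        assert (res.allocation.n_s, res.allocation.n_d) == (8, 3)
        assert round(res.variance, 2) == 2.58

    def test_result_fields_are_consistent(self):
        scn = make_scenario((2, 10, 10), (20, 1, 1), alpha=1.5, beta=1.5)
        res = ea.optimize(scn)
        assert res.variance == pytest.approx(
            ea.variance_of_mean2(res.allocation, scn.var2))
        assert res.cost == pytest.approx(ea.cost2(res.allocation, scn.cost2))
        assert res.utilization_pct == pytest.approx(100 * res.cost / 500)
        assert ea.is_feasible(res.cost, scn.budget)

    def test_oracle_equivalence_on_random_scenarios(self):
        for scn in ea.fixture_scenarios(40, 7):
            opt = ea.optimize(scn)
            _, bf_var = ea.brute_force_optimum(scn)
            assert opt.variance == pytest.approx(bf_var, rel=1e-12)

    def test_variance_non_increasing_in_budget(self):
        budgets = [100, 200, 400, 500, 800, 1600]
        prev = math.inf
        for R in budgets:
            res = ea.optimize(make_scenario((2, 10, 10), (20, 1, 1),
                                            alpha=1.25, beta=0.75, R=R))
            assert res.variance <= prev + 1e-12
            prev = res.variance

    def test_scale_invariance_of_optimum(self):
        for k in (0.1, 3.0, 250.0):
            base = ea.optimize(make_scenario((2, 10, 10), (20, 1, 1),
                                             alpha=1.5, beta=1.5))
            scaled = ea.optimize(make_scenario(
                (2, 10, 10), (20 * k, k, k), alpha=1.5, beta=1.5, R=500 * k))
            assert scaled.allocation == base.allocation

    def test_forced_enumeration_matches_case_a_dispatch(self):
        for scn in ea.build_grid(500):
            if scn.cost2.alpha == 1 == scn.cost2.beta:
                assert ea.enumerate_optimum(scn).allocation == \
                    ea.optimize(scn).allocation


class TestSensitivityProfile:
    def test_profile_near_optimal_band(self):
        prof = ea.sensitivity_profile(
            make_scenario((2, 10, 10), (20, 1, 1), alpha=0.75, beta=0.75)).rows
        sub = prof[(prof.n_s >= 15) & (prof.n_s <= 32)]
        below = sub[sub.n_s != 30]
        # every saturating strategy in the band stays within 0.226 of the
        # optimum's 0.20 except (30, 4), which wastes 8% of the budget
        assert below.variance.max() <= 0.226
        row30 = sub[sub.n_s == 30].iloc[0]
        assert (row30.n_d, round(row30.variance, 2)) == (4, 0.23)

    def test_profile_minimum_matches_optimize(self):
        scn = make_scenario((2, 10, 10), (20, 1, 1), alpha=0.75, beta=0.75)
        prof = ea.sensitivity_profile(scn)
        best = prof.best()
        res = ea.optimize(scn)
        assert (best.n_s, best.n_d) == (21, 9)
        assert (res.allocation.n_s, res.allocation.n_d) == (21, 9)
        assert round(best.variance, 2) == 0.20

    def test_single_row_when_only_one_subject_affordable(self):
        prof = ea.sensitivity_profile(
            make_scenario((2, 10, 10), (18, 2, 2), R=23.0)).rows
        assert len(prof) == 1
        assert prof.iloc[0].n_s == 1

    def test_every_row_is_budget_saturating(self):
        scn = make_scenario((2, 10, 10), (2, 10, 10), alpha=0.75, beta=0.75)
        prof = ea.sensitivity_profile(scn).rows
        for _, r in prof.iterrows():
            assert ea.is_feasible(r.cost, scn.budget)
            bigger = ea.cost2(ea.Allocation(int(r.n_s), int(r.n_d) + 1),
                              scn.cost2)
            assert not ea.is_feasible(bigger, scn.budget)
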