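import numpy as np
import pytest

from ymcflux import (
    ExpressionWeights,
    FluxProblem,
    InfeasibleProblemError,
    MetabolicNetwork,
    Metabolite,
    PhysiologyConstraint,
    Reaction,
    expression_to_reaction_weights,
    objective_value,
    solve_maxent,
    solve_series,
    split_reversible,
)
from ymcflux.synthetic_data import make_toy_network

from conftest import uniform_problem


class TestObjectiveValue:
    def test_zero_when_fluxes_proportional_to_weights(self):
        g = np.array([1.0, 2.0, 3.0])
        assert objective_value(5 * g, g) == pytest.approx(0.0, abs=1e-14)

    def test_hand_computed_two_component_value(self):
        # v=(1,1), g=(1,3): -(1/2 log 2 + 1/2 log(2/3)) = -1/2 log(4/3)
        expected = -0.5 * np.log(4.0 / 3.0)
        assert objective_value([1.0, 1.0], [1.0, 3.0]) == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(-0.1438, abs=5e-5)

    def test_nonpositive_everywhere(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            v = rng.uniform(0, 5, 6)
            g = rng.uniform(0.1, 5, 6)
            assert objective_value(v, g) <= 1e-12

    def test_zero_total_flux_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            objective_value([0.0, 0.0], [1.0, 1.0])

    def test_zero_flux_components_contribute_nothing(self):
        # 0 log 0 = 0 convention
        v = np.array([0.0, 1.0, 1.0])
        g = np.array([5.0, 1.0, 1.0])
        assert np.isfinite(objective_value(v, g))


def triple_branch_network():
    """Source -> three identical parallel branches -> sink (2 free dims)."""
    mets = [Metabolite("A"), Metabolite("B")]
    rxns = [
        Reaction("SRC", {"A": 1.0}, 1, 1),
        Reaction("BR1", {"A": -1.0, "B": 1.0}, 0, 10),
        Reaction("BR2", {"A": -1.0, "B": 1.0}, 0, 10),
        Reaction("BR3", {"A": -1.0, "B": 1.0}, 0, 10),
        Reaction("SNK", {"B": -1.0}, 0, 10),
    ]
    return MetabolicNetwork(mets, rxns)


class TestSolveMaxent:
    def test_symmetric_diamond_splits_equally(self, diamond_pinned):
        sol = solve_maxent(uniform_problem(diamond_pinned))
        assert sol.net_fluxes["BR1"] == pytest.approx(0.5, abs=1e-6)
        assert sol.net_fluxes["BR2"] == pytest.approx(0.5, abs=1e-6)
        assert sol.max_sv_residual < 1e-8

    def test_weighted_diamond_splits_three_to_one(self, diamond_pinned):
        sol = solve_maxent(uniform_problem(diamond_pinned, g=[1.0, 3.0, 1.0, 1.0]))
        ratio = sol.net_fluxes["BR1"] / sol.net_fluxes["BR2"]
        assert ratio == pytest.approx(3.0, rel=1e-5)

    def test_kl_zero_attained_when_weights_feasible(self, diamond_pinned):
        # weights proportional to a feasible flux vector (1, .5, .5, 1)
        sol = solve_maxent(uniform_problem(diamond_pinned, g=[1.0, 0.5, 0.5, 1.0]))
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)
        fractions = sol.v / sol.v.sum()
        np.testing.assert_allclose(fractions, np.array([1, 0.5, 0.5, 1]) / 3, atol=1e-6)

    def test_grid_search_oracle_one_free_dimension(self, diamond_pinned):
        g = np.array([1.0, 2.0, 1.0, 1.5])
        sol = solve_maxent(uniform_problem(diamond_pinned, g=g))
        f = np.arange(1e-6, 1.0, 1e-3)
        kl = np.empty_like(f)
        for i, fi in enumerate(f):
            kl[i] = -objective_value(np.array([1.0, fi, 1.0 - fi, 1.0]), g)
        best = f[np.argmin(kl)]
        assert abs(sol.net_fluxes["BR1"] - best) <= 1e-3

    def test_grid_search_oracle_two_free_dimensions(self):
        net = triple_branch_network()
        g = np.array([1.0, 1.0, 2.0, 3.0, 1.0])
        sol = solve_maxent(uniform_problem(net, g=g))
        step = 1e-3
        f1, f2 = np.meshgrid(
            np.arange(step, 1.0, step), np.arange(step, 1.0, step), indexing="ij"
        )
        mask = f1 + f2 < 1.0 - step / 2
        f1, f2 = f1[mask], f2[mask]
        f3 = 1.0 - f1 - f2
        total = 2.0 + f1 + f2 + f3  # SRC + branches + SNK
        q = g / g.sum()
        kl = np.zeros_like(f1)
        for col, qi in zip((np.ones_like(f1), f1, f2, f3, np.ones_like(f1)), q):
            p = col / total
            kl += p * np.log(p / qi)
        i = np.argmin(kl)
        assert abs(sol.net_fluxes["BR1"] - f1[i]) <= step
        assert abs(sol.net_fluxes["BR2"] - f2[i]) <= step
        assert abs(sol.net_fluxes["BR3"] - f3[i]) <= step

    def test_lb_above_ub_is_infeasible(self, diamond_pinned):
        diamond_pinned.reactions[1].lower_bound = 5.0
        diamond_pinned.reactions[1].upper_bound = 10.0
        diamond_pinned.reactions[3].upper_bound = 2.0  # SNK < BR1 minimum
        with pytest.raises(InfeasibleProblemError, match="stoichiometric"):
            solve_maxent(uniform_problem(diamond_pinned))

    def test_component_bound_violation_reported(self, diamond_pinned):
        irr = split_reversible(diamond_pinned)
        irr.lb[1] = 5.0
        irr.ub[1] = 2.0
        weights = ExpressionWeights(
            g=np.ones(irr.n_components), component_ids=irr.component_ids
        )
        with pytest.raises(InfeasibleProblemError, match="LB > UB"):
            solve_maxent(FluxProblem(irr=irr, weights=weights))

    def test_multistart_uniqueness(self, diamond_pinned):
        prob = uniform_problem(diamond_pinned, g=[1.0, 2.5, 0.5, 2.0])
        irr = prob.irr
        sols = [
            solve_maxent(prob, x0=x0)
            for x0 in (None, irr.lb + 0.01, np.minimum(irr.ub, 0.9), irr.ub * 0.5)
        ]
        for s in sols[1:]:
            np.testing.assert_allclose(s.v, sols[0].v, rtol=1e-6, atol=1e-8)

    def test_relaxing_binding_bound_never_decreases_optimum(self, diamond_pinned):
        g = [1.0, 3.0, 1.0, 1.0]
        tight = uniform_problem(diamond_pinned, g=g)
        tight.irr.ub[tight.irr.component_index["BR1"]] = 0.3  # binds (wants 0.75)
        obj_tight = solve_maxent(tight).objective_value
        relaxed = uniform_problem(diamond_pinned, g=g)
        obj_relaxed = solve_maxent(relaxed).objective_value
        assert obj_relaxed >= obj_tight - 1e-9


class TestPhysiologyConstraint:
    def solve_mini_cell(self, mini_cell, w_o2=5.0, w_mu=0.1):
        irr = split_reversible(mini_cell)
        fpkm = {g: 10.0 for g in (
            "HXT1 MUP1 GLK1 PFK1 PDC1 PDC5 COX1 QCR2 GSY1 GPH1 TPS1 NTH1 "
            "PDA1 PDB1 HAT1 SAM1 SAM2 SET1".split()
        )}
        weights = expression_to_reaction_weights(irr, fpkm)
        phys = PhysiologyConstraint(w_mu=w_mu, w_o2=w_o2, fix_growth=True)
        return solve_maxent(FluxProblem(irr=irr, weights=weights, physiology=phys))

    def test_growth_pinned_and_oxygen_scaled(self, mini_cell):
        sol = self.solve_mini_cell(mini_cell, w_o2=5.0)
        assert sol.net_fluxes["BIOMASS"] == pytest.approx(0.1, abs=1e-9)
        # Eq: v_mu - (w_mu/w_o2) v_o2 = 0 => uptake magnitude equals w_o2
        assert -sol.net_fluxes["EX_o2"] == pytest.approx(5.0, rel=1e-5)

    def test_ratio_constraint_residual_small(self, mini_cell):
        sol = self.solve_mini_cell(mini_cell, w_o2=3.0)
        v_mu = sol.net_fluxes["BIOMASS"]
        v_o2 = -sol.net_fluxes["EX_o2"]
        assert abs(v_mu - (0.1 / 3.0) * v_o2) < 1e-6

    def test_impossible_oxygen_demand_is_physiological_infeasibility(self, mini_cell):
        # biomass alone requires 1 mol O2 per 0.1 growth; w_o2 below that
        with pytest.raises(InfeasibleProblemError, match="physiological"):
            self.solve_mini_cell(mini_cell, w_o2=0.05)


class TestSolveSeries:
    def test_identical_problems_give_identical_solutions(self, diamond_pinned):
        probs = [uniform_problem(diamond_pinned, g=[1.0, 2.0, 1.0, 1.0]) for _ in range(2)]
        # share one parent network object
        probs[1].irr = probs[0].irr
        sols = solve_series(probs)
        np.testing.assert_array_equal(sols[0].v, sols[1].v)

    def test_failure_names_the_time_point(self, diamond_pinned):
        good = uniform_problem(diamond_pinned)
        bad = uniform_problem(diamond_pinned)
        bad.irr = good.irr
        bad2 = uniform_problem(diamond_pinned)
        bad2.irr = good.irr
        bad2.irr = good.irr
        probs = [good, bad, bad2]
        probs[1] = FluxProblem(
            irr=good.irr,
            weights=good.weights,
            physiology=PhysiologyConstraint(w_mu=1.0, w_o2=1.0),
        )
        with pytest.raises((InfeasibleProblemError, ValueError), match="time point 1|oxygen"):
            solve_series(probs)

    def test_mismatched_networks_rejected(self, diamond_pinned):
        other = make_toy_network("diamond")
        with pytest.raises(ValueError, match="share"):
            solve_series([uniform_problem(diamond_pinned), uniform_problem(other)])
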