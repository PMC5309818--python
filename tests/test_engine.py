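"""LP engine: FBA, FVA, weighted flux minimization, tasks, media."""

import math

import numpy as np
import pytest

from timbr import (
    MediaConstraints,
    MetabolicNetwork,
    Metabolite,
    Reaction,
    TaskDefinition,
    check_task,
    doubling_time,
    fba,
    fva,
    make_irreversible,
    min_weighted_flux,
    open_exchange_media,
    run_tasks,
)
from timbr.engine import EngineError, OPTIMAL
from timbr.fixtures import FixtureSpec, energy_fixture, paired_networks, \
    species_task, toy_network

from conftest import assert_steady_state, random_network, to_cobra


class TestFBA:
    def test_chain_maximum_equals_uptake_bound(self, chain_network):
        res = fba(chain_network, "EX_B")
        assert res.status == OPTIMAL
        assert res.objective_value == pytest.approx(10.0)
        assert_steady_state(chain_network, res.fluxes)

    def test_media_overrides_only_listed_exchanges(self, chain_network):
        media = MediaConstraints({"EX_A": (-4.0, 0.0)})
        res = fba(chain_network, "EX_B", media)
        assert res.objective_value == pytest.approx(4.0)

    def test_infeasible_is_distinct_status(self, chain_network):
        # force secretion above the uptake capacity
        chain_network.reactions["EX_B"].lb = 20.0
        res = fba(chain_network, "EX_B")
        assert res.status == "infeasible"

    def test_unbounded_is_distinct_status(self):
        net = MetabolicNetwork()
        net.add_metabolite(Metabolite("a", "e"))
        net.add_reaction(Reaction("EX_in", {"a[e]": 1.0}, 0.0, np.inf))
        net.add_reaction(Reaction("EX_out", {"a[e]": -1.0}, 0.0, np.inf))
        assert fba(net, "EX_out").status == "unbounded"

    def test_matches_cobra_on_fixture(self):
        cobra = pytest.importorskip("cobra")
        net = random_network(9)
        model = to_cobra(net)
        model.objective = "biomass"
        expected = model.optimize().objective_value
        got = fba(net, "biomass").objective_value
        assert got == pytest.approx(expected, rel=1e-6)


class TestDoublingTime:
    def test_rat_and_human_growth_rates(self):
        assert doubling_time(0.048) == pytest.approx(14.44, abs=5e-3)
        assert doubling_time(0.040) == pytest.approx(17.33, abs=5e-3)

    def test_ln2_rate_doubles_in_one_hour(self):
        assert doubling_time(math.log(2.0)) == pytest.approx(1.0)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            doubling_time(0.0)


class TestFVA:
    def test_chain_secretion_range(self, chain_network):
        ranges = fva(chain_network, ["EX_B"])
        assert (ranges["EX_B"].min_flux, ranges["EX_B"].max_flux) == (0.0, 10.0)

    def test_blocked_reaction_is_zero_zero(self, chain_network):
        chain_network.add_metabolite(Metabolite("C", "e"))
        chain_network.add_reaction(
            Reaction("dead", {"B[e]": -1.0, "C[e]": 1.0}, 0.0, 10.0))
        ranges = fva(chain_network, ["dead"])
        assert (ranges["dead"].min_flux, ranges["dead"].max_flux) == (0.0, 0.0)

    def test_objective_fraction_floors_growth(self):
        net = toy_network(FixtureSpec(seed=2))
        full = fba(net, "biomass").objective_value
        ranges = fva(net, ["EX_P1"], objective_fraction=0.9)
        # with 90% of biomass enforced, only the residual uptake capacity
        # can leak out as P1 secretion
        assert ranges["EX_P1"].max_flux == pytest.approx(0.1 * full, abs=1e-6)

    @pytest.mark.parametrize("seed", [1, 8])
    def test_matches_naive_two_lp_oracle(self, seed):
        """FVA ranges equal an independent per-reaction two-LP solve."""
        net = random_network(seed)
        ranges = fva(net)
        for rid in net.reactions:
            lo = fba(net, rid, maximize=False)
            hi = fba(net, rid, maximize=True)
            assert ranges[rid].min_flux == pytest.approx(
                lo.objective_value, abs=1e-6)
            assert ranges[rid].max_flux == pytest.approx(
                hi.objective_value, abs=1e-6)

    def test_matches_cobra_fva(self):
        pytest.importorskip("cobra")
        from cobra.flux_analysis import flux_variability_analysis

        net = random_network(4)
        model = to_cobra(net)
        model.objective = "biomass"
        expected = flux_variability_analysis(model, fraction_of_optimum=0.0)
        ranges = fva(net)
        for rid in net.reactions:
            assert ranges[rid].min_flux == pytest.approx(
                expected.loc[rid, "minimum"], abs=1e-5)
            assert ranges[rid].max_flux == pytest.approx(
                expected.loc[rid, "maximum"], abs=1e-5)

    def test_sandwich_invariant(self):
        net = random_network(6)
        sol = fba(net, "biomass")
        ranges = fva(net)
        for rid, flux in sol.fluxes.items():
            assert ranges[rid].min_flux - 1e-6 <= flux <= ranges[rid].max_flux + 1e-6


class TestWeightedFlux:
    def test_unit_weights_chain_demand(self, chain_network):
        irrev = make_irreversible(chain_network)
        res = min_weighted_flux(irrev, np.ones(irrev.n_columns),
                                irrev.column("EX_B", 1), 10.0)
        assert res.status == OPTIMAL
        # uptake, conversion and secretion each carry 10 at weight 1
        assert res.demand == pytest.approx(30.0)

    def test_cheaper_pathway_wins(self):
        """Two routes A->B; halving one route's weights reroutes flux."""
        net = MetabolicNetwork()
        for mid in ("A", "B"):
            net.add_metabolite(Metabolite(mid, "e"))
        net.add_reaction(Reaction("EX_A", {"A[e]": -1.0}, -10.0, 0.0))
        net.add_reaction(Reaction("path1", {"A[e]": -1.0, "B[e]": 1.0}, 0, 100))
        net.add_reaction(Reaction("path2", {"A[e]": -1.0, "B[e]": 1.0}, 0, 100))
        net.add_reaction(Reaction("EX_B", {"B[e]": -1.0}, 0.0, 100.0))
        irrev = make_irreversible(net)
        w = np.ones(irrev.n_columns)
        w[irrev.column("path2", 1)] = 0.5
        res = min_weighted_flux(irrev, w, irrev.column("EX_B", 1), 10.0)
        # hand enumeration: path1 demand = 10+10+10 = 30,
        # path2 demand = 10+5+10 = 25
        assert res.demand == pytest.approx(25.0)
        assert res.fluxes[irrev.column("path2", 1)] == pytest.approx(10.0)

    def test_weight_scaling_linearity(self, chain_network):
        irrev = make_irreversible(chain_network)
        w = np.full(irrev.n_columns, 1.7)
        base = min_weighted_flux(irrev, w, irrev.column("EX_B", 1), 10.0)
        scaled = min_weighted_flux(irrev, 3.0 * w, irrev.column("EX_B", 1), 10.0)
        assert scaled.demand == pytest.approx(3.0 * base.demand)

    def test_demand_monotone_in_min_rate(self, chain_network):
        irrev = make_irreversible(chain_network)
        w = np.ones(irrev.n_columns)
        demands = [
            min_weighted_flux(irrev, w, irrev.column("EX_B", 1), rate).demand
            for rate in (1.0, 5.0, 9.0)
        ]
        assert demands == sorted(demands)

    def test_infeasible_forcing_reported(self, chain_network):
        irrev = make_irreversible(chain_network)
        res = min_weighted_flux(irrev, np.ones(irrev.n_columns),
                                irrev.column("EX_B", 1), 50.0)
        assert res.status == "infeasible"

    def test_nonpositive_weights_rejected(self, chain_network):
        irrev = make_irreversible(chain_network)
        with pytest.raises(ValueError, match="positive"):
            min_weighted_flux(irrev, np.zeros(irrev.n_columns))


class TestTasks:
    def test_energy_fixture_suite(self):
        net, tasks = energy_fixture()
        summary = run_tasks(net, tasks)
        assert summary.n_passed == summary.n_tasks == 2
        # the should-fail task is infeasible, hence passed
        by_id = {r.task_id: r for r in summary.results}
        assert by_id["work_from_inorganic"].feasible is False
        assert by_id["work_from_inorganic"].passed is True
        assert by_id["work_from_carbon"].feasible is True

    def test_species_delta_asymmetry(self):
        spec = FixtureSpec(seed=5)
        net_a, net_b = paired_networks(spec)
        task = species_task(spec)
        assert check_task(net_a, task).feasible is True
        assert check_task(net_b, task).feasible is False

    def test_passthrough_requires_transport(self):
        spec = FixtureSpec(seed=5)
        net = toy_network(spec)
        with_transport = TaskDefinition(
            "t", inputs=[("A1[e]", 0.0, 1.0)], outputs=[("A1[c]", 0.1, 1.0)])
        without = TaskDefinition(
            "t2", inputs=[("P1[e]", 0.0, 1.0)], outputs=[("P1[c]", 0.1, 1.0)])
        assert check_task(net, with_transport).feasible is True
        # T1_out runs c->e only; no route back into the cytosol
        assert check_task(net, without).feasible is False

    def test_unknown_metabolite_is_error_not_crash(self, chain_network):
        task = TaskDefinition("t", inputs=[("nope[e]", 0.0, 1.0)],
                              outputs=[("B[e]", 1.0, 1.0)])
        result = check_task(chain_network, task)
        assert result.error is not None
        assert result.passed is False


class TestMedia:
    def test_open_exchange_bounds(self):
        net, _ = energy_fixture()
        media = open_exchange_media(net, ["pi[e]", "h2o[e]"])
        assert media.bounds["EX_pi"][0] == -np.inf
        assert media.bounds["EX_glc"][0] == -1.0
        # every exchange reaction is overridden
        assert len(media.bounds) == len(net.exchange_reactions())

    def test_non_exchangeable_ion_rejected(self):
        net, _ = energy_fixture()
        with pytest.raises(EngineError, match="not exchangeable"):
            open_exchange_media(net, ["atp[c]"])

    def test_media_on_non_exchange_rejected(self, chain_network):
        media = MediaConstraints({"conv": (0.0, 1.0)})
        with pytest.raises(EngineError, match="non-exchange"):
            fba(chain_network, "EX_B", media)
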