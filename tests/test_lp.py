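import numpy as np
import pytest

from conftest import assert_solution_valid
from lp_oracle import oracle_fba_optimum, oracle_min_total_flux_at_optimum

from methyloflux import (
    consumption_fraction,
    flux_scan,
    knockout_growth,
    solve_fba,
    solve_pfba,
)
from methyloflux.synthetic import ToyNetworkSpec, generate_toy_network


def _toy(kind, uptake=10.0):
    return generate_toy_network(ToyNetworkSpec(kind=kind, uptake=uptake))


class TestFBA:
    def test_linear_chain_analytic_optimum(self):
        model, truth = _toy("linear_chain")
        sol = solve_fba(model)
        assert_solution_valid(model, sol)
        assert sol.objective_value == pytest.approx(truth["objective"], abs=1e-8)

    def test_core_model_glucose_growth_matches_independent_solver(self, core, tmp_path):
        sol = solve_fba(core)
        assert_solution_valid(core, sol)
        # independent cross-check: cobra solving the very same file
        cobra = pytest.importorskip("cobra")
        from methyloflux.model import write_model

        path = tmp_path / "core.json"
        write_model(core, path, format="json")
        reference = cobra.io.load_json_model(str(path)).slim_optimize()
        assert sol.objective_value == pytest.approx(reference, abs=1e-6)
        assert sol.objective_value == pytest.approx(0.8739, abs=1e-3)

    def test_contradictory_bounds_are_infeasible(self):
        model, _ = _toy("linear_chain")
        model.reactions["EX_A"].lower_bound = 0.0  # no uptake …
        model.reactions["EX_A"].upper_bound = 0.0
        model.reactions["SINK_B"].lower_bound = 5.0  # … but forced output
        sol = solve_fba(model)
        assert sol.status == "infeasible"
        assert sol.fluxes == {}

    def test_unbounded_objective_detected(self):
        model, _ = _toy("futile_cycle")
        # make the internal cycle "productive" and unbounded
        model.reactions["F1"].upper_bound = float("inf")
        model.reactions["F2"].upper_bound = float("inf")
        model.reactions["F2"].stoichiometry["B"] = 2.0  # creates mass from nothing
        model.reactions["SINK_B"].upper_bound = float("inf")
        sol = solve_fba(model)
        assert sol.status == "unbounded"

    def test_scale_invariance_on_growth_linear_toys(self):
        for kind in ("linear_chain", "branch"):
            model, _ = _toy(kind)
            base = solve_fba(model).objective_value
            for rxn in model.reactions.values():
                if rxn.is_exchange:
                    rxn.lower_bound *= 2
                    rxn.upper_bound *= 2
            assert solve_fba(model).objective_value == pytest.approx(2 * base, rel=1e-9)


class TestVertexOracle:
    def test_fba_matches_exhaustive_vertex_enumeration(self, toy):
        model, _truth = toy
        sol = solve_fba(model)
        assert_solution_valid(model, sol)
        assert sol.objective_value == pytest.approx(
            oracle_fba_optimum(model), abs=1e-8
        )

    def test_pfba_total_flux_is_minimal_among_alternate_optima(self, toy):
        model, truth = toy
        pfba = solve_pfba(model)
        assert_solution_valid(model, pfba)
        assert pfba.total_abs_flux <= oracle_min_total_flux_at_optimum(model) + 1e-8
        if "pfba_total_abs_flux" in truth:
            assert pfba.total_abs_flux == pytest.approx(
                truth["pfba_total_abs_flux"], abs=1e-7
            )


class TestPFBA:
    @pytest.mark.parametrize("kind", ["linear_chain", "branch", "futile_cycle"])
    def test_pfba_objective_equals_fba_objective(self, kind):
        model, _ = _toy(kind)
        assert solve_pfba(model).objective_value == pytest.approx(
            solve_fba(model).objective_value, abs=1e-6
        )

    def test_pfba_objective_on_genome_scale_models(self, core, methylotroph):
        for model in (core, methylotroph):
            fba = solve_fba(model)
            pfba = solve_pfba(model)
            assert_solution_valid(model, pfba, tol=1e-8)
            assert pfba.objective_value == pytest.approx(fba.objective_value, abs=1e-6)
            assert pfba.total_abs_flux <= fba.total_abs_flux + 1e-6

    def test_futile_cycle_carries_no_pfba_flux(self):
        model, truth = _toy("futile_cycle")
        pfba = solve_pfba(model)
        for rid in truth["cycle_reactions"]:
            assert abs(pfba.fluxes[rid]) <= 1e-6

    def test_pfba_prefers_the_short_route(self):
        model, truth = _toy("branch")
        pfba = solve_pfba(model)
        for rid in truth["long_route"]:
            assert abs(pfba.fluxes[rid]) <= 1e-6
        assert pfba.fluxes[truth["short_route"][0]] == pytest.approx(10.0, abs=1e-6)

    def test_methylotroph_pyruvate_node_sign_pattern(self, methylotroph):
        """Carbon enters the TCA cycle by PEP carboxylation; the PEP→pyruvate
        step is silent so no ATP-dissipating cycle with PEP synthetase runs."""
        pfba = solve_pfba(methylotroph)
        assert abs(pfba.fluxes["PYK"]) <= 1e-6
        assert pfba.fluxes["PPS"] > 1e-6
        assert pfba.fluxes["PPC"] > 1e-6


class TestKnockout:
    def test_essential_reaction_knockout_is_lethal(self):
        model, _ = _toy("linear_chain")
        res = knockout_growth(model, ["R1"])
        assert res.ratio == pytest.approx(0.0, abs=1e-9)

    def test_redundant_route_knockout_is_neutral(self):
        model, _ = _toy("branch")
        res = knockout_growth(model, ["L1"])
        assert res.ratio == pytest.approx(1.0, abs=1e-9)

    def test_forced_flux_makes_knockout_infeasible(self):
        model, _ = _toy("linear_chain")
        model.reactions["SINK_B"].lower_bound = 1.0
        res = knockout_growth(model, ["R1"])
        assert res.infeasible
        assert res.knockout_growth == 0.0

    def test_unknown_target_raises(self, methylotroph):
        with pytest.raises(KeyError):
            knockout_growth(methylotroph, ["NOPE"])


class TestScan:
    def test_grid_must_be_strictly_increasing(self, methylotroph):
        with pytest.raises(ValueError):
            flux_scan(methylotroph, "GND", [0.0, 0.0, 1.0])
        with pytest.raises(ValueError):
            flux_scan(methylotroph, "GND", [])

    def test_scan_at_zero_matches_knockout(self, methylotroph):
        scan = flux_scan(methylotroph, "GND", [0.0, 0.5])
        ko = knockout_growth(methylotroph, ["GND"])
        assert scan.growth[0] == pytest.approx(ko.knockout_growth, abs=1e-6)

    def test_infeasible_grid_point_recorded_as_nan(self, methylotroph):
        gnd_max = solve_fba(methylotroph, objective="GND").objective_value
        scan = flux_scan(methylotroph, "GND", [0.0, gnd_max + 5.0])
        assert np.isnan(scan.growth[1])
        assert scan.feasible_mask == [True, False]

    def test_forcing_flux_above_its_pfba_value_never_helps(self):
        """Pushing a carbon-losing reaction above its optimal level can only
        reduce the objective."""
        model, _ = _toy("carbon_loss")
        pfba = solve_pfba(model)
        v0 = pfba.fluxes["DIRECT"]  # 0 at the optimum: DIRECT steals substrate
        scan = flux_scan(model, "DIRECT", [v0, v0 + 2.0, v0 + 5.0, v0 + 9.0])
        feasible = [g for g in scan.growth if not np.isnan(g)]
        assert all(b <= a + 1e-9 for a, b in zip(feasible, feasible[1:]))


class TestConsumptionFraction:
    def test_sole_consumer_gets_fraction_one(self):
        model, _ = _toy("linear_chain")
        sol = solve_fba(model)
        assert consumption_fraction(sol, model, "B", "SINK_B") == pytest.approx(1.0)

    def test_unconsumed_metabolite_is_an_error(self):
        model, _ = _toy("carbon_loss")
        model.reactions["DIRECT"].upper_bound = 0.0
        sol = solve_fba(model)  # all flux through SPLIT, P3 never produced/consumed
        with pytest.raises(ValueError):
            consumption_fraction(sol, model, "P3", "EX_P3")

    def test_methylotroph_gnd_fraction_is_small(self, methylotroph):
        pfba = solve_pfba(methylotroph)
        frac = consumption_fraction(pfba, methylotroph, "6pgc_c", "GND")
        assert 0.0 <= frac < 0.10
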