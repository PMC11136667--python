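import numpy as np
import pytest

from methyloflux import (
    build_production_model,
    carbon_to_mass_yield,
    production_metrics,
    theoretical_carbon_yield,
    variant_yield_grid,
)
from methyloflux.extensions import PRODUCTS, SUBSTRATES
from methyloflux.formula import ATOMIC_WEIGHTS, carbon_count
from methyloflux.lp import solve_fba
from methyloflux.synthetic import ToyNetworkSpec, generate_toy_network
from methyloflux.yields import _prepare_yield_model, paba_glucose_yield_report


def _exchange_carbon_flow(model, fluxes):
    """Net carbon flow through all boundary reactions (positive = out)."""
    total = 0.0
    for rxn in model.reactions.values():
        if not rxn.is_exchange:
            continue
        met = model.metabolites[next(iter(rxn.stoichiometry))]
        n_c = carbon_count(met.formula) if met.formula else 0
        # exchange convention: metabolite coefficient −1, positive flux = export
        total += n_c * -rxn.stoichiometry[next(iter(rxn.stoichiometry))] * fluxes[rxn.id]
    return total


class TestTheoreticalYield:
    def test_carbon_loss_toy_yield_is_two_thirds(self):
        model, truth = generate_toy_network(ToyNetworkSpec(kind="carbon_loss"))
        res = theoretical_carbon_yield(model, "EX_S", "EX_P2")
        assert res.carbon_yield_percent == pytest.approx(
            truth["carbon_yield_P2_percent"], abs=1e-6
        )

    def test_substrate_without_uptake_is_rejected(self):
        model, _ = generate_toy_network(ToyNetworkSpec(kind="carbon_loss"))
        model.reactions["EX_S"].lower_bound = 0.0
        with pytest.raises(ValueError):
            theoretical_carbon_yield(model, "EX_S", "EX_P2")

    def test_blocked_product_yields_zero_not_error(self):
        model, _ = generate_toy_network(ToyNetworkSpec(kind="carbon_loss"))
        model.reactions["SPLIT"].upper_bound = 0.0
        res = theoretical_carbon_yield(model, "EX_S", "EX_P2")
        assert res.carbon_yield_percent == pytest.approx(0.0, abs=1e-9)

    def test_uptake_scaling_invariance(self, core):
        model = build_production_model(core, "ed_ta", "lactate", c1_salvage=True)
        yields = []
        for uptake in (10.0, 60.0, 137.0):
            model.reactions["EX_meoh_e"].lower_bound = -uptake
            res = theoretical_carbon_yield(model, "EX_meoh_e", "EX_lac__L_e")
            yields.append(res.carbon_yield_percent)
        assert max(yields) - min(yields) <= 1e-6

    @pytest.mark.parametrize("product", list(PRODUCTS))
    def test_carbon_conservation_and_cap_at_yield_optimum(self, core, product):
        model = build_production_model(core, "ed_ta", product, c1_salvage=True)
        ex, n_c, _f = PRODUCTS[product][1], None, None
        prepared = _prepare_yield_model(model, "EX_meoh_e")
        sol = solve_fba(prepared, objective=PRODUCTS[product][1], sense="maximize")
        assert sol.optimal
        # carbon in equals carbon out over all boundary fluxes
        assert abs(_exchange_carbon_flow(prepared, sol.fluxes)) <= 1e-6 * 60
        res = theoretical_carbon_yield(model, "EX_meoh_e", PRODUCTS[product][1])
        assert res.carbon_yield_percent <= 100.0 + 1e-6

    def test_wild_type_glucose_yield_cap(self, core):
        for product in PRODUCTS:
            model = build_production_model(core, "wild_type", product)
            res = theoretical_carbon_yield(model, "EX_glc__D_e", PRODUCTS[product][1])
            assert 0.0 <= res.carbon_yield_percent <= 100.0 + 1e-6


class TestYieldGrid:
    def test_full_grid_shape_and_variant_equality(self, core):
        grid = variant_yield_grid(core)
        assert len(grid) == 8  # 4 products × methanol × 2 variants
        pivot = grid.pivot_table(
            index="product", columns="variant", values="carbon_yield_percent"
        )
        assert np.all(pivot["ed_ta"] >= pivot["fba_ta"] - 1e-6)

    def test_empty_product_list_gives_empty_table(self, core):
        assert variant_yield_grid(core, products=[]).empty

    def test_unknown_names_raise(self, core):
        with pytest.raises(KeyError):
            variant_yield_grid(core, products=["gold"])
        with pytest.raises(KeyError):
            variant_yield_grid(core, variants=["xu5p_cycle"], products=["lactate"])

    def test_paba_sensitivity_report_brackets_both_accountings(self, core):
        report = paba_glucose_yield_report(core)
        assert set(report["accounting"]) == {"glutamine", "ammonium"}
        default = report[report.atpm == "default"]
        gln = float(default[default.accounting == "glutamine"].carbon_yield_percent.iloc[0])
        nh4 = float(default[default.accounting == "ammonium"].carbon_yield_percent.iloc[0])
        assert gln < nh4  # charging the amide-recharge ATP lowers the ceiling
        # dropping maintenance can only raise the ceiling
        zero = report[report.atpm == "zero"]
        assert (zero.carbon_yield_percent.values >= default.carbon_yield_percent.values).all()


class TestUnitArithmetic:
    @pytest.mark.parametrize(
        "cy,prod,sub,expected",
        [
            (15.7, "C3H6O3", "CH4O", 0.147),  # lactic acid from methanol
            (3.0, "C7H7NO2", "CH4O", 0.018),  # PABA from methanol
            (100.0, "C3H6O3", "C6H12O6", 1.000),  # equal carbon:mass density
        ],
    )
    def test_carbon_to_mass_yield_examples(self, cy, prod, sub, expected):
        assert carbon_to_mass_yield(cy, prod, sub) == pytest.approx(expected, abs=5e-4)

    def test_carbon_free_formula_rejected(self):
        with pytest.raises(ValueError):
            carbon_to_mass_yield(50.0, "H2O", "CH4O")

    def test_random_inputs_match_hand_arithmetic(self):
        rng = np.random.default_rng(11)
        formulas = ["C3H6O3", "C4H6O2", "C5H6O4", "C7H7NO2", "CH4O", "C6H12O6"]
        masses = {
            f: sum(
                ATOMIC_WEIGHTS[el] * n
                for el, n in __import__("methyloflux.formula", fromlist=["parse_formula"])
                .parse_formula(f)
                .items()
            )
            for f in formulas
        }
        for _ in range(100):
            cy = float(rng.uniform(0, 100))
            prod, sub = rng.choice(formulas, 2)
            expected = round(
                (cy / 100)
                * (masses[prod] / carbon_count(prod))
                / (masses[sub] / carbon_count(sub)),
                3,
            )
            assert carbon_to_mass_yield(cy, prod, sub) == expected

    @pytest.mark.parametrize(
        "titre,formula,expected_mM",
        [
            (284.0, "C3H6O3", 3.2),  # lactic acid
            (1000.0, "C5H6O4", 7.7),  # itaconic acid, bioreactor
            (138.9, "C5H6O4", 1.1),  # itaconic acid, shake flask
            (199.9, "C7H7NO2", 1.5),  # PABA
        ],
    )
    def test_titre_conversions(self, titre, formula, expected_mM):
        assert production_metrics(titre, formula).titre_mM == pytest.approx(expected_mM)

    def test_productivity_fold_change(self):
        flask = production_metrics(138.9, "C5H6O4", elapsed_h=138.9 / 1.85)
        assert flask.productivity_mg_per_l_h == pytest.approx(1.85)
        reactor = production_metrics(
            1000.0, "C5H6O4", elapsed_h=1000.0 / 15.0, reference=flask
        )
        assert reactor.fold_changes["productivity"] == pytest.approx(8.1)

    def test_non_positive_elapsed_time_rejected(self):
        with pytest.raises(ValueError):
            production_metrics(100.0, "C3H6O3", elapsed_h=0.0)

    def test_mass_yield_attached_when_requested(self):
        m = production_metrics(
            284.0, "C3H6O3", carbon_yield_percent=15.7, substrate_formula="CH4O"
        )
        assert m.mass_yield_g_per_g == pytest.approx(0.147, abs=5e-4)
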