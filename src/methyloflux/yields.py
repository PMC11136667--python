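"""Theoretical product yields and production-metric arithmetic.

The theoretical carbon yield of a product P from a substrate S is

    Y_C = 100 × (n_C(P) · v_P) / (n_C(S) · |v_S|)      [%]

where v_P is the maximal product exchange flux with growth fixed to zero
and v_S the fixed substrate uptake; n_C are carbon atoms per molecule. The
yield is an LP ceiling: it is invariant to the uptake magnitude and can
never exceed 100% when the substrate is the sole carbon source, which is
enforced here by closing the uptake of every other carbon-containing
exchange.

Unit conversions connect the model world to bench numbers: carbon yield →
mass yield (g product per g substrate) through per-carbon molar masses, and
titres (mg/l) → molar concentrations and volumetric productivities with
fold changes against a reference condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .extensions import PRODUCTS, SUBSTRATES, build_production_model
from .formula import carbon_count, molar_mass
from .lp import FEASIBILITY_TOL, solve_fba
from .model import MetabolicModel

__all__ = [
    "YieldResult",
    "ProductionMetrics",
    "theoretical_carbon_yield",
    "variant_yield_grid",
    "paba_glucose_yield_report",
    "carbon_to_mass_yield",
    "production_metrics",
]


@dataclass
class YieldResult:
    substrate_exchange_id: str
    product_exchange_id: str
    substrate_uptake: float
    product_flux: float
    carbon_yield_percent: float
    variant_tag: str = ""


@dataclass
class ProductionMetrics:
    titre_mg_per_l: float
    titre_mM: float
    carbon_yield_percent: float | None = None
    mass_yield_g_per_g: float | None = None
    productivity_mg_per_l_h: float | None = None
    fold_changes: dict[str, float] = field(default_factory=dict)


def _exchange_metabolite(model: MetabolicModel, reaction_id: str) -> str:
    rxn = model.reactions[reaction_id]
    if not rxn.is_exchange:
        raise ValueError(f"{reaction_id!r} is not an exchange/demand reaction")
    return next(iter(rxn.stoichiometry))


def _prepare_yield_model(
    model: MetabolicModel,
    substrate_exchange_id: str,
    atpm: str = "default",
) -> MetabolicModel:
    """Zero biomass, keep/drop maintenance, make the substrate the sole
    permitted carbon inflow."""
    m = model.copy()
    for rxn in m.reactions.values():
        if "biomass" in rxn.id.lower():
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    if atpm == "zero" and "ATPM" in m.reactions:
        m.reactions["ATPM"].lower_bound = 0.0
    elif atpm not in ("default", "zero"):
        raise ValueError(f"atpm must be 'default' or 'zero', got {atpm!r}")
    for rxn in m.reactions.values():
        if not rxn.is_exchange or rxn.id == substrate_exchange_id:
            continue
        met = m.metabolites[_exchange_metabolite(m, rxn.id)]
        if met.formula and carbon_count(met.formula) > 0 and rxn.lower_bound < 0:
            rxn.lower_bound = 0.0
    return m


def theoretical_carbon_yield(
    model: MetabolicModel,
    substrate_exchange_id: str,
    product_exchange_id: str,
    variant_tag: str = "",
    atpm: str = "default",
) -> YieldResult:
    """Maximal carbon-mole yield of a product from a fixed substrate uptake.

    The model must already carry the product pathway; the substrate
    exchange must have a negative lower bound (the uptake basis). Growth is
    fixed to zero and the objective switched to the product exchange.
    """
    for rid in (substrate_exchange_id, product_exchange_id):
        if rid not in model.reactions:
            raise KeyError(f"exchange {rid!r} not in model")
    uptake = model.reactions[substrate_exchange_id].lower_bound
    if uptake >= 0:
        raise ValueError(
            f"substrate exchange {substrate_exchange_id!r} has no uptake "
            f"(lower bound {uptake})"
        )
    m = _prepare_yield_model(model, substrate_exchange_id, atpm)
    sol = solve_fba(m, objective=product_exchange_id, sense="maximize")
    if not sol.optimal:
        raise RuntimeError(f"yield model does not solve: {sol.status}")
    v_product = sol.objective_value
    v_substrate = sol.fluxes[substrate_exchange_id]
    n_c_sub = model.metabolites[
        _exchange_metabolite(model, substrate_exchange_id)
    ].carbon_count
    n_c_prod = model.metabolites[
        _exchange_metabolite(model, product_exchange_id)
    ].carbon_count
    if n_c_sub == 0:
        raise ValueError("substrate contains no carbon")
    consumed = abs(v_substrate) if abs(v_substrate) > FEASIBILITY_TOL else abs(uptake)
    carbon_yield = 100.0 * n_c_prod * max(v_product, 0.0) / (n_c_sub * consumed)
    return YieldResult(
        substrate_exchange_id=substrate_exchange_id,
        product_exchange_id=product_exchange_id,
        substrate_uptake=float(-consumed),
        product_flux=float(v_product),
        carbon_yield_percent=float(carbon_yield),
        variant_tag=variant_tag,
    )


def variant_yield_grid(
    core: MetabolicModel,
    products: Iterable[str] = ("lactate", "phb", "itaconate", "paba"),
    substrates: Iterable[str] = ("methanol",),
    variants: Iterable[str] = ("ed_ta", "fba_ta"),
    atpm: str = "default",
    c1_salvage: bool = True,
) -> pd.DataFrame:
    """Cross-product table of theoretical carbon yields.

    ``wild_type`` in ``variants`` pairs with glucose; the RuMP variants
    pair with methanol. Combinations without the required uptake pathway
    report a zero yield.
    """
    rows = []
    for product in products:
        if product not in PRODUCTS:
            raise KeyError(f"unknown product {product!r}")
        for substrate in substrates:
            if substrate not in SUBSTRATES:
                raise KeyError(f"unknown substrate {substrate!r}")
            for variant in variants:
                model = build_production_model(
                    core, variant, product, c1_salvage=c1_salvage
                )
                sub_ex, uptake, _f = SUBSTRATES[substrate]
                if sub_ex not in model.reactions:
                    rows.append(
                        {
                            "product": product,
                            "substrate": substrate,
                            "variant": variant,
                            "carbon_yield_percent": 0.0,
                        }
                    )
                    continue
                model.reactions[sub_ex].lower_bound = -uptake
                res = theoretical_carbon_yield(
                    model,
                    sub_ex,
                    PRODUCTS[product][1],
                    variant_tag=variant,
                    atpm=atpm,
                )
                rows.append(
                    {
                        "product": product,
                        "substrate": substrate,
                        "variant": variant,
                        "carbon_yield_percent": res.carbon_yield_percent,
                    }
                )
    return pd.DataFrame(rows)


def paba_glucose_yield_report(core: MetabolicModel, uptake: float = 10.0) -> pd.DataFrame:
    """PABA-from-glucose yield under both amide-nitrogen accountings.

    The chorismate-pathway lump can charge the glutamine amide recharge
    (GLNS ATP) to the product pathway (``glutamine`` accounting, the
    shipped default) or source the amine from ammonium without that ATP
    (``ammonium``). The two accountings bracket the attainable ceiling;
    the table reports both, at default and zero ATP maintenance, as the
    sensitivity statement for this reconstruction-dependent number.
    """
    from .extensions import get_extension
    from .model import extend_model

    rows = []
    for accounting, ext_name in (
        ("glutamine", "product_paba"),
        ("ammonium", "product_paba_nh4"),
    ):
        model = extend_model(core, get_extension(ext_name))
        model.reactions["EX_glc__D_e"].lower_bound = -uptake
        for atpm in ("default", "zero"):
            res = theoretical_carbon_yield(
                model, "EX_glc__D_e", "EX_4abz_e", variant_tag="wild_type", atpm=atpm
            )
            rows.append(
                {
                    "accounting": accounting,
                    "atpm": atpm,
                    "carbon_yield_percent": res.carbon_yield_percent,
                }
            )
    return pd.DataFrame(rows)


def carbon_to_mass_yield(
    carbon_yield_percent: float,
    product_formula: str,
    substrate_formula: str,
) -> float:
    """Convert a carbon-mole yield to g product per g substrate.

    Uses per-carbon molar masses from standard atomic weights; reported to
    three decimals, matching the precision of bench yield reports.
    """
    n_c_p = carbon_count(product_formula)
    n_c_s = carbon_count(substrate_formula)
    if n_c_p == 0 or n_c_s == 0:
        raise ValueError("both formulas must contain carbon")
    mass_per_c_product = molar_mass(product_formula) / n_c_p
    mass_per_c_substrate = molar_mass(substrate_formula) / n_c_s
    return round(
        (carbon_yield_percent / 100.0) * mass_per_c_product / mass_per_c_substrate, 3
    )


def production_metrics(
    titre_mg_per_l: float,
    product_formula: str,
    elapsed_h: float | None = None,
    carbon_yield_percent: float | None = None,
    substrate_formula: str | None = None,
    reference: "ProductionMetrics | None" = None,
) -> ProductionMetrics:
    """Titre → mM, productivity and optional mass yield / fold changes.

    Molar concentrations and fold changes are rounded to one decimal, the
    mass yield to three, following the reporting precision of fermentation
    summaries.
    """
    if titre_mg_per_l < 0:
        raise ValueError("titre must be non-negative")
    titre_mM = round(titre_mg_per_l / molar_mass(product_formula), 1)
    productivity = None
    if elapsed_h is not None:
        if elapsed_h <= 0:
            raise ValueError("elapsed time must be positive")
        productivity = titre_mg_per_l / elapsed_h
    mass_yield = None
    if carbon_yield_percent is not None and substrate_formula is not None:
        mass_yield = carbon_to_mass_yield(
            carbon_yield_percent, product_formula, substrate_formula
        )
    metrics = ProductionMetrics(
        titre_mg_per_l=titre_mg_per_l,
        titre_mM=titre_mM,
        carbon_yield_percent=carbon_yield_percent,
        mass_yield_g_per_g=mass_yield,
        productivity_mg_per_l_h=productivity,
    )
    if reference is not None:
        folds: dict[str, float] = {}
        if reference.titre_mg_per_l > 0:
            folds["titre"] = round(titre_mg_per_l / reference.titre_mg_per_l, 1)
        if productivity is not None and reference.productivity_mg_per_l_h:
            folds["productivity"] = round(
                productivity / reference.productivity_mg_per_l_h, 1
            )
        metrics.fold_changes = folds
    return metrics
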