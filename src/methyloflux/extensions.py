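"""Shipped pathway-extension library and model builders.

The library reconstructs the pathway additions used to turn the *E. coli*
core network into a synthetic methylotroph and into production strains:

``rump_base``
    Methanol oxidation (MEDH), formaldehyde assimilation via the RuMP cycle
    (HPS, PHI), the sedoheptulose-1,7-bisphosphate regeneration branch
    (FBA3, SBP17BPase), the linear dissimilation branch to CO2 (FALDDH,
    FDH), the Entner-Doudoroff pair (EDD, EDA — absent from the core
    network), methanol transport/exchange, malic-enzyme knockouts and a
    closed glucose exchange.
``ed_ta`` / ``fba_ta``
    The two RuMP-cycle regeneration variants: ED/transaldolase (forced by a
    triosephosphate-isomerase knockout, as in the evolved strain) versus
    fructose-bisphosphate-aldolase/transaldolase (ED branch closed, TPI
    retained).
``c1_salvage``
    Opens the C1 oxidation branch in both directions so formate/CO2 carbon
    can re-enter the formaldehyde pool. Used for theoretical-yield ceilings
    (see docs/methods.md); growth simulations keep the branch oxidative.
``product_*``
    One extension per bioproduct: L-lactate (LDH), PHB monomer (phaCAB
    lump with a demand sink), itaconate (cis-aconitate decarboxylase) and
    PABA (chorismate-pathway lump), each with export and exchange.
"""

from __future__ import annotations

from importlib import resources

from .model import MetabolicModel, PathwayExtension, extend_model, load_model

__all__ = [
    "EXTENSION_NAMES",
    "PRODUCTS",
    "SUBSTRATES",
    "get_extension",
    "load_core_model",
    "build_methylotroph",
    "build_production_model",
]

EXTENSION_NAMES = (
    "rump_base",
    "ed_ta",
    "fba_ta",
    "c1_salvage",
    "product_lactate",
    "product_phb",
    "product_itaconate",
    "product_paba",
    "product_paba_nh4",
)

#: product name → (extension name, product exchange/demand reaction, formula)
PRODUCTS: dict[str, tuple[str, str, str]] = {
    "lactate": ("product_lactate", "EX_lac__L_e", "C3H6O3"),
    "phb": ("product_phb", "DM_phb_c", "C4H6O2"),
    "itaconate": ("product_itaconate", "EX_itacon_e", "C5H6O4"),
    "paba": ("product_paba", "EX_4abz_e", "C7H7NO2"),
}

#: substrate name → (exchange reaction, default uptake in mmol/gDW/h, formula)
SUBSTRATES: dict[str, tuple[str, float, str]] = {
    "methanol": ("EX_meoh_e", 60.0, "CH4O"),
    "glucose": ("EX_glc__D_e", 10.0, "C6H12O6"),
}


def get_extension(name: str) -> PathwayExtension:
    """Load a shipped extension by name."""
    if name not in EXTENSION_NAMES:
        raise KeyError(
            f"unknown extension {name!r}; shipped: {', '.join(EXTENSION_NAMES)}"
        )
    ref = resources.files("methyloflux.data.extensions") / f"{name}.yaml"
    with resources.as_file(ref) as path:
        return PathwayExtension.from_yaml(path)


def load_core_model() -> MetabolicModel:
    """The bundled *E. coli* core model (72 metabolites, 95 reactions)."""
    ref = resources.files("methyloflux.data") / "e_coli_core.json"
    with resources.as_file(ref) as path:
        return load_model(path, format="json")


def build_methylotroph(
    core: MetabolicModel, variant: str = "ed_ta"
) -> MetabolicModel:
    """Core network + RuMP-cycle extension in the requested variant.

    ``variant`` is ``ed_ta`` (TPI knocked out, Entner-Doudoroff routing, as
    in the evolved methylotroph), ``fba_ta`` (TPI retained, ED closed) or
    ``wild_type`` (the unmodified core network, for glucose baselines).
    """
    if variant == "wild_type":
        return core.copy()
    if variant not in ("ed_ta", "fba_ta"):
        raise KeyError(f"unknown RuMP variant {variant!r}")
    model = extend_model(core, get_extension("rump_base"))
    model = extend_model(model, get_extension(variant))
    model.id = f"methylotroph_{variant}"
    return model


def build_production_model(
    core: MetabolicModel,
    variant: str,
    product: str,
    c1_salvage: bool = False,
) -> MetabolicModel:
    """Methylotroph (or wild-type) model carrying one product pathway.

    With ``c1_salvage=True`` (used for theoretical-yield ceilings) the C1
    oxidation branch of a methylotroph model is made reversible; the flag is
    ignored for the wild-type model, which has no C1 branch.
    """
    if product not in PRODUCTS:
        raise KeyError(f"unknown product {product!r}; known: {', '.join(PRODUCTS)}")
    model = build_methylotroph(core, variant)
    model = extend_model(model, get_extension(PRODUCTS[product][0]))
    if c1_salvage and variant != "wild_type":
        model = extend_model(model, get_extension("c1_salvage"))
    model.id = f"{variant}_{product}"
    return model
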