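"""Stoichiometric models: containers, I/O and pathway-extension algebra.

The in-memory representation is deliberately small: a model is metabolites,
reactions with signed stoichiometry and flux bounds, and one objective
reaction. Two interchange dialects are supported — BIGG-style JSON and SBML
Level 3 with the FBC package (read/written through libsbml). A
:class:`PathwayExtension` is a named bundle of reaction additions, removals
(knockout = both bounds forced to 0) and bound changes, which is how the
methylotroph (RuMP cycle) and production models are built from the
*E. coli* core network.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .formula import carbon_count, parse_formula

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "PathwayExtension",
    "ModelError",
    "ParseError",
    "load_model",
    "write_model",
    "extend_model",
    "validate_mass_balance",
    "DEFAULT_BOUND",
]

DEFAULT_BOUND = 1000.0

#: elements checked by validate_mass_balance
BALANCE_ELEMENTS = ("C", "H", "O", "N", "P", "S")


class ModelError(ValueError):
    """Structural problem in a model or extension."""


class ParseError(ModelError):
    """A model file could not be interpreted in the declared format."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    charge: int | None = None

    @property
    def carbon_count(self) -> int:
        """Carbon atoms per molecule, 0 if the formula is unknown."""
        if not self.formula:
            return 0
        return carbon_count(self.formula)


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    name: str = ""
    gene_tag: str | None = None
    subsystem: str | None = None

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r} has empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def is_exchange(self) -> bool:
        """A boundary reaction touching exactly one metabolite."""
        return len(self.stoichiometry) == 1


@dataclass
class MetabolicModel:
    id: str = "model"
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    objective_reaction: str | None = None
    objective_sense: str = "maximize"

    # -- construction ------------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelError(f"duplicate reaction id {rxn.id!r}")
        missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
        if missing:
            raise ModelError(
                f"reaction {rxn.id!r} references unknown metabolites {missing}"
            )
        self.reactions[rxn.id] = rxn

    def copy(self) -> "MetabolicModel":
        return copy.deepcopy(self)

    def validate(self) -> None:
        """Check the container invariants; raise ModelError on violation."""
        for rxn in self.reactions.values():
            for met in rxn.stoichiometry:
                if met not in self.metabolites:
                    raise ModelError(
                        f"reaction {rxn.id!r} references unknown metabolite {met!r}"
                    )
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelError(f"reaction {rxn.id!r} has inverted bounds")
        if (
            self.objective_reaction is not None
            and self.objective_reaction not in self.reactions
        ):
            raise ModelError(
                f"objective reaction {self.objective_reaction!r} not in model"
            )

    # -- matrix view -------------------------------------------------------
    def stoichiometric_matrix(self):
        """Dense S matrix plus row (metabolite) and column (reaction) orders."""
        import numpy as np

        met_ids = list(self.metabolites)
        rxn_ids = list(self.reactions)
        met_index = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for mid, coef in self.reactions[rid].stoichiometry.items():
                S[met_index[mid], j] = coef
        return S, met_ids, rxn_ids


# ---------------------------------------------------------------------------
# I/O: BIGG-style JSON
# ---------------------------------------------------------------------------

def _model_from_bigg_dict(doc: Mapping) -> MetabolicModel:
    try:
        mets = doc["metabolites"]
        rxns = doc["reactions"]
    except (KeyError, TypeError) as exc:
        raise ParseError(f"missing top-level key: {exc}") from None
    model = MetabolicModel(id=doc.get("id", "model"))
    for m in mets:
        try:
            model.add_metabolite(
                Metabolite(
                    id=m["id"],
                    name=m.get("name", ""),
                    compartment=m.get("compartment", "c"),
                    formula=m.get("formula"),
                    charge=m.get("charge"),
                )
            )
        except KeyError as exc:
            raise ParseError(f"metabolite record lacks {exc}") from None
    objective = None
    for r in rxns:
        try:
            rxn = Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["metabolites"].items()},
                lower_bound=float(r.get("lower_bound", -DEFAULT_BOUND)),
                upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                name=r.get("name", ""),
                gene_tag=r.get("gene_reaction_rule") or None,
                subsystem=r.get("subsystem") or None,
            )
        except KeyError as exc:
            raise ParseError(f"reaction record lacks {exc}") from None
        model.add_reaction(rxn)
        if float(r.get("objective_coefficient", 0.0)) != 0.0:
            objective = rxn.id
    if objective is None:
        # BIGG convention: biomass reaction is the default objective
        for rid in model.reactions:
            if "biomass" in rid.lower():
                objective = rid
                break
    model.objective_reaction = objective
    model.validate()
    return model


def _model_to_bigg_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                **({"formula": m.formula} if m.formula else {}),
                **({"charge": m.charge} if m.charge is not None else {}),
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                **(
                    {"objective_coefficient": 1.0}
                    if r.id == model.objective_reaction
                    else {}
                ),
                **({"subsystem": r.subsystem} if r.subsystem else {}),
                **({"gene_reaction_rule": r.gene_tag} if r.gene_tag else {}),
            }
            for r in model.reactions.values()
        ],
        "genes": [],
    }


# ---------------------------------------------------------------------------
# I/O: SBML Level 3 + FBC (via libsbml)
# ---------------------------------------------------------------------------

def _model_from_sbml(path: str | Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ParseError(f"SBML error: {err.getMessage() if err else 'unreadable'}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ParseError("SBML document contains no model")
    model = MetabolicModel(id=sbml_model.getId() or "model")

    def _unprefix(sid: str) -> str:
        return sid[2:] if sid.startswith(("M_", "R_")) else sid

    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        fbc = sp.getPlugin("fbc")
        model.add_metabolite(
            Metabolite(
                id=_unprefix(sp.getId()),
                name=sp.getName(),
                compartment=sp.getCompartment(),
                formula=(fbc.getChemicalFormula() or None) if fbc else None,
                charge=(fbc.getCharge() if fbc and fbc.isSetCharge() else None),
            )
        )
    params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            mid = _unprefix(ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            mid = _unprefix(ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        fbc = rx.getPlugin("fbc")
        lb = params.get(fbc.getLowerFluxBound(), -DEFAULT_BOUND) if fbc else -DEFAULT_BOUND
        ub = params.get(fbc.getUpperFluxBound(), DEFAULT_BOUND) if fbc else DEFAULT_BOUND
        model.add_reaction(
            Reaction(
                id=_unprefix(rx.getId()),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                name=rx.getName(),
            )
        )
    fbc_model = sbml_model.getPlugin("fbc")
    if fbc_model is not None and fbc_model.getNumObjectives() > 0:
        obj = fbc_model.getActiveObjective() or fbc_model.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            model.objective_reaction = _unprefix(
                obj.getFluxObjective(0).getReaction()
            )
            model.objective_sense = (
                "maximize" if obj.getType() == "maximize" else "minimize"
            )
    model.validate()
    return model


def _model_to_sbml(model: MetabolicModel, path: str | Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(model.id)
    fbc_model = sbml_model.getPlugin("fbc")
    fbc_model.setStrict(True)

    compartments = {m.compartment for m in model.metabolites.values()}
    for comp in sorted(compartments):
        c = sbml_model.createCompartment()
        c.setId(comp)
        c.setConstant(True)

    for met in model.metabolites.values():
        sp = sbml_model.createSpecies()
        sp.setId("M_" + met.id)
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        fbc = sp.getPlugin("fbc")
        if met.formula:
            fbc.setChemicalFormula(met.formula)
        if met.charge is not None:
            fbc.setCharge(int(met.charge))

    bound_params: dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(float(value))
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions.values():
        rx = sbml_model.createReaction()
        rx.setId("R_" + rxn.id)
        rx.setName(rxn.name)
        rx.setFast(False)
        rx.setReversible(rxn.lower_bound < 0)
        for mid, coef in rxn.stoichiometry.items():
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies("M_" + mid)
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        fbc = rx.getPlugin("fbc")
        fbc.setLowerFluxBound(_bound_param(rxn.lower_bound))
        fbc.setUpperFluxBound(_bound_param(rxn.upper_bound))

    if model.objective_reaction is not None:
        obj = fbc_model.createObjective()
        obj.setId("obj")
        obj.setType(model.objective_sense)
        fo = obj.createFluxObjective()
        fo.setReaction("R_" + model.objective_reaction)
        fo.setCoefficient(1.0)
        fbc_model.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


def load_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Load a model from BIGG-style JSON or SBML L3+FBC.

    The format is inferred from the suffix when not given (``.json`` vs
    ``.xml``/``.sbml``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "sbml"
    if format == "json":
        try:
            with open(path) as fh:
                doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"not valid JSON: {exc}") from None
        return _model_from_bigg_dict(doc)
    if format == "sbml":
        return _model_from_sbml(path)
    raise ValueError(f"unknown format {format!r}")


def write_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    """Write a model as BIGG-style JSON or SBML L3+FBC."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "sbml"
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_model_to_bigg_dict(model), fh, indent=1)
    elif format == "sbml":
        _model_to_sbml(model, path)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Pathway extensions
# ---------------------------------------------------------------------------

@dataclass
class PathwayExtension:
    """A named, reusable bundle of model edits.

    ``add`` supplies new reactions (with any new metabolites listed in
    ``new_metabolites``); ``remove`` knocks reactions out by forcing both
    bounds to zero; ``bound_changes`` rewrites flux bounds.
    """

    name: str
    add: list[Reaction] = field(default_factory=list)
    new_metabolites: list[Metabolite] = field(default_factory=list)
    remove: list[str] = field(default_factory=list)
    bound_changes: dict[str, tuple[float, float]] = field(default_factory=dict)

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "metabolites": [
                {
                    "id": m.id,
                    "name": m.name,
                    "compartment": m.compartment,
                    "formula": m.formula,
                    "charge": m.charge,
                }
                for m in self.new_metabolites
            ],
            "add": [
                {
                    "id": r.id,
                    "name": r.name,
                    "metabolites": dict(r.stoichiometry),
                    "lower_bound": r.lower_bound,
                    "upper_bound": r.upper_bound,
                }
                for r in self.add
            ],
            "remove": list(self.remove),
            "bound_changes": {k: list(v) for k, v in self.bound_changes.items()},
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "PathwayExtension":
        return cls(
            name=doc["name"],
            new_metabolites=[
                Metabolite(
                    id=m["id"],
                    name=m.get("name", ""),
                    compartment=m.get("compartment", "c"),
                    formula=m.get("formula"),
                    charge=m.get("charge"),
                )
                for m in doc.get("metabolites", [])
            ],
            add=[
                Reaction(
                    id=r["id"],
                    stoichiometry={k: float(v) for k, v in r["metabolites"].items()},
                    lower_bound=float(r.get("lower_bound", -DEFAULT_BOUND)),
                    upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                    name=r.get("name", ""),
                )
                for r in doc.get("add", [])
            ],
            remove=list(doc.get("remove", [])),
            bound_changes={
                k: (float(v[0]), float(v[1]))
                for k, v in doc.get("bound_changes", {}).items()
            },
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PathwayExtension":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def extend_model(model: MetabolicModel, ext: PathwayExtension) -> MetabolicModel:
    """Apply a pathway extension, returning a new model.

    The input model is never mutated. Knockouts set lb = ub = 0 so the
    reaction stays in the network (and can be re-opened by a later bound
    change), mirroring how a gene deletion leaves the reaction column in S.
    """
    out = model.copy()
    for rid in ext.remove:
        if rid not in out.reactions:
            raise ModelError(f"extension {ext.name!r} removes unknown reaction {rid!r}")
    for met in ext.new_metabolites:
        if met.id not in out.metabolites:
            out.add_metabolite(copy.deepcopy(met))
    for rxn in ext.add:
        if rxn.id in out.reactions:
            raise ModelError(
                f"extension {ext.name!r} adds reaction {rxn.id!r} which already exists"
            )
        out.add_reaction(copy.deepcopy(rxn))
    for rid in ext.remove:
        out.reactions[rid].lower_bound = 0.0
        out.reactions[rid].upper_bound = 0.0
    for rid, (lb, ub) in ext.bound_changes.items():
        if rid not in out.reactions:
            raise ModelError(
                f"extension {ext.name!r} changes bounds of unknown reaction {rid!r}"
            )
        out.reactions[rid].lower_bound = lb
        out.reactions[rid].upper_bound = ub
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Mass balance audit
# ---------------------------------------------------------------------------

def validate_mass_balance(
    model: MetabolicModel,
    elements: Iterable[str] = BALANCE_ELEMENTS,
    exempt: Iterable[str] = (),
) -> dict[str, dict[str, float] | str]:
    """Per-reaction elemental imbalance report.

    Exchange/demand reactions (single metabolite) and biomass reactions are
    exempt by convention. A reaction touching a metabolite without a formula
    is flagged ``"unknown"`` rather than failed. The returned mapping only
    contains problematic reactions; an empty dict means fully balanced.
    """
    elements = tuple(elements)
    exempt = set(exempt)
    report: dict[str, dict[str, float] | str] = {}
    for rxn in model.reactions.values():
        if rxn.id in exempt or rxn.is_exchange or "biomass" in rxn.id.lower():
            continue
        net: dict[str, float] = {}
        unknown = False
        for mid, coef in rxn.stoichiometry.items():
            met = model.metabolites[mid]
            if not met.formula:
                unknown = True
                break
            for element, n in parse_formula(met.formula).items():
                net[element] = net.get(element, 0.0) + coef * n
        if unknown:
            report[rxn.id] = "unknown"
            continue
        imbalance = {
            e: round(net.get(e, 0.0), 9) for e in elements if abs(net.get(e, 0.0)) > 1e-9
        }
        if imbalance:
            report[rxn.id] = imbalance
    return report
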