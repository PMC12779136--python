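"""Stoichiometric model container and readers/writers.

The in-memory representation is deliberately small: metabolites, reactions
with bounds / subsystem / GPR, and one biomass objective.  Two on-disk
formats are supported, the community COBRA JSON dialect (read/write, so
Human1-style distributions load without transformation) and SBML Level 3
with the FBC package (read only: bounds, objective and gene associations).
Infinite or oversized bounds are canonicalized to +/-1000 so downstream
big-M MILP constraints stay well posed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

from .gpr import GPRExpression, parse_gpr

BOUND_CAP = 1000.0


class ModelValidationError(ValueError):
    pass


class ModelParseError(ValueError):
    pass


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    #: optional integer conservation tag (a lumped "carbon count") used by
    #: the toy-network balance checks; 0 marks currency/untracked species.
    mass_tag: int = 0


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -BOUND_CAP
    upper_bound: float = BOUND_CAP
    subsystem: str = ""
    gpr: GPRExpression | None = None
    is_exchange: bool = False

    def with_bounds(self, lb: float, ub: float) -> "Reaction":
        return replace(self, lower_bound=lb, upper_bound=ub)

    @property
    def gpr_string(self) -> str:
        return self.gpr.to_string() if self.gpr is not None else ""


def _canonical_bound(value: float) -> float:
    if value is None or math.isnan(value):
        raise ModelValidationError("bound is missing or NaN")
    return max(-BOUND_CAP, min(BOUND_CAP, float(value)))


@dataclass
class MetabolicNetwork:
    """A genome-scale (or toy) metabolic network with a biomass objective."""

    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    objective_reaction: str
    compartments: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups -----------------------------------------------------------
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions:
            if r.gpr is not None:
                out |= r.gpr.genes()
        return out

    def subsystems(self) -> set[str]:
        return {r.subsystem or "Unassigned" for r in self.reactions}

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        declared = set(met_ids)
        for r in self.reactions:
            for met in r.stoichiometry:
                if met not in declared:
                    raise ModelParseError(
                        f"reaction {r.id!r} references undeclared metabolite {met!r}"
                    )
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(
                    f"reaction {r.id!r} has lower_bound > upper_bound"
                )
        if self.objective_reaction not in set(rxn_ids):
            raise ModelValidationError(
                f"objective reaction {self.objective_reaction!r} not in model"
            )
        self.compartments = {m.compartment for m in self.metabolites if m.compartment}

    def stoichiometric_matrix(self):
        """Dense S matrix (metabolites x reactions) as a numpy array."""
        import numpy as np

        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met, coef in r.stoichiometry.items():
                S[met_index[met], j] = coef
        return S


# ---------------------------------------------------------------------------
# COBRA-style JSON dialect
# ---------------------------------------------------------------------------

def network_to_json_dict(net: MetabolicNetwork) -> dict:
    return {
        "id": net.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "notes": {"mass_tag": m.mass_tag},
            }
            for m in net.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "metabolites": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "subsystem": r.subsystem,
                "gene_reaction_rule": r.gpr_string,
                "objective_coefficient": 1.0 if r.id == net.objective_reaction else 0.0,
            }
            for r in net.reactions
        ],
        "genes": [{"id": g} for g in sorted(net.genes())],
        "compartments": {c: c for c in sorted(net.compartments)},
    }


def _network_from_json_dict(doc: dict) -> MetabolicNetwork:
    try:
        raw_mets = doc["metabolites"]
        raw_rxns = doc["reactions"]
    except KeyError as exc:
        raise ModelParseError(f"JSON model missing section {exc}") from exc
    mets = [
        Metabolite(
            id=m["id"],
            name=m.get("name", ""),
            compartment=m.get("compartment", ""),
            mass_tag=int((m.get("notes") or {}).get("mass_tag", 0)),
        )
        for m in raw_mets
    ]
    rxns = []
    objective = None
    for r in raw_rxns:
        stoich = {k: float(v) for k, v in r.get("metabolites", {}).items()}
        lb = _canonical_bound(r.get("lower_bound", -BOUND_CAP))
        ub = _canonical_bound(r.get("upper_bound", BOUND_CAP))
        gpr = parse_gpr(r.get("gene_reaction_rule", ""))
        is_exchange = bool(r.get("is_exchange", len(stoich) == 1))
        rxns.append(
            Reaction(
                id=r["id"],
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                subsystem=r.get("subsystem", "") or "",
                gpr=gpr,
                is_exchange=is_exchange,
            )
        )
        if float(r.get("objective_coefficient", 0.0)) != 0.0:
            objective = r["id"]
    if objective is None:
        raise ModelParseError("model declares no objective reaction")
    return MetabolicNetwork(
        id=doc.get("id", "model"),
        metabolites=mets,
        reactions=rxns,
        objective_reaction=objective,
    )


def write_metabolic_model(net: MetabolicNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(network_to_json_dict(net), fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# SBML L3 + FBC subset
# ---------------------------------------------------------------------------

def _strip_sbml_prefix(sid: str, prefix: str) -> str:
    """SBML ids conventionally carry R_/M_/G_ type prefixes; strip them."""
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _gpr_from_fbc_association(assoc) -> str:
    """Render a libsbml FbcAssociation subtree as GPR text."""
    import libsbml

    if assoc is None:
        return ""
    if isinstance(assoc, libsbml.GeneProductRef):
        return _strip_sbml_prefix(assoc.getGeneProduct(), "G_")
    if isinstance(assoc, libsbml.FbcAnd):
        parts = [
            _gpr_from_fbc_association(assoc.getAssociation(i))
            for i in range(assoc.getNumAssociations())
        ]
        return "(" + " and ".join(parts) + ")"
    if isinstance(assoc, libsbml.FbcOr):
        parts = [
            _gpr_from_fbc_association(assoc.getAssociation(i))
            for i in range(assoc.getNumAssociations())
        ]
        return "(" + " or ".join(parts) + ")"
    raise ModelParseError(f"unsupported FBC association node {type(assoc).__name__}")


def _read_sbml(path: str) -> MetabolicNetwork:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(f"SBML parse error: {err.getMessage().strip()}")
    model = doc.getModel()
    if model is None:
        raise ModelParseError("SBML file contains no model element")

    params = {
        model.getParameter(i).getId(): model.getParameter(i).getValue()
        for i in range(model.getNumParameters())
    }
    mets = []
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        if sp.getBoundaryCondition():
            continue
        mets.append(
            Metabolite(
                id=_strip_sbml_prefix(sp.getId(), "M_"),
                name=sp.getName() or "",
                compartment=sp.getCompartment(),
            )
        )

    fbc_model = model.getPlugin("fbc")
    objective_id = None
    if fbc_model is not None and fbc_model.getNumObjectives() > 0:
        obj = fbc_model.getActiveObjective() or fbc_model.getObjective(0)
        for i in range(obj.getNumFluxObjectives()):
            fo = obj.getFluxObjective(i)
            if fo.getCoefficient() != 0.0:
                objective_id = _strip_sbml_prefix(fo.getReaction(), "R_")
    if objective_id is None:
        raise ModelParseError("SBML/FBC model declares no active objective reaction")

    boundary = {
        model.getSpecies(i).getId()
        for i in range(model.getNumSpecies())
        if model.getSpecies(i).getBoundaryCondition()
    }
    rxns = []
    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            if sr.getSpecies() in boundary:
                continue
            met = _strip_sbml_prefix(sr.getSpecies(), "M_")
            stoich[met] = stoich.get(met, 0.0) - sr.getStoichiometry()
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            if sr.getSpecies() in boundary:
                continue
            met = _strip_sbml_prefix(sr.getSpecies(), "M_")
            stoich[met] = stoich.get(met, 0.0) + sr.getStoichiometry()

        fbc_rxn = rx.getPlugin("fbc")
        lb, ub = -BOUND_CAP, BOUND_CAP
        gpr_text = ""
        if fbc_rxn is not None:
            if fbc_rxn.isSetLowerFluxBound():
                lb = params.get(fbc_rxn.getLowerFluxBound(), -BOUND_CAP)
            if fbc_rxn.isSetUpperFluxBound():
                ub = params.get(fbc_rxn.getUpperFluxBound(), BOUND_CAP)
            gpa = fbc_rxn.getGeneProductAssociation()
            if gpa is not None:
                gpr_text = _gpr_from_fbc_association(gpa.getAssociation())
        rxns.append(
            Reaction(
                id=_strip_sbml_prefix(rx.getId(), "R_"),
                stoichiometry=stoich,
                lower_bound=_canonical_bound(lb),
                upper_bound=_canonical_bound(ub),
                subsystem="",
                gpr=parse_gpr(gpr_text),
                is_exchange=len(stoich) <= 1,
            )
        )

    return MetabolicNetwork(
        id=model.getId() or "sbml_model",
        metabolites=mets,
        reactions=rxns,
        objective_reaction=objective_id,
    )


def read_metabolic_model(path, format: str = "json") -> MetabolicNetwork:
    """Read a metabolic network from COBRA-style JSON or SBML L3/FBC.

    Unbounded or oversized flux bounds are capped at +/-1000.
    """
    if format == "json":
        with open(path) as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ModelParseError(f"malformed JSON model: {exc}") from exc
        return _network_from_json_dict(doc)
    if format == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {format!r} (expected 'json' or 'sbml')")
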