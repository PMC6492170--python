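"""SBML input/output.

Reads Level 3 + fbc documents as well as legacy Level 2 COBRA-style
files (bounds in kinetic-law parameters, GPR in ``GENE_ASSOCIATION``
notes). Always writes Level 3 + fbc, with SBO terms identifying
pseudo-metabolites (SBO:0000409), enzyme species and exchange
reactions, so documents round-trip to structurally equal models.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional

import libsbml

from .gpr import GPR, And, Gene, Or, parse_gpr
from .model import (
    DEFAULT_INF_BOUND,
    MetabolicModel,
    Reaction,
    SBO_PSEUDO_METABOLITE,
    Species,
    SpeciesCategory,
)

__all__ = ["read_sbml", "write_sbml"]

_SBO_ENZYME = "SBO:0000014"
_SBO_EXCHANGE = "SBO:0000627"


# ---------------------------------------------------------------------------
# notes helpers (COBRA-style key/value paragraphs)
# ---------------------------------------------------------------------------

def _notes_xml(pairs: Dict[str, str]) -> str:
    body = "".join(
        f'<p>{k}: {v}</p>' for k, v in pairs.items()
    )
    return (
        '<notes><body xmlns="http://www.w3.org/1999/xhtml">'
        + body
        + "</body></notes>"
    )


def _parse_notes(node) -> Dict[str, str]:
    out: Dict[str, str] = {}
    if node is None:
        return out
    text = libsbml.XMLNode.convertXMLNodeToString(node)
    import re

    for match in re.finditer(r"<p[^>]*>(.*?)</p>", text, re.S):
        line = re.sub(r"<[^>]+>", "", match.group(1)).strip()
        sep = ": " if ": " in line else ":"
        if sep in line:
            key, value = line.split(sep, 1)
            out[key.strip()] = value.strip()
    return out


def _set_notes(element, pairs: Dict[str, str]) -> None:
    if pairs:
        element.setNotes(_notes_xml(pairs))


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _check(code: int, what: str) -> None:
    if code not in (libsbml.LIBSBML_OPERATION_SUCCESS, None):
        raise RuntimeError(f"libsbml failure while setting {what} (code {code})")


def write_sbml(model: MetabolicModel, path: str) -> str:
    """Serialise *model* to an SBML Level 3 + fbc version 2 document."""
    model.validate()

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(model.id)
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(False)

    model_notes = {"default_growth_rate": repr(model.default_growth_rate)}
    for k, v in model.annotations.items():
        model_notes[f"x-{k}"] = str(v)
    _set_notes(sbml_model, model_notes)

    for cid in model.compartments:
        comp = sbml_model.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)

    for sp in model.species:
        s = sbml_model.createSpecies()
        _check(s.setId(sp.id), f"species id {sp.id!r}")
        s.setName(sp.name or sp.id)
        s.setCompartment(sp.compartment)
        s.setConstant(False)
        s.setBoundaryCondition(False)
        s.setHasOnlySubstanceUnits(False)
        s.setInitialAmount(0.0)
        sbo = sp.annotations.get("sbo")
        if sp.category is SpeciesCategory.PSEUDO_METABOLITE:
            sbo = SBO_PSEUDO_METABOLITE
        elif sp.category is SpeciesCategory.ENZYME_SPECIES and not sbo:
            sbo = _SBO_ENZYME
        if sbo:
            s.setSBOTerm(sbo)
        notes = {"category": sp.category.value}
        for k, v in sp.annotations.items():
            if k != "sbo":
                notes[f"x-{k}"] = str(v)
        _set_notes(s, notes)

    # flux-bound parameters (deduplicated by value)
    bound_param: Dict[float, str] = {}

    def _bound_id(value: float) -> str:
        if value not in bound_param:
            pid = f"fb_{len(bound_param)}"
            par = sbml_model.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_param[value] = pid
        return bound_param[value]

    for gene in sorted(model.genes):
        gp = mplug.createGeneProduct()
        _check(gp.setId(gene), f"gene product id {gene!r}")
        gp.setLabel(gene)

    for rxn in model.reactions:
        r = sbml_model.createReaction()
        _check(r.setId(rxn.id), f"reaction id {rxn.id!r}")
        r.setName(rxn.name or rxn.id)
        r.setReversible(rxn.lower_bound < 0)
        r.setFast(False)
        if rxn.is_exchange:
            r.setSBOTerm(_SBO_EXCHANGE)

        literal = rxn.literal_cofactors()
        for sid, coeff in sorted(rxn.stoichiometry.items()):
            extra = literal.get(sid, 0.0)
            if coeff < 0 or (coeff == 0 and sid in literal):
                ref = r.createReactant()
                ref.setSpecies(sid)
                ref.setStoichiometry(-coeff + extra if coeff < 0 else extra)
                ref.setConstant(True)
            if coeff > 0 or (coeff == 0 and sid in literal):
                ref = r.createProduct()
                ref.setSpecies(sid)
                ref.setStoichiometry(coeff + extra if coeff > 0 else extra)
                ref.setConstant(True)
        for sid, x in sorted(literal.items()):
            if sid not in rxn.stoichiometry:
                ra = r.createReactant()
                ra.setSpecies(sid)
                ra.setStoichiometry(x)
                ra.setConstant(True)
                pa = r.createProduct()
                pa.setSpecies(sid)
                pa.setStoichiometry(x)
                pa.setConstant(True)

        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(_bound_id(rxn.lower_bound))
        rplug.setUpperFluxBound(_bound_id(rxn.upper_bound))
        if rxn.gpr is not None:
            gpa = rplug.createGeneProductAssociation()
            gpa.setAssociation(rxn.gpr_string)

        notes = {}
        if rxn.membrane_spanning:
            notes["membrane_spanning"] = "true"
        if rxn.is_exchange:
            notes["is_exchange"] = "true"
        for k, v in rxn.annotations.items():
            notes[f"x-{k}"] = str(v)
        _set_notes(r, notes)

    if model.objective is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(model.objective)
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    writer = libsbml.SBMLWriter()
    if not writer.writeSBMLToFile(doc, str(path)):
        raise IOError(f"could not write SBML document to {path!r}")
    return str(path)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _association_to_gpr(assoc) -> Optional[GPR]:
    if assoc is None:
        return None
    if isinstance(assoc, libsbml.GeneProductRef):
        gp = assoc.getSBMLDocument().getModel().getPlugin("fbc").getGeneProduct(
            assoc.getGeneProduct()
        )
        label = gp.getLabel() if gp is not None and gp.getLabel() else assoc.getGeneProduct()
        return Gene(label)
    if isinstance(assoc, libsbml.FbcAnd):
        return And(
            _association_to_gpr(assoc.getAssociation(i))
            for i in range(assoc.getNumAssociations())
        )
    if isinstance(assoc, libsbml.FbcOr):
        return Or(
            _association_to_gpr(assoc.getAssociation(i))
            for i in range(assoc.getNumAssociations())
        )
    raise ValueError(f"unsupported gene association node {assoc!r}")


def _bounds_from_kinetic_law(r) -> tuple[Optional[float], Optional[float]]:
    kl = r.getKineticLaw()
    if kl is None:
        return None, None
    lb = ub = None
    for i in range(kl.getNumParameters()):
        par = kl.getParameter(i)
        if par.getId().upper() == "LOWER_BOUND":
            lb = par.getValue()
        elif par.getId().upper() == "UPPER_BOUND":
            ub = par.getValue()
    return lb, ub


def read_sbml(path: str, require_objective: bool = False) -> MetabolicModel:
    """Parse an SBML file into a :class:`MetabolicModel`.

    Accepts Level 3 + fbc and Level 2 COBRA-notes dialects. Species
    categories are inferred from SBO terms / notes where present and
    default to ``metabolite``.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise ValueError(
                f"malformed SBML in {path!r}, line {err.getLine()}: "
                f"{err.getMessage().strip()}"
            )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ValueError(f"{path!r} contains no SBML model element")

    model = MetabolicModel(model_id=sbml_model.getId() or "model")
    notes = _parse_notes(sbml_model.getNotes())
    if "default_growth_rate" in notes:
        model.default_growth_rate = float(notes["default_growth_rate"])
    for k, v in notes.items():
        if k.startswith("x-"):
            model.annotations[k[2:]] = v

    for i in range(sbml_model.getNumCompartments()):
        model.add_compartment(sbml_model.getCompartment(i).getId())
    if not model.compartments:
        model.add_compartment("c")

    boundary_species = set()
    for i in range(sbml_model.getNumSpecies()):
        s = sbml_model.getSpecies(i)
        if s.getBoundaryCondition():
            boundary_species.add(s.getId())
            continue
        s_notes = _parse_notes(s.getNotes())
        sbo = s.getSBOTermID() if s.isSetSBOTerm() else s_notes.get("x-sbo", "")
        if sbo == SBO_PSEUDO_METABOLITE or s_notes.get("category") == "pseudo_metabolite":
            category = SpeciesCategory.PSEUDO_METABOLITE
        elif sbo == _SBO_ENZYME or s_notes.get("category") == "enzyme_species":
            category = SpeciesCategory.ENZYME_SPECIES
        else:
            category = SpeciesCategory.METABOLITE
        annotations = {k[2:]: v for k, v in s_notes.items() if k.startswith("x-")}
        if sbo:
            annotations["sbo"] = sbo
        compartment = s.getCompartment() or model.compartments[0]
        if compartment not in model.compartments:
            raise ValueError(
                f"species {s.getId()!r} placed in undeclared compartment "
                f"{compartment!r}"
            )
        model.add_species(
            Species(
                id=s.getId(),
                name=s.getName() or s.getId(),
                compartment=compartment,
                category=category,
                annotations=annotations,
            )
        )

    mplug = sbml_model.getPlugin("fbc")

    def _param_value(pid: str) -> Optional[float]:
        par = sbml_model.getParameter(pid)
        return par.getValue() if par is not None else None

    for i in range(sbml_model.getNumReactions()):
        r = sbml_model.getReaction(i)
        reactants: Dict[str, float] = {}
        products: Dict[str, float] = {}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            if ref.getSpecies() in boundary_species:
                continue
            reactants[ref.getSpecies()] = (
                reactants.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
            )
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            if ref.getSpecies() in boundary_species:
                continue
            products[ref.getSpecies()] = (
                products.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
            )

        stoich: Dict[str, float] = {}
        annotations: Dict[str, str] = {}
        for sid in set(reactants) | set(products):
            cons = reactants.get(sid, 0.0)
            prod = products.get(sid, 0.0)
            literal = min(cons, prod)
            if literal > 0:
                annotations[f"cofactor:{sid}"] = repr(literal)
            net = prod - cons
            if net != 0.0 or literal > 0:
                stoich[sid] = net

        lb = ub = None
        rplug = r.getPlugin("fbc")
        if rplug is not None and rplug.isSetLowerFluxBound():
            lb = _param_value(rplug.getLowerFluxBound())
        if rplug is not None and rplug.isSetUpperFluxBound():
            ub = _param_value(rplug.getUpperFluxBound())
        if lb is None and ub is None:
            lb, ub = _bounds_from_kinetic_law(r)
        if lb is None:
            lb = -DEFAULT_INF_BOUND if r.getReversible() else 0.0
        if ub is None:
            ub = DEFAULT_INF_BOUND
        lb = max(lb, -DEFAULT_INF_BOUND) if lb != float("-inf") else -DEFAULT_INF_BOUND
        ub = min(ub, DEFAULT_INF_BOUND) if ub != float("inf") else DEFAULT_INF_BOUND

        gpr: Optional[GPR] = None
        if rplug is not None and rplug.isSetGeneProductAssociation():
            gpr = _association_to_gpr(
                rplug.getGeneProductAssociation().getAssociation()
            )
        else:
            r_notes = _parse_notes(r.getNotes())
            assoc_text = r_notes.get("GENE_ASSOCIATION") or r_notes.get(
                "GENE ASSOCIATION"
            )
            if assoc_text:
                gpr = parse_gpr(assoc_text)

        r_notes = _parse_notes(r.getNotes())
        for k, v in r_notes.items():
            if k.startswith("x-"):
                annotations.setdefault(k[2:], v)
        is_exchange = (
            (r.isSetSBOTerm() and r.getSBOTermID() == _SBO_EXCHANGE)
            or r_notes.get("is_exchange") == "true"
            or len(stoich) <= 1
        )
        model.add_reaction(
            Reaction(
                id=r.getId(),
                name=r.getName() or r.getId(),
                stoichiometry=stoich,
                lower_bound=float(lb),
                upper_bound=float(ub),
                gpr=gpr,
                is_exchange=is_exchange,
                membrane_spanning=r_notes.get("membrane_spanning") == "true",
                annotations=annotations,
            )
        )

    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getActiveObjective() or mplug.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            model.objective = obj.getFluxObjective(0).getReaction()

    if model.objective is None and require_objective:
        raise ValueError(
            f"SBML file {path!r} declares no flux objective; set one with "
            "model.objective = '<biomass reaction id>' or add an fbc objective "
            "to the file"
        )

    model.validate()
    return model
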