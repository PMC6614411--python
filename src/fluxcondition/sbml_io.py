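"""SBML reading and writing via libSBML.

Reads Level 3 + fbc-v2 models (gene-product associations, flux-bound
parameters) as well as the older COBRA dialect in which bounds live in
kinetic-law parameters and GPRs in ``GENE_ASSOCIATION:`` note strings —
deposited liver models span both eras.  Writing always emits Level 3
Version 1 with fbc v2, with subsystems recorded both as reaction notes
and, on read, recovered from either notes or group annotations.
"""

from __future__ import annotations

import logging
import re
from typing import Dict, List, Optional

import libsbml

from .gpr import GPR, GPRParseError, parse_gpr
from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, ModelValidationError, Reaction

__all__ = ["read_sbml", "write_sbml"]

logger = logging.getLogger(__name__)

_NOTE_GPR = re.compile(r"GENE[ _]?ASSOCIATION:\s*([^<\n]*)", re.IGNORECASE)
_NOTE_SUBSYSTEM = re.compile(r"SUBSYSTEM:\s*([^<\n]*)", re.IGNORECASE)


def _sanitize(sid: str) -> str:
    out = re.sub(r"[^A-Za-z0-9_]", "_", sid)
    if not out or not (out[0].isalpha() or out[0] == "_"):
        out = "_" + out
    return out


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def read_sbml(path: str) -> MetabolicModel:
    """Read an SBML file into a :class:`MetabolicModel`.

    Raises ``FileNotFoundError`` for a missing file and
    ``ModelValidationError`` when a GPR string cannot be parsed (naming
    the offending reaction).
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getModel() is None:
        for i in range(doc.getNumErrors()):
            err = doc.getError(i)
            if err.getErrorId() == libsbml.XMLFileUnreadable:
                raise FileNotFoundError(f"cannot read SBML file: {path}")
        raise ModelValidationError(f"no model found in SBML file: {path}")
    smodel = doc.getModel()
    fbc = smodel.getPlugin("fbc")

    compartments = [smodel.getCompartment(i).getId() for i in range(smodel.getNumCompartments())]

    metabolites: List[Metabolite] = []
    boundary_species: set[str] = set()
    for i in range(smodel.getNumSpecies()):
        sp = smodel.getSpecies(i)
        if sp.getBoundaryCondition():
            boundary_species.add(sp.getId())
            continue
        metabolites.append(
            Metabolite(id=sp.getId(), name=sp.getName() or "", compartment=sp.getCompartment())
        )

    gene_labels = _gene_product_labels(fbc)

    reactions: List[Reaction] = []
    objective_id = _fbc_objective(smodel, fbc)
    for i in range(smodel.getNumReactions()):
        srxn = smodel.getReaction(i)
        stoich: Dict[str, float] = {}
        for j in range(srxn.getNumReactants()):
            ref = srxn.getReactant(j)
            if ref.getSpecies() in boundary_species:
                continue
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(srxn.getNumProducts()):
            ref = srxn.getProduct(j)
            if ref.getSpecies() in boundary_species:
                continue
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0}

        lb, ub = _read_bounds(smodel, srxn)
        if srxn.isSetReversible() and srxn.getReversible() != (lb < 0):
            logger.warning(
                "reaction %s: SBML reversible flag disagrees with bounds [%g, %g]; "
                "bounds take precedence",
                srxn.getId(), lb, ub,
            )
        gpr = _read_gpr(srxn, gene_labels)
        notes = srxn.getNotesString() if srxn.isSetNotes() else ""
        m = _NOTE_SUBSYSTEM.search(notes)
        subsystem = m.group(1).strip() if m else ""
        if objective_id is None:
            klaw = srxn.getKineticLaw()
            if klaw is not None:
                par = klaw.getParameter("OBJECTIVE_COEFFICIENT")
                if par is not None and par.getValue() != 0:
                    objective_id = srxn.getId()
        reactions.append(
            Reaction(
                id=srxn.getId(),
                name=srxn.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                subsystem=subsystem,
            )
        )

    model = MetabolicModel(
        id=smodel.getId() or "model",
        name=smodel.getName() or "",
        metabolites=metabolites,
        reactions=reactions,
        compartments=compartments,
        objective_reaction_id=objective_id,
    )
    _read_group_subsystems(smodel, model)
    return model


def _gene_product_labels(fbc) -> Dict[str, str]:
    labels: Dict[str, str] = {}
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            labels[gp.getId()] = gp.getLabel() or gp.getId()
    return labels


def _fbc_objective(smodel, fbc) -> Optional[str]:
    if fbc is None:
        return None
    obj = fbc.getActiveObjective()
    if obj is None and fbc.getNumObjectives() > 0:
        obj = fbc.getObjective(0)
    if obj is None or obj.getNumFluxObjectives() == 0:
        return None
    return obj.getFluxObjective(0).getReaction()


def _read_bounds(smodel, srxn) -> tuple[float, float]:
    rfbc = srxn.getPlugin("fbc")
    if rfbc is not None and rfbc.isSetLowerFluxBound():
        lb = smodel.getParameter(rfbc.getLowerFluxBound()).getValue()
        ub = smodel.getParameter(rfbc.getUpperFluxBound()).getValue()
        return lb, ub
    klaw = srxn.getKineticLaw()
    if klaw is not None:
        plb = klaw.getParameter("LOWER_BOUND")
        pub = klaw.getParameter("UPPER_BOUND")
        if plb is not None and pub is not None:
            return plb.getValue(), pub.getValue()
    if srxn.isSetReversible() and not srxn.getReversible():
        return 0.0, DEFAULT_BOUND
    return -DEFAULT_BOUND, DEFAULT_BOUND


def _read_gpr(srxn, gene_labels: Dict[str, str]) -> GPR:
    rfbc = srxn.getPlugin("fbc")
    if rfbc is not None and rfbc.getGeneProductAssociation() is not None:
        assoc = rfbc.getGeneProductAssociation().getAssociation()
        if assoc is None:
            return GPR()
        try:
            gpr = GPR(_association_to_node(assoc))
        except ValueError as exc:
            raise ModelValidationError(
                f"reaction {srxn.getId()}: unparsable gene association"
            ) from exc
        return gpr.map_genes(lambda g: gene_labels.get(g, g))
    notes = srxn.getNotesString() if srxn.isSetNotes() else ""
    m = _NOTE_GPR.search(notes)
    if m:
        text = m.group(1).strip()
        try:
            return parse_gpr(text)
        except GPRParseError as exc:
            raise ModelValidationError(
                f"reaction {srxn.getId()}: unparsable gene association {text!r}"
            ) from exc
    return GPR()


def _association_to_node(assoc):
    """Recursively convert an fbc association tree to a GPR node."""
    if isinstance(assoc, libsbml.GeneProductRef):
        return assoc.getGeneProduct()
    if isinstance(assoc, libsbml.FbcAnd):
        return ("and", [_association_to_node(assoc.getAssociation(i))
                        for i in range(assoc.getNumAssociations())])
    if isinstance(assoc, libsbml.FbcOr):
        return ("or", [_association_to_node(assoc.getAssociation(i))
                       for i in range(assoc.getNumAssociations())])
    raise ValueError(f"unsupported fbc association node: {type(assoc).__name__}")


def _read_group_subsystems(smodel, model: MetabolicModel) -> None:
    gplug = smodel.getPlugin("groups")
    if gplug is None:
        return
    from dataclasses import replace

    for i in range(gplug.getNumGroups()):
        grp = gplug.getGroup(i)
        name = grp.getName() or grp.getId()
        for j in range(grp.getNumMembers()):
            ref = grp.getMember(j).getIdRef()
            if model.has_reaction(ref):
                k = model.reaction_index(ref)
                if not model.reactions[k].subsystem:
                    model.reactions[k] = replace(model.reactions[k], subsystem=name)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def write_sbml(model: MetabolicModel, path: str) -> None:
    """Write a model as SBML Level 3 Version 1 with fbc v2."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    smodel = doc.createModel()
    smodel.setId(_sanitize(model.id))
    if model.name:
        smodel.setName(model.name)
    mplug = smodel.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = model.compartments or sorted({m.compartment for m in model.metabolites})
    for comp in compartments:
        c = smodel.createCompartment()
        c.setId(_sanitize(comp))
        c.setConstant(True)

    for met in model.metabolites:
        sp = smodel.createSpecies()
        sp.setId(_sanitize(met.id))
        if met.name:
            sp.setName(met.name)
        sp.setCompartment(_sanitize(met.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    genes = model.genes
    gene_sid = {g: "G_" + _sanitize(g) for g in genes}
    for g in genes:
        gp = mplug.createGeneProduct()
        gp.setId(gene_sid[g])
        gp.setLabel(g)

    bound_params: Dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = smodel.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions:
        srxn = smodel.createReaction()
        srxn.setId(_sanitize(rxn.id))
        if rxn.name:
            srxn.setName(rxn.name)
        srxn.setFast(False)
        srxn.setReversible(rxn.lower_bound < 0)
        for met_id, coeff in sorted(rxn.stoichiometry.items()):
            ref = srxn.createReactant() if coeff < 0 else srxn.createProduct()
            ref.setSpecies(_sanitize(met_id))
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rplug = srxn.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if not rxn.gpr.empty:
            gpa = rplug.createGeneProductAssociation()
            _build_association(gpa, rxn.gpr.root, gene_sid)
        if rxn.subsystem:
            srxn.setNotes(
                f"<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>SUBSYSTEM: {rxn.subsystem}</p></body>"
            )

    _finish_objective(model, mplug)
    libsbml.writeSBMLToFile(doc, str(path))


def _build_association(parent, node, gene_sid: Dict[str, str]) -> None:
    if isinstance(node, str):
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(gene_sid[node])
        return
    op, children = node
    container = parent.createAnd() if op == "and" else parent.createOr()
    for child in children:
        _build_association(container, child, gene_sid)


def _finish_objective(model: MetabolicModel, mplug) -> None:
    if model.objective_reaction_id is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(_sanitize(model.objective_reaction_id))
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")
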