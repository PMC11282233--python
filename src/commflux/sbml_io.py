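"""SBML Level-3 + FBC reading and writing, via libSBML.

Only the constraint-based subset is handled: species with chemical formula
and charge (fbc), reactions with flux bounds referencing parameters (fbc),
one active maximization objective, and gene-product associations kept as
rule text. Ids are used verbatim; no SBML-id mangling is attempted beyond
what libSBML requires.
"""

from __future__ import annotations

from pathlib import Path

import libsbml

from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    ModelParseError,
    Reaction,
    format_formula,
    parse_formula,
)

__all__ = ["read_sbml", "write_sbml"]


def read_sbml(path: str | Path) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors() > 0:
        for i in range(doc.getNumErrors()):
            err = doc.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                raise ModelParseError(
                    f"{path}: line {err.getLine()}: {err.getMessage()}"
                )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelParseError(f"{path}: file contains no model element")

    model = MetabolicModel(sbml_model.getId() or Path(path).stem)
    for i in range(sbml_model.getNumCompartments()):
        comp = sbml_model.getCompartment(i)
        model.compartments[comp.getId()] = comp.getName() or comp.getId()

    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        fbc_sp = sp.getPlugin("fbc")
        formula: dict[str, int] = {}
        charge = None
        if fbc_sp is not None:
            if fbc_sp.isSetChemicalFormula() and fbc_sp.getChemicalFormula():
                formula = parse_formula(fbc_sp.getChemicalFormula())
            if fbc_sp.isSetCharge():
                charge = fbc_sp.getCharge()
        model.add_metabolite(Metabolite(
            sp.getId(), sp.getName() or "", sp.getCompartment(), formula, charge,
        ))

    def _bound_value(rxn_fbc, getter_id, default):
        if rxn_fbc is None:
            return default
        pid = getter_id()
        if not pid:
            return default
        param = sbml_model.getParameter(pid)
        if param is None:
            raise ModelParseError(f"{path}: flux bound parameter {pid!r} not defined")
        return param.getValue()

    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for k in range(rxn.getNumReactants()):
            ref = rxn.getReactant(k)
            if sbml_model.getSpecies(ref.getSpecies()) is None:
                raise ModelParseError(
                    f"{path}: reaction {rxn.getId()} cites undeclared species "
                    f"{ref.getSpecies()!r}"
                )
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for k in range(rxn.getNumProducts()):
            ref = rxn.getProduct(k)
            if sbml_model.getSpecies(ref.getSpecies()) is None:
                raise ModelParseError(
                    f"{path}: reaction {rxn.getId()} cites undeclared species "
                    f"{ref.getSpecies()!r}"
                )
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()

        rxn_fbc = rxn.getPlugin("fbc")
        lb = _bound_value(rxn_fbc, rxn_fbc.getLowerFluxBound if rxn_fbc else None,
                          -DEFAULT_BOUND if rxn.getReversible() else 0.0)
        ub = _bound_value(rxn_fbc, rxn_fbc.getUpperFluxBound if rxn_fbc else None,
                          DEFAULT_BOUND)
        gene_rule = ""
        if rxn_fbc is not None and rxn_fbc.isSetGeneProductAssociation():
            assoc = rxn_fbc.getGeneProductAssociation().getAssociation()
            if assoc is not None:
                gene_rule = assoc.toInfix()
        subsystem = ""
        if rxn.isSetNotes():
            notes = rxn.getNotesString()
            marker = "SUBSYSTEM:"
            if marker in notes:
                fragment = notes.split(marker, 1)[1]
                subsystem = fragment.split("<", 1)[0].strip()
        model.add_reaction(Reaction(
            rxn.getId(), stoich, lb, ub, rxn.getName() or "", gene_rule, subsystem,
        ))

    fbc_model = sbml_model.getPlugin("fbc")
    objective_id = None
    if fbc_model is not None and fbc_model.getNumObjectives() > 0:
        obj = fbc_model.getActiveObjective() or fbc_model.getObjective(0)
        if obj.getNumFluxObjectives() > 0:
            objective_id = obj.getFluxObjective(0).getReaction()
    if objective_id is None:
        raise ModelParseError(f"{path}: model declares no FBC objective")
    model.objective_id = objective_id
    model.refresh_exchange_flags()
    return model


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(model.id)
    fbc_model = sbml_model.getPlugin("fbc")
    fbc_model.setStrict(True)

    for cid in sorted(model.compartments):
        comp = sbml_model.createCompartment()
        comp.setId(cid)
        comp.setName(model.compartments[cid])
        comp.setConstant(True)

    for met_id in model.metabolite_ids():
        met = model.metabolites[met_id]
        sp = sbml_model.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        fbc_sp = sp.getPlugin("fbc")
        if met.formula:
            fbc_sp.setChemicalFormula(format_formula(met.formula))
        if met.charge is not None:
            fbc_sp.setCharge(int(met.charge))

    # shared flux-bound parameters, one per distinct value
    bound_params: dict[float, str] = {}

    def _param_for(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            param = sbml_model.createParameter()
            param.setId(pid)
            param.setValue(value)
            param.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn_id in model.reaction_ids():
        rxn = model.reactions[rxn_id]
        sbml_rxn = sbml_model.createReaction()
        sbml_rxn.setId(rxn.id)
        sbml_rxn.setName(rxn.name)
        sbml_rxn.setReversible(rxn.lower_bound < 0)
        sbml_rxn.setFast(False)
        for met_id, coeff in sorted(rxn.stoichiometry.items()):
            if coeff < 0:
                ref = sbml_rxn.createReactant()
                ref.setStoichiometry(-coeff)
            else:
                ref = sbml_rxn.createProduct()
                ref.setStoichiometry(coeff)
            ref.setSpecies(met_id)
            ref.setConstant(True)
        rxn_fbc = sbml_rxn.getPlugin("fbc")
        rxn_fbc.setLowerFluxBound(_param_for(rxn.lower_bound))
        rxn_fbc.setUpperFluxBound(_param_for(rxn.upper_bound))
        if rxn.gene_rule:
            gpa = rxn_fbc.createGeneProductAssociation()
            # parses infix text and auto-declares the gene products
            gpa.setAssociation(rxn.gene_rule)
        if rxn.subsystem:
            sbml_rxn.setNotes(
                '<body xmlns="http://www.w3.org/1999/xhtml">'
                f"<p>SUBSYSTEM: {rxn.subsystem}</p></body>"
            )

    objective = fbc_model.createObjective()
    objective.setId("obj")
    objective.setType("maximize")
    flux_obj = objective.createFluxObjective()
    flux_obj.setReaction(model.objective_id)
    flux_obj.setCoefficient(1.0)
    fbc_model.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))
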