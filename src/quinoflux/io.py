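"""Readers and writers: SBML L3+fbc, constraint-based JSON, and a TSV dialect.

All three dialects carry the same structural content (ids,
stoichiometries, bounds in mmol/gDW/hr, GPR trees, the biomass
objective).  SBML and JSON additionally round-trip metabolite formulas;
the TSV dialect is a human-editable table of reaction equations in which
compartments are recovered from the ``_e`` id suffix and formulas are
dropped.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import libsbml

from .gpr import GprExpression, parse_gpr
from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    equation_to_string,
    reaction_from_equation,
)

__all__ = [
    "load_model",
    "save_model",
    "FormatError",
    "load_gene_list",
    "save_gene_list",
    "save_fluxes",
    "load_fluxes",
]


class FormatError(ValueError):
    """A file does not parse in the requested dialect."""


def load_model(path, format: Optional[str] = None) -> MetabolicModel:
    """Load a model from ``path`` in ``format`` ('sbml', 'json' or 'tsv').

    The format is inferred from the suffix (.xml/.sbml, .json, .tsv)
    when not given.  Raises :class:`FormatError` on parse failure and
    :class:`ModelValidationError` on structural problems such as a
    reaction citing an undeclared species.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "sbml":
        return _read_sbml(path)
    if fmt == "json":
        return _read_json(path)
    if fmt == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown model format {fmt!r}")


def save_model(model: MetabolicModel, path, format: Optional[str] = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "sbml":
        _write_sbml(model, path)
    elif fmt == "json":
        _write_json(model, path)
    elif fmt == "tsv":
        _write_tsv(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix == ".json":
        return "json"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    raise ValueError(f"cannot infer model format from {path.name!r}")


# ---------------------------------------------------------------------------
# JSON (community constraint-based schema)
# ---------------------------------------------------------------------------

def _write_json(model: MetabolicModel, path: Path) -> None:
    doc = {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                **({"formula": m.formula} if m.formula else {}),
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr.to_string(),
                **({"subsystem": r.subsystem} if r.subsystem else {}),
                "objective_coefficient": 1.0 if r.id == model.biomass_reaction_id else 0.0,
            }
            for r in model.reactions
        ],
        "genes": [{"id": g} for g in sorted(model.genes)],
    }
    path.write_text(json.dumps(doc, indent=1, sort_keys=False) + "\n")


def _read_json(path: Path) -> MetabolicModel:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path.name}: invalid JSON ({exc})") from exc
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                formula=m.get("formula"),
            )
            for m in doc["metabolites"]
        ]
        rxns = []
        biomass_id = None
        for r in doc["reactions"]:
            rxns.append(
                Reaction(
                    id=r["id"],
                    name=r.get("name", ""),
                    stoichiometry={k: float(v) for k, v in r["metabolites"].items()},
                    lower_bound=float(r.get("lower_bound", 0.0)),
                    upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                    gpr=parse_gpr(r.get("gene_reaction_rule", "")),
                    subsystem=r.get("subsystem"),
                )
            )
            if float(r.get("objective_coefficient", 0.0)) != 0.0:
                biomass_id = r["id"]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path.name}: missing field {exc} in model JSON") from exc
    if biomass_id is None:
        raise FormatError(f"{path.name}: no reaction carries a nonzero objective")
    genes = sorted({g["id"] if isinstance(g, dict) else g for g in doc.get("genes", [])})
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id=biomass_id,
        genes=genes,
        id=doc.get("id", "model"),
    )


# ---------------------------------------------------------------------------
# TSV dialect: id, equation, lb, ub, gpr, subsystem
# ---------------------------------------------------------------------------

def _write_tsv(model: MetabolicModel, path: Path) -> None:
    lines = [
        f"# model: {model.id}",
        f"# biomass: {model.biomass_reaction_id}",
        "id\tequation\tlb\tub\tgpr\tsubsystem",
    ]
    for r in model.reactions:
        lines.append(
            "\t".join(
                [
                    r.id,
                    equation_to_string(model, r),
                    f"{r.lower_bound:.12g}",
                    f"{r.upper_bound:.12g}",
                    r.gpr.to_string(),
                    r.subsystem or "",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def _read_tsv(path: Path) -> MetabolicModel:
    model_id, biomass_id = "model", None
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("model:"):
                model_id = body.split(":", 1)[1].strip()
            elif body.startswith("biomass:"):
                biomass_id = body.split(":", 1)[1].strip()
            continue
        if line.startswith("id\t"):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise FormatError(f"{path.name}:{lineno}: expected >=4 tab-separated columns")
        rows.append((lineno, parts + [""] * (6 - len(parts))))
    if biomass_id is None:
        raise FormatError(f"{path.name}: missing '# biomass:' header line")
    reactions = []
    met_ids: dict = {}
    for lineno, (rid, equation, lb, ub, gpr, subsystem) in [
        (ln, p[:6]) for ln, p in rows
    ]:
        try:
            rxn = reaction_from_equation(
                rid,
                equation,
                lb=float(lb),
                ub=float(ub),
                gpr=gpr,
                subsystem=subsystem or None,
            )
        except ValueError as exc:
            raise FormatError(f"{path.name}:{lineno}: {exc}") from exc
        reactions.append(rxn)
        for met in rxn.stoichiometry:
            met_ids[met] = True
    metabolites = [
        Metabolite(
            id=m,
            name=m,
            compartment="e" if m.endswith("_e") else "c",
        )
        for m in met_ids
    ]
    genes = sorted(set().union(*[r.gpr.genes() for r in reactions]) if reactions else set())
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=biomass_id,
        genes=genes,
        id=model_id,
    )


# ---------------------------------------------------------------------------
# SBML Level 3 with the fbc extension
# ---------------------------------------------------------------------------

def _write_sbml(model: MetabolicModel, path: Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.id)
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = sorted({m.compartment for m in model.metabolites})
    for comp in compartments:
        c = sm.createCompartment()
        c.setId(comp)
        c.setConstant(True)

    for met in model.metabolites:
        s = sm.createSpecies()
        s.setId(met.id)
        s.setName(met.name or met.id)
        s.setCompartment(met.compartment)
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)
        if met.formula:
            s.getPlugin("fbc").setChemicalFormula(met.formula)

    for gene in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gp.setId(_gene_sid(gene))
        gp.setLabel(gene)

    bound_values: dict = {}

    def bound_param(value: float) -> str:
        key = f"{value:.10g}"
        if key not in bound_values:
            pid = f"fb_{len(bound_values)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_values[key] = pid
        return bound_values[key]

    for rxn in model.reactions:
        r = sm.createReaction()
        r.setId(rxn.id)
        r.setName(rxn.name or rxn.id)
        r.setReversible(rxn.reversible)
        r.setFast(False)
        for met_id, coef in rxn.stoichiometry.items():
            ref = r.createReactant() if coef < 0 else r.createProduct()
            ref.setSpecies(met_id)
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if not rxn.gpr.is_empty:
            assoc = rplug.createGeneProductAssociation()
            _gpr_to_sbml(rxn.gpr.root, assoc)

    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    fo = obj.createFluxObjective()
    fo.setReaction(model.biomass_reaction_id)
    fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


def _gene_sid(gene: str) -> str:
    sid = "G_" + "".join(ch if ch.isalnum() or ch == "_" else "_" for ch in gene)
    return sid


def _gpr_to_sbml(node, parent) -> None:
    if isinstance(node, str):
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(_gene_sid(node))
        return
    op, children = node
    grouping = parent.createAnd() if op == "and" else parent.createOr()
    for child in children:
        _gpr_to_sbml(child, grouping)


def _gpr_from_sbml(assoc) -> object:
    if assoc is None:
        return None
    if isinstance(assoc, libsbml.GeneProductRef):
        label = assoc.getGeneProduct()
        return label
    op = "and" if isinstance(assoc, libsbml.FbcAnd) else "or"
    children = tuple(
        _gpr_from_sbml(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations())
    )
    return (op, children)


def _read_sbml(path: Path) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise FormatError(f"{path.name}: SBML parse error: {err.getMessage().strip()}")
    sm = doc.getModel()
    if sm is None:
        raise FormatError(f"{path.name}: no <model> element")
    mplug = sm.getPlugin("fbc")

    # gene-product SId -> label
    gene_label: dict = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gene_label[gp.getId()] = gp.getLabel() or gp.getId()

    species_ids = set()
    mets = []
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        splug = sp.getPlugin("fbc")
        formula = None
        if splug is not None and splug.isSetChemicalFormula():
            formula = splug.getChemicalFormula()
        mets.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or sp.getId(),
                compartment=sp.getCompartment() or "c",
                formula=formula,
            )
        )
        species_ids.add(sp.getId())

    def resolve_gpr(node):
        if node is None:
            return None
        if isinstance(node, str):
            return gene_label.get(node, node)
        op, children = node
        return (op, tuple(resolve_gpr(c) for c in children))

    params = {
        sm.getParameter(i).getId(): sm.getParameter(i).getValue()
        for i in range(sm.getNumParameters())
    }
    rxns = []
    for i in range(sm.getNumReactions()):
        r = sm.getReaction(i)
        stoich: dict = {}
        for j in range(r.getNumReactants()):
            ref = r.getReactant(j)
            if ref.getSpecies() not in species_ids:
                raise ModelValidationError(
                    f"{path.name}: reaction {r.getId()} cites undeclared "
                    f"species {ref.getSpecies()!r}"
                )
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(r.getNumProducts()):
            ref = r.getProduct(j)
            if ref.getSpecies() not in species_ids:
                raise ModelValidationError(
                    f"{path.name}: reaction {r.getId()} cites undeclared "
                    f"species {ref.getSpecies()!r}"
                )
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        rplug = r.getPlugin("fbc")
        lb, ub = -DEFAULT_BOUND if r.getReversible() else 0.0, DEFAULT_BOUND
        gpr_root = None
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = params.get(rplug.getLowerFluxBound(), lb)
            if rplug.isSetUpperFluxBound():
                ub = params.get(rplug.getUpperFluxBound(), ub)
            if rplug.isSetGeneProductAssociation():
                gpr_root = resolve_gpr(
                    _gpr_from_sbml(rplug.getGeneProductAssociation().getAssociation())
                )
        rxns.append(
            Reaction(
                id=r.getId(),
                name=r.getName() or r.getId(),
                stoichiometry={k: v for k, v in stoich.items() if v != 0.0},
                lower_bound=lb,
                upper_bound=ub,
                gpr=GprExpression(gpr_root),
            )
        )

    biomass_id = None
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getActiveObjective() or mplug.getObjective(0)
        for i in range(obj.getNumFluxObjectives()):
            fo = obj.getFluxObjective(i)
            if fo.getCoefficient() != 0.0:
                biomass_id = fo.getReaction()
    if biomass_id is None:
        raise FormatError(f"{path.name}: SBML model declares no flux objective")
    genes = sorted(set().union(*[r.gpr.genes() for r in rxns]) if rxns else set())
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id=biomass_id,
        genes=genes,
        id=sm.getId() or "model",
    )


# ---------------------------------------------------------------------------
# Gene lists (plain text, one locus per line)
# ---------------------------------------------------------------------------

def save_fluxes(solution, path, format: Optional[str] = None) -> None:
    """Write a FluxSolution as TSV (reaction_id, flux) or JSON."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "tsv")
    if fmt == "json":
        doc = {
            "status": solution.status,
            "objective_value": solution.objective_value,
            "tilted_objective_value": solution.tilted_objective_value,
            "fluxes": dict(solution.fluxes),
        }
        path.write_text(json.dumps(doc, indent=1) + "\n")
    else:
        lines = ["reaction_id\tflux"] + [
            f"{rid}\t{v:.10g}" for rid, v in solution.fluxes.items()
        ]
        path.write_text("\n".join(lines) + "\n")


def load_fluxes(path) -> dict:
    """Read a flux table written by :func:`save_fluxes` back to a dict."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return json.loads(path.read_text())["fluxes"]
    out = {}
    for line in path.read_text().splitlines()[1:]:
        if line.strip():
            rid, v = line.split("\t")
            out[rid] = float(v)
    return out


def load_gene_list(path) -> list:
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]


def save_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")
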