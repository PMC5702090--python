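"""Reading and writing models, rates tables and screen reports.

Two model carriers are supported: a native JSON dialect that mirrors
SBML-FBC semantics (numeric bounds, GPR as an infix string, role ids for
the photon/carbon/product exchanges), and SBML Level 3 + FBC v2 via
python-libsbml.  SBML ids are namespaced with the community M_/R_/G_
prefixes on write and stripped on read; the role ids travel in the SBML
model notes.  Exchange status is inferred on SBML read from a single-
species reaction whose id starts with ``EX_``.

Older cyanobacterial reconstructions predate FBC and carry GPRs in reaction
notes ("GENE_ASSOCIATION: ..."); reading those is supported behind the
``parse_notes_gpr`` flag.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    DEFAULT_BOUND,
    FluxState,
    MetabolicModel,
    Metabolite,
    ModelValidationError,
    Reaction,
    parse_gpr,
)
from .moma import PhenotypeRecord
from .pathway import PathwaySpec

logger = logging.getLogger("pdoflux")

_ROLE_ATTRS = ("photon_exchange_id", "carbon_exchange_id",
               "pdo_exchange_id", "glycerol_exchange_id")


# ---------------------------------------------------------------------------
# Native JSON dialect
# ---------------------------------------------------------------------------

def _reaction_to_dict(r: Reaction) -> dict:
    return {
        "id": r.id,
        "name": r.name,
        "stoichiometry": {k: float(v) for k, v in sorted(r.stoichiometry.items())},
        "lower_bound": r.lower_bound,
        "upper_bound": r.upper_bound,
        "gpr": r.gpr.to_string(),
        "is_exchange": r.is_exchange,
    }


def _reaction_from_dict(d: dict) -> Reaction:
    return Reaction(
        id=d["id"],
        name=d.get("name", ""),
        stoichiometry={k: float(v) for k, v in d["stoichiometry"].items()},
        lower_bound=float(d.get("lower_bound", -DEFAULT_BOUND)),
        upper_bound=float(d.get("upper_bound", DEFAULT_BOUND)),
        gpr=parse_gpr(d.get("gpr", "")),
        is_exchange=bool(d.get("is_exchange", False)),
    )


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [_reaction_to_dict(r) for r in model.reactions],
        "genes": sorted(model.genes),
        "biomass_reaction_id": model.biomass_reaction_id,
        "roles": {a: getattr(model, a) for a in _ROLE_ATTRS
                  if getattr(model, a) is not None},
        "pathway_genes": sorted(model.pathway_genes),
    }


def model_from_dict(data: dict) -> MetabolicModel:
    try:
        model = MetabolicModel(
            id=data.get("id", "model"),
            metabolites=[Metabolite(m["id"], m.get("name", ""),
                                    m.get("compartment", "c"))
                         for m in data["metabolites"]],
            reactions=[_reaction_from_dict(r) for r in data["reactions"]],
            genes=set(data.get("genes", [])),
            biomass_reaction_id=data.get("biomass_reaction_id", ""),
            pathway_genes=set(data.get("pathway_genes", [])),
        )
    except KeyError as exc:
        raise ModelValidationError(f"model JSON missing element {exc}") from exc
    for attr, rid in data.get("roles", {}).items():
        if attr in _ROLE_ATTRS:
            setattr(model, attr, rid)
    model.validate()
    return model


def write_model_json(model: MetabolicModel, path) -> None:
    Path(path).write_text(
        json.dumps(model_to_dict(model), indent=1, sort_keys=True) + "\n")


def read_model_json(path) -> MetabolicModel:
    return model_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Pathway spec JSON (same dialect)
# ---------------------------------------------------------------------------

def pathway_spec_to_dict(spec: PathwaySpec) -> dict:
    return {
        "tag": spec.tag,
        "new_metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in spec.new_metabolites
        ],
        "new_reactions": [_reaction_to_dict(r) for r in spec.new_reactions],
        "new_genes": sorted(spec.new_genes),
        "role_ids": dict(spec.role_ids),
    }


def pathway_spec_from_dict(data: dict) -> PathwaySpec:
    return PathwaySpec(
        tag=data.get("tag", "pathway"),
        new_metabolites=[Metabolite(m["id"], m.get("name", ""),
                                    m.get("compartment", "c"))
                         for m in data.get("new_metabolites", [])],
        new_reactions=[_reaction_from_dict(r)
                       for r in data.get("new_reactions", [])],
        new_genes=set(data.get("new_genes", [])),
        role_ids=dict(data.get("role_ids", {})),
    )


def write_pathway_spec(spec: PathwaySpec, path) -> None:
    Path(path).write_text(
        json.dumps(pathway_spec_to_dict(spec), indent=1, sort_keys=True) + "\n")


def read_pathway_spec(path) -> PathwaySpec:
    return pathway_spec_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC v2
# ---------------------------------------------------------------------------

_SID_BAD = re.compile(r"[^A-Za-z0-9_]")


def _sid(prefix: str, raw: str) -> str:
    return prefix + _SID_BAD.sub("__", raw)


def _unsid(prefix: str, sid: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _gpr_to_fbc(assoc_parent, expr, create_root):
    """Recursively build an FBC association under ``assoc_parent``."""
    from .model import GprAnd, GprLeaf, GprOr
    if isinstance(expr, GprLeaf):
        ref = create_root.createGeneProductRef()
        ref.setGeneProduct(_sid("G_", expr.gene))
    elif isinstance(expr, GprAnd):
        node = create_root.createAnd()
        for child in expr.children:
            _gpr_to_fbc(assoc_parent, child, node)
    elif isinstance(expr, GprOr):
        node = create_root.createOr()
        for child in expr.children:
            _gpr_to_fbc(assoc_parent, child, node)


def _fbc_to_gpr_string(assoc) -> str:
    import libsbml
    if assoc is None:
        return ""
    if isinstance(assoc, libsbml.GeneProductRef):
        return _unsid("G_", assoc.getGeneProduct())
    if isinstance(assoc, libsbml.FbcAnd):
        parts = [_fbc_to_gpr_string(assoc.getAssociation(i))
                 for i in range(assoc.getNumAssociations())]
        return "(" + " and ".join(parts) + ")"
    if isinstance(assoc, libsbml.FbcOr):
        parts = [_fbc_to_gpr_string(assoc.getAssociation(i))
                 for i in range(assoc.getNumAssociations())]
        return "(" + " or ".join(parts) + ")"
    return ""


def write_model_sbml(model: MetabolicModel, path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sid("", model.id) or "model")
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    roles = {a: getattr(model, a) for a in _ROLE_ATTRS
             if getattr(model, a) is not None}
    notes_payload = json.dumps(
        {"roles": roles, "pathway_genes": sorted(model.pathway_genes)},
        sort_keys=True)
    sbml_model.setNotes(
        '<body xmlns="http://www.w3.org/1999/xhtml">'
        f"<p>pdoflux:{notes_payload}</p></body>"
    )

    compartments = sorted({m.compartment for m in model.metabolites} or {"c"})
    for cid in compartments:
        comp = sbml_model.createCompartment()
        comp.setId(_sid("", cid))
        comp.setConstant(True)

    for m in model.metabolites:
        sp = sbml_model.createSpecies()
        sp.setId(_sid("M_", m.id))
        sp.setName(m.name or m.id)
        sp.setCompartment(_sid("", m.compartment))
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)

    for gene in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gp.setId(_sid("G_", gene))
        gp.setLabel(gene)

    bound_params = {}

    def _bound_param(value: float) -> str:
        key = float(value)
        if key not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sbml_model.createParameter()
            par.setId(pid)
            par.setValue(key)
            par.setConstant(True)
            bound_params[key] = pid
        return bound_params[key]

    for r in model.reactions:
        rx = sbml_model.createReaction()
        rx.setId(_sid("R_", r.id))
        rx.setName(r.name or r.id)
        rx.setFast(False)
        rx.setReversible(r.lower_bound < 0)
        for met_id, coef in sorted(r.stoichiometry.items()):
            if coef < 0:
                ref = rx.createReactant()
                ref.setStoichiometry(-float(coef))
            else:
                ref = rx.createProduct()
                ref.setStoichiometry(float(coef))
            ref.setSpecies(_sid("M_", met_id))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(_bound_param(r.lower_bound))
        rplug.setUpperFluxBound(_bound_param(r.upper_bound))
        if not r.gpr.is_empty():
            gpa = rplug.createGeneProductAssociation()
            _gpr_to_fbc(gpa, r.gpr, gpa)

    if model.biomass_reaction_id:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(_sid("R_", model.biomass_reaction_id))
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


def read_model_sbml(path, parse_notes_gpr: bool = False) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelValidationError(
            f"SBML parse error in {path}: {err.getMessage() if err else 'unknown'}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelValidationError(f"{path} contains no SBML model")
    mplug = sbml_model.getPlugin("fbc")

    params = {sbml_model.getParameter(i).getId():
              sbml_model.getParameter(i).getValue()
              for i in range(sbml_model.getNumParameters())}

    metabolites = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        metabolites.append(Metabolite(
            _unsid("M_", sp.getId()), sp.getName(),
            sp.getCompartment() or "c"))

    genes = set()
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            genes.add(gp.getLabel() or _unsid("G_", gp.getId()))

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        rid = _unsid("R_", rx.getId())
        stoich = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            mid = _unsid("M_", ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            mid = _unsid("M_", ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        rplug = rx.getPlugin("fbc")
        lb, ub = -DEFAULT_BOUND, DEFAULT_BOUND
        gpr_text = ""
        if rplug is not None:
            lb = params.get(rplug.getLowerFluxBound(), lb)
            ub = params.get(rplug.getUpperFluxBound(), ub)
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None:
                gpr_text = _fbc_to_gpr_string(gpa.getAssociation())
        elif not rx.getReversible():
            lb = 0.0
        if not gpr_text and parse_notes_gpr and rx.isSetNotes():
            m = re.search(r"GENE_ASSOCIATION:\s*([^<\n]+)",
                          rx.getNotesString())
            if m:
                gpr_text = m.group(1).strip()
        gpr = parse_gpr(gpr_text)
        genes |= gpr.genes()
        reactions.append(Reaction(
            id=rid, name=rx.getName(), stoichiometry=stoich,
            lower_bound=lb, upper_bound=ub, gpr=gpr,
            is_exchange=(len(stoich) == 1 and rid.startswith("EX_")),
        ))

    biomass_id = ""
    if mplug is not None and mplug.getActiveObjective() is not None:
        obj = mplug.getActiveObjective()
        if obj.getNumFluxObjectives() > 0:
            biomass_id = _unsid("R_", obj.getFluxObjective(0).getReaction())

    model = MetabolicModel(
        id=sbml_model.getId() or "model",
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        biomass_reaction_id=biomass_id,
    )
    if sbml_model.isSetNotes():
        import html
        notes = html.unescape(sbml_model.getNotesString())
        m = re.search(r"pdoflux:(\{.*\})", notes, re.DOTALL)
        if m:
            try:
                payload = json.loads(m.group(1))
            except json.JSONDecodeError:
                payload = {}
            for attr, rid in payload.get("roles", {}).items():
                if attr in _ROLE_ATTRS:
                    setattr(model, attr, rid)
            model.pathway_genes = set(payload.get("pathway_genes", []))
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Unified entry points
# ---------------------------------------------------------------------------

def _infer_format(path, fmt: Optional[str]) -> str:
    if fmt:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix in (".xml", ".sbml"):
        return "sbml"
    raise ValueError(f"cannot infer model format from {path}")


def read_model(path, format: Optional[str] = None,
               parse_notes_gpr: bool = False) -> MetabolicModel:
    fmt = _infer_format(path, format)
    if fmt == "json":
        model = read_model_json(path)
    elif fmt == "sbml":
        model = read_model_sbml(path, parse_notes_gpr=parse_notes_gpr)
    else:
        raise ValueError(f"unknown model format {fmt!r}")
    g, r, m = model.counts()
    logger.info("read model %s from %s: %d genes, %d reactions, %d metabolites",
                model.id, path, g, r, m)
    return model


def write_model(model: MetabolicModel, path, format: Optional[str] = None) -> None:
    fmt = _infer_format(path, format)
    if fmt == "json":
        write_model_json(model, path)
    elif fmt == "sbml":
        write_model_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}")


# ---------------------------------------------------------------------------
# Rates tables
# ---------------------------------------------------------------------------

RATES_COLUMNS = ["strain", "mu", "q_pdo", "q_glycerol"]


def read_rates_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(RATES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"rates table {path} missing columns {sorted(missing)}")
    for col in RATES_COLUMNS[1:]:
        if not np.all(np.isfinite(df[col].to_numpy(dtype=float))):
            raise ValueError(f"rates table {path}: non-finite values in {col}")
    if (df["mu"] < 0).any():
        raise ValueError(f"rates table {path}: negative growth rate")
    return df[RATES_COLUMNS].copy()


def write_rates_table(df: pd.DataFrame, path) -> None:
    df[RATES_COLUMNS].to_csv(path, sep="\t", index=False,
                             float_format="%.6g", lineterminator="\n")


# ---------------------------------------------------------------------------
# Screen reports
# ---------------------------------------------------------------------------

@dataclass
class ScreenReport:
    """Phenotype records plus run metadata, round-trippable as TSV."""

    records: list
    metadata: dict = field(default_factory=dict)


REPORT_COLUMNS = ["gene", "status", "group", "mu", "q_pdo", "q_gly",
                  "product_score", "pattern_id"]


def _fmt(x) -> str:
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def write_screen_report(report: ScreenReport, path) -> None:
    """Deterministic TSV: metadata as sorted '#'-comments, one row per gene
    in ascending gene-id order, floats at 6 significant digits."""
    lines = []
    for key in sorted(report.metadata):
        val = json.dumps(report.metadata[key], sort_keys=True)
        lines.append(f"# {key}={val}")
    lines.append("\t".join(REPORT_COLUMNS))
    for rec in sorted(report.records, key=lambda r: r.gene):
        lines.append("\t".join([
            rec.gene, rec.status, str(rec.group), _fmt(rec.mu),
            _fmt(rec.q_pdo), _fmt(rec.q_glycerol), _fmt(rec.product_score),
            str(rec.pattern_id),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_screen_report(path) -> ScreenReport:
    metadata, records = {}, []
    lines = Path(path).read_text().splitlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            metadata[key.strip()] = json.loads(val) if val else None
        elif line.strip():
            body.append(line)
    if not body or body[0].split("\t") != REPORT_COLUMNS:
        raise ValueError(f"screen report {path}: unexpected header")
    for line in body[1:]:
        f = line.split("\t")
        records.append(PhenotypeRecord(
            gene=f[0], status=f[1], group=int(f[2]), mu=float(f[3]),
            q_pdo=float(f[4]), q_glycerol=float(f[5]),
            product_score=float(f[6]), pattern_id=int(f[7]),
        ))
    return ScreenReport(records=records, metadata=metadata)


# ---------------------------------------------------------------------------
# Flux states and envelopes
# ---------------------------------------------------------------------------

def write_flux_state(state: FluxState, path) -> None:
    lines = ["reaction\tflux"]
    for rid in sorted(state.flux):
        lines.append(f"{rid}\t{state.flux[rid]:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_flux_state(path) -> FluxState:
    flux = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        rid, _, val = line.partition("\t")
        if rid:
            flux[rid] = float(val)
    return FluxState(flux=flux)


def write_envelope(points: list, path) -> None:
    lines = ["mu\tq_min\tq_max"]
    for p in points:
        lines.append(f"{p.mu:.10g}\t{p.q_min:.10g}\t{p.q_max:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")
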