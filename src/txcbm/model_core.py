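"""Compartmentalized stoichiometric models with gene associations.

A :class:`MetabolicModel` holds the stoichiometric matrix ``S`` (one row per
metabolite, one column per reaction), flux bounds in mmol·gDW⁻¹·day⁻¹, flat
gene lists per reaction, a biomass objective carrying the growth-associated
maintenance (GAM) ATP coefficient, and a designated substrate-uptake reaction
with its measured rate.

Two on-disk formats are supported: SBML Level 3 with the ``fbc`` extension,
and a plain JSON dialect (see :func:`load_model` / :func:`write_model`).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

logger = logging.getLogger("txcbm")

#: conventional big-M flux cap used when a bound is absent
DEFAULT_BOUND = 1000.0

CATEGORIES = ("biochemical", "transport_exchange", "auxiliary")
PATHWAYS = ("SSP", "RES", "PPP", "CEL", "AMI", "FAT", "NUC")


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


class FormatError(ValueError):
    """Raised when an input file cannot be parsed in the named format."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "cytosol"


@dataclass
class Reaction:
    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float | None = None
    upper_bound: float | None = None
    reversible: bool = False
    genes: list[str] = field(default_factory=list)
    category: str = "biochemical"
    pathway: str | None = None

    def __post_init__(self) -> None:
        if self.lower_bound is None:
            self.lower_bound = -DEFAULT_BOUND if self.reversible else 0.0
        if self.upper_bound is None:
            self.upper_bound = DEFAULT_BOUND

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.lower_bound, self.upper_bound)


@dataclass
class MetabolicModel:
    """A constraint-based model: metabolites, reactions, biomass, uptake.

    ``gam_metabolite_ids`` names the ATP-hydrolysis species inside the biomass
    reaction: metabolites in ``consumed`` carry coefficient ``-S_GAM``, those
    in ``released`` carry ``+S_GAM``.  ``gam_coefficient`` is therefore a live
    view onto the biomass stoichiometry and is mutable to support calibration
    scans.
    """

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    biomass_reaction_id: str | None = None
    substrate_uptake_id: str | None = None
    uptake_rate: float | None = None
    gam_metabolite_ids: dict[str, list[str]] = field(default_factory=dict)
    id: str = "model"

    # -- indexing -----------------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, mid: str) -> Metabolite:
        try:
            return next(m for m in self.metabolites if m.id == mid)
        except StopIteration:
            raise KeyError(f"no metabolite {mid!r} in model {self.id!r}") from None

    def reaction(self, rid: str) -> Reaction:
        try:
            return next(r for r in self.reactions if r.id == rid)
        except StopIteration:
            raise KeyError(f"no reaction {rid!r} in model {self.id!r}") from None

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for r in self.reactions:
            counts[r.category] += 1
        return counts

    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.reactions:
            for g in r.genes:
                seen.setdefault(g, None)
        return list(seen)

    # -- GAM coefficient ----------------------------------------------------

    @property
    def gam_coefficient(self) -> float | None:
        """S_GAM, the ATP-maintenance coefficient in the biomass reaction."""
        if not self.gam_metabolite_ids or self.biomass_reaction_id is None:
            return None
        consumed = self.gam_metabolite_ids.get("consumed", [])
        if not consumed:
            return None
        biomass = self.reaction(self.biomass_reaction_id)
        return -biomass.stoichiometry.get(consumed[0], 0.0)

    def set_gam(self, s_gam: float) -> None:
        if s_gam <= 0:
            raise ValueError(f"S_GAM must be > 0, got {s_gam}")
        if not self.gam_metabolite_ids:
            raise ModelValidationError("model declares no GAM metabolites")
        biomass = self.reaction(self.biomass_reaction_id)
        for mid in self.gam_metabolite_ids.get("consumed", []):
            biomass.stoichiometry[mid] = -s_gam
        for mid in self.gam_metabolite_ids.get("released", []):
            biomass.stoichiometry[mid] = s_gam

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        mids = self.metabolite_ids
        if len(set(mids)) != len(mids):
            dup = sorted({m for m in mids if mids.count(m) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        rids = self.reaction_ids
        if len(set(rids)) != len(rids):
            dup = sorted({r for r in rids if rids.count(r) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        mset = set(mids)
        dangling = sorted(
            {mid for r in self.reactions for mid in r.stoichiometry if mid not in mset}
        )
        if dangling:
            raise ModelValidationError(f"dangling metabolite references: {dangling}")
        for r in self.reactions:
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(
                    f"reaction {r.id}: lower bound {r.lower_bound} > upper bound {r.upper_bound}"
                )
            if not r.reversible and r.lower_bound < 0:
                raise ModelValidationError(
                    f"reaction {r.id}: irreversible but lower bound {r.lower_bound} < 0"
                )
            if r.category not in CATEGORIES:
                raise ModelValidationError(f"reaction {r.id}: unknown category {r.category!r}")
        if self.biomass_reaction_id is not None and self.biomass_reaction_id not in set(rids):
            raise ModelValidationError(f"biomass reaction {self.biomass_reaction_id!r} not found")
        if self.substrate_uptake_id is not None and self.substrate_uptake_id not in set(rids):
            raise ModelValidationError(f"uptake reaction {self.substrate_uptake_id!r} not found")
        gam = self.gam_coefficient
        if gam is not None and gam <= 0:
            raise ModelValidationError(f"S_GAM must be positive, got {gam}")


def stoichiometric_matrix(model: MetabolicModel, sparse_format: bool = False):
    """Matrix ``S`` with ``S[i, j]`` the coefficient of metabolite *i* in reaction *j*.

    The steady-state constraint of every program in this package is
    ``S @ v == 0`` over this matrix.
    """
    model.validate()
    mindex = {m: i for i, m in enumerate(model.metabolite_ids)}
    n_met, n_rxn = len(model.metabolites), len(model.reactions)
    rows, cols, data = [], [], []
    for j, rxn in enumerate(model.reactions):
        for mid, coef in rxn.stoichiometry.items():
            if coef == 0:
                continue
            rows.append(mindex[mid])
            cols.append(j)
            data.append(float(coef))
    mat = sparse.coo_matrix((data, (rows, cols)), shape=(n_met, n_rxn)).tocsr()
    return mat if sparse_format else mat.toarray()


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _model_to_dict(model: MetabolicModel) -> dict:
    d: dict = {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoich": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "reversible": r.reversible,
                "genes": list(r.genes),
                "category": r.category,
                "pathway": r.pathway,
            }
            for r in model.reactions
        ],
        "biomass": model.biomass_reaction_id,
    }
    if model.substrate_uptake_id is not None:
        d["uptake"] = {"id": model.substrate_uptake_id, "rate": model.uptake_rate}
    if model.gam_metabolite_ids:
        d["gam_metabolites"] = model.gam_metabolite_ids
    return d


def _model_from_dict(d: dict) -> MetabolicModel:
    try:
        mets = [
            Metabolite(id=m["id"].strip(), name=m.get("name", ""), compartment=m.get("compartment", "cytosol"))
            for m in d["metabolites"]
        ]
        rxns = []
        for r in d["reactions"]:
            rxns.append(
                Reaction(
                    id=r["id"].strip(),
                    name=r.get("name", ""),
                    stoichiometry={k: float(v) for k, v in r.get("stoich", {}).items()},
                    lower_bound=r.get("lb"),
                    upper_bound=r.get("ub"),
                    reversible=bool(r.get("reversible", False)),
                    genes=list(r.get("genes", [])),
                    category=r.get("category", "biochemical"),
                    pathway=r.get("pathway"),
                )
            )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed model JSON: {exc}") from exc
    uptake = d.get("uptake") or {}
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id=d.get("biomass"),
        substrate_uptake_id=uptake.get("id"),
        uptake_rate=uptake.get("rate"),
        gam_metabolite_ids=d.get("gam_metabolites", {}),
        id=d.get("id", "model"),
    )


def model_to_json(model: MetabolicModel) -> str:
    """Canonical (sorted-key, fixed-indent) JSON text for a model."""
    return json.dumps(_model_to_dict(model), indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# SBML L3 + fbc
# ---------------------------------------------------------------------------

_COMPARTMENT_CODES = {
    "cytosol": "c",
    "plastid": "p",
    "mitochondrion": "m",
    "external": "e",
}


def _sbml_escape(s: str) -> str:
    # SBML SIds must match [a-zA-Z_][a-zA-Z0-9_]*
    out = "".join(ch if ch.isalnum() or ch == "_" else "_" for ch in s)
    if not out or not (out[0].isalpha() or out[0] == "_"):
        out = "x_" + out
    return out


def _write_sbml(model: MetabolicModel, path: str) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sbml_escape(model.id))
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    meta = {
        "uptake_id": model.substrate_uptake_id,
        "uptake_rate": model.uptake_rate,
        "gam_metabolites": model.gam_metabolite_ids,
    }
    sbml_model.setNotes(
        "<body xmlns='http://www.w3.org/1999/xhtml'><p>txcbm:"
        + _xml_escape(json.dumps(meta, sort_keys=True))
        + "</p></body>"
    )

    comps = sorted({m.compartment for m in model.metabolites}) or ["cytosol"]
    for cname in comps:
        comp = sbml_model.createCompartment()
        comp.setId(_COMPARTMENT_CODES.get(cname, _sbml_escape(cname)))
        comp.setName(cname)
        comp.setConstant(True)

    for m in model.metabolites:
        sp = sbml_model.createSpecies()
        sp.setId(_sbml_escape(m.id))
        sp.setName(m.name)
        sp.setCompartment(_COMPARTMENT_CODES.get(m.compartment, _sbml_escape(m.compartment)))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    for g in model.genes():
        gp = mplug.createGeneProduct()
        gp.setId(_sbml_escape(g))
        gp.setLabel(g)

    bound_ids: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_ids:
            pid = f"fb_{len(bound_ids)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_ids[value] = pid
        return bound_ids[value]

    for r in model.reactions:
        sr = sbml_model.createReaction()
        sr.setId(_sbml_escape(r.id))
        sr.setName(r.name)
        sr.setReversible(r.reversible)
        sr.setFast(False)
        sr.setNotes(
            "<body xmlns='http://www.w3.org/1999/xhtml'><p>txcbm:"
            + _xml_escape(
                json.dumps({"category": r.category, "pathway": r.pathway}, sort_keys=True)
            )
            + "</p></body>"
        )
        for mid, coef in sorted(r.stoichiometry.items()):
            if coef < 0:
                ref = sr.createReactant()
                ref.setStoichiometry(-coef)
            else:
                ref = sr.createProduct()
                ref.setStoichiometry(coef)
            ref.setSpecies(_sbml_escape(mid))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(float(r.lower_bound)))
        rplug.setUpperFluxBound(bound_param(float(r.upper_bound)))
        if r.genes:
            gpa = rplug.createGeneProductAssociation()
            if len(r.genes) == 1:
                ref = gpa.createGeneProductRef()
                ref.setGeneProduct(_sbml_escape(r.genes[0]))
            else:
                orn = gpa.createOr()
                for g in r.genes:
                    ref = orn.createGeneProductRef()
                    ref.setGeneProduct(_sbml_escape(g))

    if model.biomass_reaction_id is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        mplug.setActiveObjectiveId("obj")
        fo = obj.createFluxObjective()
        fo.setReaction(_sbml_escape(model.biomass_reaction_id))
        fo.setCoefficient(1.0)

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


def _xml_escape(s: str) -> str:
    return s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


def _xml_unescape(s: str) -> str:
    return (
        s.replace("&lt;", "<")
        .replace("&gt;", ">")
        .replace("&quot;", '"')
        .replace("&apos;", "'")
        .replace("&amp;", "&")
    )


def _notes_payload(node) -> dict:
    if node is None or not node.isSetNotes():
        return {}
    text = node.getNotesString()
    marker = "txcbm:"
    i = text.find(marker)
    if i < 0:
        return {}
    j = text.find("</p>", i)
    try:
        return json.loads(_xml_unescape(text[i + len(marker): j]))
    except json.JSONDecodeError:
        return {}


def _gpr_leaf_genes(assoc, gp_labels: dict[str, str]) -> list[str]:
    """Flatten an fbc gene-product association tree to its leaf genes.

    AND/OR structure is discarded: expression aggregation treats the genes
    of a reaction as an unordered set (max-expressed gene wins), so only the
    leaf union matters.  A warning is logged when an AND node is flattened.
    """
    import libsbml

    genes: list[str] = []

    def walk(node, under_and: bool) -> None:
        if isinstance(node, libsbml.GeneProductRef):
            gid = node.getGeneProduct()
            genes.append(gp_labels.get(gid, gid))
            return
        if isinstance(node, libsbml.FbcAnd):
            logger.warning("flattening AND gene association to the union of leaf genes")
            under_and = True
        for i in range(node.getNumAssociations()):
            walk(node.getAssociation(i), under_and)

    walk(assoc, False)
    out: dict[str, None] = {}
    for g in genes:
        out.setdefault(g, None)
    return list(out)


def _read_sbml(path: str) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getError(0)
        raise FormatError(f"SBML parse failure: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise FormatError("SBML file contains no model element")
    mplug = sbml_model.getPlugin("fbc")

    comp_names = {
        c.getId(): (c.getName() or c.getId()) for c in sbml_model.getListOfCompartments()
    }
    mets = [
        Metabolite(
            id=sp.getId(),
            name=sp.getName(),
            compartment=comp_names.get(sp.getCompartment(), sp.getCompartment()),
        )
        for sp in sbml_model.getListOfSpecies()
    ]

    gp_labels = {}
    if mplug is not None:
        for gp in mplug.getListOfGeneProducts():
            gp_labels[gp.getId()] = gp.getLabel() or gp.getId()

    params = {p.getId(): p.getValue() for p in sbml_model.getListOfParameters()}

    rxns = []
    for sr in sbml_model.getListOfReactions():
        stoich: dict[str, float] = {}
        for ref in sr.getListOfReactants():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for ref in sr.getListOfProducts():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        rplug = sr.getPlugin("fbc")
        lb = ub = None
        genes: list[str] = []
        if rplug is not None:
            lb = params.get(rplug.getLowerFluxBound())
            ub = params.get(rplug.getUpperFluxBound())
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None:
                genes = _gpr_leaf_genes(gpa.getAssociation(), gp_labels)
        notes = _notes_payload(sr)
        rxns.append(
            Reaction(
                id=sr.getId().strip(),
                name=sr.getName(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                reversible=sr.getReversible(),
                genes=genes,
                category=notes.get("category", "biochemical"),
                pathway=notes.get("pathway"),
            )
        )

    biomass = None
    if mplug is not None:
        obj = mplug.getActiveObjective()
        if obj is not None and obj.getNumFluxObjectives() > 0:
            biomass = obj.getFluxObjective(0).getReaction()

    meta = _notes_payload(sbml_model)
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id=biomass,
        substrate_uptake_id=meta.get("uptake_id"),
        uptake_rate=meta.get("uptake_rate"),
        gam_metabolite_ids=meta.get("gam_metabolites", {}),
        id=sbml_model.getId() or "model",
    )


# ---------------------------------------------------------------------------
# public I/O
# ---------------------------------------------------------------------------

def load_model(path: str, format: str = "tabular_json") -> MetabolicModel:
    """Read and validate a model from ``path`` in the named format."""
    if format == "tabular_json":
        try:
            with open(path) as fh:
                d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"invalid JSON in {path}: {exc}") from exc
        model = _model_from_dict(d)
    elif format == "sbml":
        model = _read_sbml(path)
    else:
        raise ValueError(f"unknown model format {format!r}")
    model.validate()
    return model


def write_model(model: MetabolicModel, path: str, format: str = "tabular_json") -> None:
    """Write a validated model; the emitted file round-trips via :func:`load_model`."""
    model.validate()
    if format == "tabular_json":
        with open(path, "w") as fh:
            fh.write(model_to_json(model))
            fh.write("\n")
    elif format == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {format!r}")


def models_equal(a: MetabolicModel, b: MetabolicModel, tol: float = 1e-9) -> bool:
    """Structural equality: same species/reactions/stoichiometry/bounds/genes."""
    if [m.id for m in a.metabolites] != [m.id for m in b.metabolites]:
        return False
    if [m.compartment for m in a.metabolites] != [m.compartment for m in b.metabolites]:
        return False
    if a.reaction_ids != b.reaction_ids:
        return False
    for ra, rb in zip(a.reactions, b.reactions):
        if set(ra.stoichiometry) != set(rb.stoichiometry):
            return False
        if any(
            not math.isclose(ra.stoichiometry[k], rb.stoichiometry[k], abs_tol=tol)
            for k in ra.stoichiometry
        ):
            return False
        if not math.isclose(ra.lower_bound, rb.lower_bound, abs_tol=tol):
            return False
        if not math.isclose(ra.upper_bound, rb.upper_bound, abs_tol=tol):
            return False
        if ra.reversible != rb.reversible or sorted(ra.genes) != sorted(rb.genes):
            return False
        if ra.category != rb.category or ra.pathway != rb.pathway:
            return False
    return (
        a.biomass_reaction_id == b.biomass_reaction_id
        and a.substrate_uptake_id == b.substrate_uptake_id
    )
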