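"""Data model for genome-scale metabolic networks.

A metabolic network is represented by :class:`MetabolicModel` — metabolites
with compartment tags, reactions with flux bounds and boolean
gene-protein-reaction (GPR) associations, and a single biomass objective.
The module provides SBML I/O (Level 3 + fbc as the canonical dialect, with a
Level 2 note-string fallback), stoichiometric-matrix assembly, structural
reaction classification, and the model-statistics partition used to summarise
reconstructions (gene / metabolite / reaction counts, reversibility,
exchange/transport/demand splits).

Conventions
-----------
* Fluxes are mmol/gDW/h throughout; default global bounds are (-100, 100) for
  reversible reactions and (0, 100) for forward-only reactions.
* Exchange reactions move a single metabolite across the system boundary;
  positive flux is secretion, negative flux is uptake.
* A reaction is reversible iff lower_bound < 0 < upper_bound.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("cofactorscope")

#: default absolute flux bound, mmol/gDW/h
DEFAULT_BOUND = 100.0

#: numerical tolerance below which a flux/coefficient is treated as zero
ZERO_TOL = 1e-9

REACTION_CATEGORIES = ("enzymatic", "transport", "exchange", "demand", "spontaneous")


class ModelValidationError(ValueError):
    """A model or file violates a structural invariant."""


class SBMLParseError(ValueError):
    """The SBML document could not be parsed."""


# ---------------------------------------------------------------------------
# GPR expressions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GPRExpression:
    """Boolean gene association tree.

    ``op`` is ``"gene"`` (leaf, ``gene`` set), ``"and"``, ``"or"``, or
    ``"empty"`` (no association).  OR nodes encode isozymes, AND nodes
    multi-subunit complexes.
    """

    op: str = "empty"
    gene: str | None = None
    children: tuple["GPRExpression", ...] = ()

    def __post_init__(self) -> None:
        if self.op not in ("gene", "and", "or", "empty"):
            raise ValueError(f"unknown GPR node type {self.op!r}")
        if self.op == "gene" and not self.gene:
            raise ValueError("gene leaf requires a gene id")
        if self.op in ("and", "or") and len(self.children) < 1:
            raise ValueError(f"{self.op} node requires children")

    @property
    def is_empty(self) -> bool:
        return self.op == "empty"

    def genes(self) -> set[str]:
        """All gene identifiers appearing as leaves."""
        if self.op == "gene":
            return {self.gene}  # type: ignore[arg-type]
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return out

    def evaluate(self, active: Mapping[str, bool]) -> bool:
        """Evaluate the boolean expression; missing genes count as active."""
        if self.op == "empty":
            return True
        if self.op == "gene":
            return active.get(self.gene, True)  # type: ignore[arg-type]
        values = (c.evaluate(active) for c in self.children)
        return all(values) if self.op == "and" else any(values)

    def to_string(self) -> str:
        if self.op == "empty":
            return ""
        if self.op == "gene":
            return str(self.gene)
        joiner = f" {self.op} "
        parts = []
        for child in self.children:
            s = child.to_string()
            if child.op in ("and", "or") and child.op != self.op:
                s = f"({s})"
            parts.append(s)
        return joiner.join(parts)


_GPR_TOKEN = re.compile(r"\(|\)|\band\b|\bor\b|[^\s()]+", re.IGNORECASE)


def parse_gpr(text: str | None) -> GPRExpression:
    """Parse a boolean gene-association string into a :class:`GPRExpression`.

    Grammar: identifiers combined with case-insensitive ``and`` / ``or`` and
    parentheses; ``or`` binds weaker than ``and``.  An empty or whitespace
    string yields the empty association.
    """
    if text is None or not text.strip():
        return GPRExpression()
    tokens = _GPR_TOKEN.findall(text)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GPRExpression:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        if len(terms) == 1:
            return terms[0]
        return GPRExpression(op="or", children=tuple(terms))

    def parse_and() -> GPRExpression:
        factors = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            factors.append(parse_atom())
        if len(factors) == 1:
            return factors[0]
        return GPRExpression(op="and", children=tuple(factors))

    def parse_atom() -> GPRExpression:
        tok = peek()
        if tok is None:
            raise ValueError(f"unexpected end of GPR string {text!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise ValueError(f"unbalanced parentheses in GPR string {text!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ValueError(f"malformed GPR string {text!r}")
        return GPRExpression(op="gene", gene=take())

    node = parse_or()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in GPR string {text!r}")
    return node


# ---------------------------------------------------------------------------
# Metabolites / reactions / model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Metabolite:
    """A chemical species in a named compartment (c cytosol, p periplasm,
    e extracellular)."""

    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    charge: int | None = None
    boundary: bool = False


@dataclass
class Reaction:
    """A stoichiometry-balanced flux variable with bounds and a GPR.

    ``stoichiometry`` maps metabolite id to a signed coefficient (negative =
    consumed).  ``category`` is one of ``enzymatic``, ``transport``,
    ``exchange``, ``demand``, ``spontaneous``.
    """

    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gpr: GPRExpression = field(default_factory=GPRExpression)
    category: str = "enzymatic"

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.category not in REACTION_CATEGORIES:
            raise ModelValidationError(
                f"reaction {self.id!r}: unknown category {self.category!r}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0.0 < self.upper_bound


@dataclass
class MetabolicModel:
    """A genome-scale (or toy) metabolic network with one biomass objective."""

    id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    genes: list[str] = field(default_factory=list)
    objective_id: str = ""
    compartments: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            self.genes = sorted(
                {g for r in self.reactions for g in r.gpr.genes()}
            )

    # -- lookups ------------------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(f"metabolite {met_id!r} not in model {self.id!r}")

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(f"reaction {rxn_id!r} not in model {self.id!r}")

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.category == "exchange"]

    # -- structural helpers -------------------------------------------------

    def copy(self) -> "MetabolicModel":
        """Deep-enough copy: reactions are fresh objects, metabolites shared
        (they are frozen)."""
        return MetabolicModel(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=[
                replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions
            ],
            genes=list(self.genes),
            objective_id=self.objective_id,
            compartments=dict(self.compartments),
        )

    def validate(self) -> None:
        """Raise :class:`ModelValidationError` on any invariant violation."""
        met_ids = self.metabolite_ids
        dup_m = _duplicates(met_ids)
        dup_r = _duplicates(self.reaction_ids)
        if dup_m or dup_r:
            raise ModelValidationError(
                f"model {self.id!r}: duplicate ids {sorted(dup_m | dup_r)}"
            )
        met_set = set(met_ids)
        for r in self.reactions:
            unknown = set(r.stoichiometry) - met_set
            if unknown:
                raise ModelValidationError(
                    f"reaction {r.id!r} references unknown metabolites {sorted(unknown)}"
                )
            if r.lower_bound > r.upper_bound:
                raise ModelValidationError(
                    f"reaction {r.id!r}: lower_bound > upper_bound"
                )
        if not self.objective_id:
            raise ModelValidationError(f"model {self.id!r}: no objective reaction")
        if not self.has_reaction(self.objective_id):
            raise ModelValidationError(
                f"model {self.id!r}: objective {self.objective_id!r} not a reaction"
            )
        gpr_genes = {g for r in self.reactions for g in r.gpr.genes()}
        if gpr_genes - set(self.genes):
            raise ModelValidationError(
                f"model {self.id!r}: GPR genes missing from gene list: "
                f"{sorted(gpr_genes - set(self.genes))}"
            )


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def models_equal(a: MetabolicModel, b: MetabolicModel, tol: float = 0.0) -> bool:
    """Field-by-field equality of two models (id order insensitive for genes)."""
    if a.id != b.id or a.objective_id != b.objective_id:
        return False
    if sorted(a.genes) != sorted(b.genes):
        return False
    if a.metabolite_ids != b.metabolite_ids or a.reaction_ids != b.reaction_ids:
        return False
    for ma, mb in zip(a.metabolites, b.metabolites):
        if (ma.id, ma.compartment, ma.boundary) != (mb.id, mb.compartment, mb.boundary):
            return False
    for ra, rb in zip(a.reactions, b.reactions):
        if ra.id != rb.id or ra.category != rb.category:
            return False
        if abs(ra.lower_bound - rb.lower_bound) > tol:
            return False
        if abs(ra.upper_bound - rb.upper_bound) > tol:
            return False
        if set(ra.stoichiometry) != set(rb.stoichiometry):
            return False
        for met, coef in ra.stoichiometry.items():
            if abs(coef - rb.stoichiometry[met]) > tol:
                return False
        if ra.gpr.to_string() != rb.gpr.to_string():
            return False
    return True


# ---------------------------------------------------------------------------
# Stoichiometric matrix
# ---------------------------------------------------------------------------


@dataclass
class StoichMatrix:
    """Dense m-by-n stoichiometric matrix S with id-to-index maps."""

    coefficients: np.ndarray
    row_index: dict[str, int]
    col_index: dict[str, int]


def build_stoich_matrix(model: MetabolicModel) -> StoichMatrix:
    """Assemble S (metabolites x reactions) from the model.

    Entry (i, j) is the stoichiometric coefficient of metabolite i in reaction
    j; boundary metabolites are excluded from the rows (they are not
    mass-balanced).
    """
    rows = [m.id for m in model.metabolites if not m.boundary]
    row_index = {mid: i for i, mid in enumerate(rows)}
    col_index = {r.id: j for j, r in enumerate(model.reactions)}
    S = np.zeros((len(rows), len(model.reactions)))
    for j, r in enumerate(model.reactions):
        for met, coef in r.stoichiometry.items():
            i = row_index.get(met)
            if i is not None:
                S[i, j] = coef
    return StoichMatrix(coefficients=S, row_index=row_index, col_index=col_index)


# ---------------------------------------------------------------------------
# Classification and statistics
# ---------------------------------------------------------------------------


def classify_reactions(model: MetabolicModel) -> dict[str, str]:
    """Classify every reaction structurally.

    exchange — touches exactly one non-boundary metabolite and that metabolite
    is extracellular (or the reaction is flagged exchange);
    demand — flagged sink (category ``demand`` or id prefixed ``DM_``);
    transport — moves species between compartments;
    spontaneous — annotated category ``spontaneous``;
    everything else — enzymatic.  Unclassifiable structures fall back to
    enzymatic with a logged warning.
    """
    out: dict[str, str] = {}
    for r in model.reactions:
        out[r.id] = _classify_one(model, r)
    return out


def _classify_one(model: MetabolicModel, r: Reaction) -> str:
    mets = [model.metabolite(mid) for mid in r.stoichiometry]
    internal = [m for m in mets if not m.boundary]
    if r.category == "demand" or r.id.startswith("DM_"):
        return "demand"
    if len(internal) == 1 and (
        internal[0].compartment == "e" or r.category == "exchange" or len(mets) > len(internal)
    ):
        return "exchange"
    compartments = {m.compartment for m in internal}
    if len(compartments) > 1:
        return "transport"
    if r.category == "spontaneous":
        return "spontaneous"
    if not internal:
        logger.warning("reaction %s has no classifiable structure; treated enzymatic", r.id)
    return "enzymatic"


@dataclass
class ModelStats:
    """Reconstruction summary counts (reversibility, category and
    gene-association partitions)."""

    genes: int
    metabolites: int
    reactions: int
    enzymatic: int
    transport: int
    gene_associated: int
    spontaneous: int
    no_gene_association: int
    reversible: int
    irreversible: int
    exchange: int
    demand: int

    def as_rows(self) -> list[tuple[str, int]]:
        return [
            ("Genes", self.genes),
            ("Metabolites", self.metabolites),
            ("Reactions", self.reactions),
            ("Enzymatic Reactions", self.enzymatic),
            ("Transport reactions", self.transport),
            ("Reactions Associated with genes", self.gene_associated),
            ("Spontaneous/Diffusion reactions", self.spontaneous),
            ("Reactions without gene association", self.no_gene_association),
            ("Reversible Reactions", self.reversible),
            ("Irreversible Reactions", self.irreversible),
            ("Exchange Reactions", self.exchange),
            ("Demand Reactions", self.demand),
        ]


def model_statistics(model: MetabolicModel) -> ModelStats:
    """Compute the reconstruction-summary partition.

    Reversible means lower_bound < 0 < upper_bound, so
    reversible + irreversible always equals the reaction total.  Spontaneous
    reactions are counted separately from (other) reactions without a gene
    association.
    """
    categories = classify_reactions(model)
    n_rev = sum(1 for r in model.reactions if r.reversible)
    n_spont = sum(1 for c in categories.values() if c == "spontaneous")
    n_assoc = sum(1 for r in model.reactions if not r.gpr.is_empty)
    n_noassoc = sum(
        1
        for r in model.reactions
        if r.gpr.is_empty and categories[r.id] != "spontaneous"
    )
    return ModelStats(
        genes=len(model.genes),
        metabolites=sum(1 for m in model.metabolites if not m.boundary),
        reactions=len(model.reactions),
        enzymatic=sum(1 for c in categories.values() if c == "enzymatic"),
        transport=sum(1 for c in categories.values() if c == "transport"),
        gene_associated=n_assoc,
        spontaneous=n_spont,
        no_gene_association=n_noassoc,
        reversible=n_rev,
        irreversible=len(model.reactions) - n_rev,
        exchange=sum(1 for c in categories.values() if c == "exchange"),
        demand=sum(1 for c in categories.values() if c == "demand"),
    )


# ---------------------------------------------------------------------------
# SBML I/O
# ---------------------------------------------------------------------------

_SBO_EXCHANGE = "SBO:0000627"
_SBO_DEMAND = "SBO:0000628"
_CATEGORY_TO_SBO = {"exchange": 627, "demand": 628}


def read_sbml(path: str) -> MetabolicModel:
    """Read an SBML file into a :class:`MetabolicModel`.

    Level 3 with the fbc package (flux bounds as parameters, gene-product
    associations, an active objective) is canonical; Level 2 documents with
    ``GENE_ASSOCIATION:`` note strings and kinetic-law bound parameters are
    accepted as a fallback.  If no fbc objective is present, a unique reaction
    whose id or name contains "biomass" (case-insensitive) is used; ambiguity
    is an error.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLParseError(
            f"{path}: line {err.getLine()}: {err.getMessage().strip()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLParseError(f"{path}: document contains no model")
    fbc = sbml_model.getPlugin("fbc")

    compartments = {
        c.getId(): c.getName() or c.getId()
        for c in (sbml_model.getCompartment(i) for i in range(sbml_model.getNumCompartments()))
    }

    metabolites = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        sp_fbc = sp.getPlugin("fbc")
        formula = None
        charge = None
        if sp_fbc is not None:
            if sp_fbc.isSetChemicalFormula():
                formula = sp_fbc.getChemicalFormula()
            if sp_fbc.isSetCharge():
                charge = sp_fbc.getCharge()
        metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                compartment=sp.getCompartment(),
                formula=formula,
                charge=charge,
                boundary=bool(sp.getBoundaryCondition()),
            )
        )

    def _param_value(pid: str) -> float:
        p = sbml_model.getParameter(pid)
        if p is None:
            raise SBMLParseError(f"{path}: missing flux-bound parameter {pid!r}")
        return p.getValue()

    gene_names: dict[str, str] = {}
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            gene_names[gp.getId()] = gp.getLabel() or gp.getId()

    reactions = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for k in range(rx.getNumReactants()):
            sr = rx.getReactant(k)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for k in range(rx.getNumProducts()):
            sr = rx.getProduct(k)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()

        rx_fbc = rx.getPlugin("fbc")
        if rx_fbc is not None and rx_fbc.isSetLowerFluxBound():
            lb = _param_value(rx_fbc.getLowerFluxBound())
            ub = _param_value(rx_fbc.getUpperFluxBound())
        else:
            lb, ub = _bounds_from_notes_or_kinetics(rx)

        gpr = GPRExpression()
        if rx_fbc is not None and rx_fbc.getGeneProductAssociation() is not None:
            assoc = rx_fbc.getGeneProductAssociation().getAssociation()
            gpr = _association_to_gpr(assoc, gene_names)
        else:
            notes = rx.getNotesString() or ""
            m = re.search(r"GENE_ASSOCIATION:\s*([^<\n]*)", notes)
            if m:
                gpr = parse_gpr(m.group(1))

        category = "enzymatic"
        if rx.isSetSBOTerm():
            if rx.getSBOTerm() == 627:
                category = "exchange"
            elif rx.getSBOTerm() == 628:
                category = "demand"
        notes = rx.getNotesString() or ""
        m = re.search(r"COFACTORSCOPE_CATEGORY:\s*(\w+)", notes)
        if m and m.group(1) in REACTION_CATEGORIES:
            category = m.group(1)

        if lb > ub:
            raise ModelValidationError(
                f"{path}: reaction {rx.getId()!r} has lower_bound {lb} > upper_bound {ub}"
            )
        reactions.append(
            Reaction(
                id=rx.getId(),
                name=rx.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                category=category,
            )
        )

    objective_id = ""
    if fbc is not None and fbc.getNumObjectives() > 0:
        active = fbc.getActiveObjective() or fbc.getObjective(0)
        if active is not None and active.getNumFluxObjectives() > 0:
            objective_id = active.getFluxObjective(0).getReaction()
    if not objective_id:
        candidates = [
            r.id
            for r in reactions
            if "biomass" in r.id.lower() or "biomass" in r.name.lower()
        ]
        if len(candidates) == 1:
            objective_id = candidates[0]
        elif len(candidates) > 1:
            raise ModelValidationError(
                f"{path}: no objective declared and multiple biomass-like "
                f"reactions found: {candidates}"
            )
        else:
            raise ModelValidationError(f"{path}: no objective reaction found")

    model = MetabolicModel(
        id=sbml_model.getId() or "model",
        metabolites=metabolites,
        reactions=reactions,
        objective_id=objective_id,
        compartments=compartments,
    )
    model.validate()
    return model


def _bounds_from_notes_or_kinetics(rx) -> tuple[float, float]:
    kl = rx.getKineticLaw()
    if kl is not None:
        lb = ub = None
        for i in range(kl.getNumParameters()):
            p = kl.getParameter(i)
            if p.getId() == "LOWER_BOUND":
                lb = p.getValue()
            elif p.getId() == "UPPER_BOUND":
                ub = p.getValue()
        if lb is not None and ub is not None:
            return lb, ub
    return (-DEFAULT_BOUND if rx.getReversible() else 0.0, DEFAULT_BOUND)


def _association_to_gpr(assoc, gene_names: Mapping[str, str]) -> GPRExpression:
    import libsbml

    if assoc is None:
        return GPRExpression()
    if isinstance(assoc, libsbml.GeneProductRef):
        gid = assoc.getGeneProduct()
        return GPRExpression(op="gene", gene=gene_names.get(gid, gid))
    children = tuple(
        _association_to_gpr(assoc.getAssociation(i), gene_names)
        for i in range(assoc.getNumAssociations())
    )
    op = "and" if isinstance(assoc, libsbml.FbcAnd) else "or"
    return GPRExpression(op=op, children=children)


def write_sbml(model: MetabolicModel, path: str) -> None:
    """Write the model as SBML Level 3 + fbc v2.

    The emitted file round-trips through :func:`read_sbml` to a field-by-field
    identical model: bounds become fbc flux-bound parameters, GPRs become
    gene-product associations (omitted entirely for empty associations), the
    objective becomes the active fbc objective, and the category is carried in
    an SBO term (exchange/demand) plus a note for the full five-way category.
    """
    import libsbml

    model.validate()
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.id)
    m_fbc = sm.getPlugin("fbc")
    m_fbc.setStrict(True)

    for cid in sorted(model.compartments or {m.compartment for m in model.metabolites}):
        comp = sm.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)
        name = (model.compartments or {}).get(cid, cid)
        comp.setName(name)

    for met in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(met.boundary)
        sp.setConstant(False)
        sp_fbc = sp.getPlugin("fbc")
        if met.formula is not None:
            sp_fbc.setChemicalFormula(met.formula)
        if met.charge is not None:
            sp_fbc.setCharge(int(met.charge))

    for gene in sorted(model.genes):
        gp = m_fbc.createGeneProduct()
        gp.setId(_sanitize_id(gene))
        gp.setLabel(gene)

    bound_params: dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    gene_id_map = {g: _sanitize_id(g) for g in model.genes}

    for r in model.reactions:
        rx = sm.createReaction()
        rx.setId(r.id)
        rx.setName(r.name or r.id)
        rx.setReversible(r.lower_bound < 0)
        rx.setFast(False)
        sbo = _CATEGORY_TO_SBO.get(r.category)
        if sbo is not None:
            rx.setSBOTerm(sbo)
        rx.setNotes(
            f"<body xmlns='http://www.w3.org/1999/xhtml'>"
            f"<p>COFACTORSCOPE_CATEGORY: {r.category}</p></body>"
        )
        for met, coef in r.stoichiometry.items():
            if coef < 0:
                sr = rx.createReactant()
                sr.setStoichiometry(-coef)
            else:
                sr = rx.createProduct()
                sr.setStoichiometry(coef)
            sr.setSpecies(met)
            sr.setConstant(True)
        rx_fbc = rx.getPlugin("fbc")
        rx_fbc.setLowerFluxBound(_bound_param(r.lower_bound))
        rx_fbc.setUpperFluxBound(_bound_param(r.upper_bound))
        if not r.gpr.is_empty:
            gpa = rx_fbc.createGeneProductAssociation()
            gpa.setAssociation(_gpr_to_infix(r.gpr, gene_id_map), True, False)

    obj = m_fbc.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    fo = obj.createFluxObjective()
    fo.setReaction(model.objective_id)
    fo.setCoefficient(1.0)
    m_fbc.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"could not write SBML to {path}")


def _sanitize_id(gene: str) -> str:
    s = re.sub(r"[^A-Za-z0-9_]", "_", gene)
    if not re.match(r"[A-Za-z_]", s):
        s = "G_" + s
    return s


def _gpr_to_infix(gpr: GPRExpression, gene_id_map: Mapping[str, str]) -> str:
    if gpr.op == "gene":
        return gene_id_map.get(gpr.gene, gpr.gene)  # type: ignore[arg-type]
    parts = [f"({_gpr_to_infix(c, gene_id_map)})" for c in gpr.children]
    return (" and " if gpr.op == "and" else " or ").join(parts)
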