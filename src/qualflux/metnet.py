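"""Metabolic model data structures, SBML I/O, and the constraint file.

Models are stoichiometric: metabolites, reactions with flux bounds in
mmol/(gDW·h), optional gene-protein-reaction (GPR) boolean expressions,
and a linear objective.  External (boundary) metabolites are exempt from
mass balance; they are connected to the network by exchange reactions
whose bounds encode the environment.

Two SBML dialects are read: Level 3 with the fbc (v2) package, and the
legacy Level 2 COBRA dialect (bounds in kinetic-law parameters, GPR in a
``GENE_ASSOCIATION:`` note, boundary metabolites flagged either by
``boundaryCondition="true"`` or by the ``_b`` id suffix).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple, Union

import libsbml

from .qualio import And, Cmp, LogicExpr, Lit, Not, Or, QualModelError, expr_species

__all__ = [
    "Metabolite",
    "Reaction",
    "Objective",
    "MetabolicModel",
    "ConstraintFile",
    "ModelError",
    "read_sbml_metabolic",
    "write_sbml_metabolic",
    "parse_constraint_file",
    "find_exchange_reactions",
    "evaluate_gpr",
    "parse_gpr",
    "split_overrides",
]

log = logging.getLogger(__name__)

DEFAULT_BOUND = 9999.0


class ModelError(ValueError):
    """Raised for invalid model structure or unreadable files."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    is_external: bool = False


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds and an optional GPR."""

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gpr: Optional[LogicExpr] = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r}: empty stoichiometry")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0


@dataclass
class Objective:
    coeffs: Dict[str, float]
    sense: str = "MAX"  # MAX | MIN

    def __post_init__(self) -> None:
        if self.sense not in ("MAX", "MIN"):
            raise ModelError(f"objective sense must be MAX or MIN, got {self.sense!r}")


@dataclass
class MetabolicModel:
    metabolites: Dict[str, Metabolite] = field(default_factory=dict)
    reactions: Dict[str, Reaction] = field(default_factory=dict)
    objective: Optional[Objective] = None
    default_bound: float = DEFAULT_BOUND
    id: str = "model"

    def add_metabolite(self, m: Metabolite) -> None:
        if m.id in self.metabolites:
            raise ModelError(f"duplicate metabolite id {m.id!r}")
        self.metabolites[m.id] = m

    def add_reaction(self, r: Reaction) -> None:
        if r.id in self.reactions:
            raise ModelError(f"duplicate reaction id {r.id!r}")
        for mid in r.stoichiometry:
            if mid not in self.metabolites:
                raise ModelError(
                    f"reaction {r.id!r} references undeclared metabolite {mid!r}"
                )
        self.reactions[r.id] = r

    def validate(self) -> None:
        for r in self.reactions.values():
            for mid in r.stoichiometry:
                if mid not in self.metabolites:
                    raise ModelError(
                        f"reaction {r.id!r} references undeclared metabolite {mid!r}"
                    )
        if self.objective is not None:
            for rid in self.objective.coeffs:
                if rid not in self.reactions:
                    raise ModelError(f"objective references unknown reaction {rid!r}")

    def genes(self) -> set:
        out: set = set()
        for r in self.reactions.values():
            if r.gpr is not None:
                out |= expr_species(r.gpr)
        return out


# --------------------------------------------------------------------------
# GPR expressions

_GPR_TOKEN = re.compile(r"\(|\)|\band\b|\bor\b|\bAND\b|\bOR\b|[^\s()]+")


def parse_gpr(text: str) -> Optional[LogicExpr]:
    """Parse a COBRA-style GPR string, e.g. ``(g1 and g2) or g3``.

    Genes become ``gene >= 1`` comparisons so the expression shares the
    regulatory-logic representation.  Returns None for an empty string.
    """
    tokens = _GPR_TOKEN.findall(text)
    if not tokens:
        return None
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> LogicExpr:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else Or(*terms)

    def parse_and() -> LogicExpr:
        terms = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            terms.append(parse_atom())
        return terms[0] if len(terms) == 1 else And(*terms)

    def parse_atom() -> LogicExpr:
        tok = peek()
        if tok is None:
            raise ModelError(f"GPR parse error in {text!r}: unexpected end")
        if tok == "(":
            take()
            inner = parse_or()
            if peek() != ")":
                raise ModelError(f"GPR parse error in {text!r}: missing ')'")
            take()
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ModelError(f"GPR parse error in {text!r}: unexpected {tok!r}")
        return Cmp(take(), ">=", 1)

    expr = parse_or()
    if pos != len(tokens):
        raise ModelError(f"GPR parse error in {text!r}: trailing {tokens[pos:]!r}")
    return expr


def evaluate_gpr(
    gpr: Optional[LogicExpr], gene_states: Mapping[str, float]
) -> bool:
    """A gene is active iff its level/value is nonzero; absent genes are
    unregulated and default to active.  A reaction with no GPR is active."""
    if gpr is None:
        return True
    if isinstance(gpr, Lit):
        return gpr.value
    if isinstance(gpr, Cmp):
        return gene_states.get(gpr.species, 1) != 0
    if isinstance(gpr, And):
        return all(evaluate_gpr(a, gene_states) for a in gpr.args)
    if isinstance(gpr, Or):
        return any(evaluate_gpr(a, gene_states) for a in gpr.args)
    if isinstance(gpr, Not):
        return not evaluate_gpr(gpr.arg, gene_states)
    raise ModelError(f"not a GPR expression: {gpr!r}")


def _gpr_to_string(gpr: LogicExpr) -> str:
    if isinstance(gpr, Cmp):
        return gpr.species
    if isinstance(gpr, And):
        return "(" + " and ".join(_gpr_to_string(a) for a in gpr.args) + ")"
    if isinstance(gpr, Or):
        return "(" + " or ".join(_gpr_to_string(a) for a in gpr.args) + ")"
    raise ModelError(f"cannot serialise GPR node {gpr!r}")


# --------------------------------------------------------------------------
# SBML reading


def read_sbml_metabolic(path: str, default_bound: float = DEFAULT_BOUND) -> MetabolicModel:
    """Read a metabolic model from SBML (L3+fbc, or L2 COBRA notes)."""
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelError(f"cannot read {path}: {err.getMessage().strip()}")
    smodel = doc.getModel()
    if smodel is None:
        raise ModelError(f"{path} contains no SBML model")

    model = MetabolicModel(default_bound=default_bound, id=smodel.getId() or "model")
    for i in range(smodel.getNumSpecies()):
        sp = smodel.getSpecies(i)
        external = sp.getBoundaryCondition() or sp.getId().endswith("_b")
        model.add_metabolite(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "c",
                is_external=external,
            )
        )

    fbc = smodel.getPlugin("fbc")
    for i in range(smodel.getNumReactions()):
        sr = smodel.getReaction(i)
        stoich: Dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()

        lb, ub = _read_bounds(sr, smodel, sr.getReversible(), default_bound)
        gpr = _read_gpr(sr)
        model.add_reaction(
            Reaction(
                id=sr.getId(),
                name=sr.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
            )
        )

    obj = _read_objective(smodel, fbc)
    if obj is not None:
        model.objective = obj
    model.validate()
    return model


def _read_bounds(
    sr: libsbml.Reaction, smodel: libsbml.Model, reversible: bool, default_bound: float
) -> Tuple[float, float]:
    rfbc = sr.getPlugin("fbc")
    lb = ub = None
    if rfbc is not None:
        if rfbc.isSetLowerFluxBound():
            p = smodel.getParameter(rfbc.getLowerFluxBound())
            if p is not None:
                lb = p.getValue()
        if rfbc.isSetUpperFluxBound():
            p = smodel.getParameter(rfbc.getUpperFluxBound())
            if p is not None:
                ub = p.getValue()
    if (lb is None or ub is None) and sr.isSetKineticLaw():
        kl = sr.getKineticLaw()
        for k in range(kl.getNumParameters()):
            p = kl.getParameter(k)
            if p.getId() == "LOWER_BOUND" and lb is None:
                lb = p.getValue()
            elif p.getId() == "UPPER_BOUND" and ub is None:
                ub = p.getValue()
    if lb is None:
        lb = -default_bound if reversible else 0.0
    if ub is None:
        ub = default_bound
    # clip SBML infinities to the configurable default magnitude
    if math.isinf(lb):
        lb = -default_bound
    if math.isinf(ub):
        ub = default_bound
    return lb, ub


def _read_gpr(sr: libsbml.Reaction) -> Optional[LogicExpr]:
    rfbc = sr.getPlugin("fbc")
    if rfbc is not None and rfbc.isSetGeneProductAssociation():
        assoc = rfbc.getGeneProductAssociation().getAssociation()
        try:
            return _fbc_assoc_to_expr(assoc)
        except ModelError as exc:
            log.warning("reaction %s: dropping unparsable GPR (%s)", sr.getId(), exc)
            return None
    if sr.isSetNotes():
        notes = sr.getNotesString()
        m = re.search(r"GENE_ASSOCIATION:\s*([^<\n]*)", notes)
        if m:
            text = m.group(1).strip()
            if text:
                try:
                    return parse_gpr(text)
                except ModelError as exc:
                    log.warning(
                        "reaction %s: dropping unparsable GPR (%s)", sr.getId(), exc
                    )
    return None


def _fbc_assoc_to_expr(assoc: libsbml.Association) -> LogicExpr:
    if assoc is None:
        raise ModelError("empty fbc association")
    if assoc.isGeneProductRef():
        return Cmp(assoc.getGeneProduct(), ">=", 1)
    if assoc.isFbcAnd():
        return And(*(_fbc_assoc_to_expr(assoc.getAssociation(i))
                     for i in range(assoc.getNumAssociations())))
    if assoc.isFbcOr():
        return Or(*(_fbc_assoc_to_expr(assoc.getAssociation(i))
                    for i in range(assoc.getNumAssociations())))
    raise ModelError(f"unsupported fbc association node {assoc!r}")


def _read_objective(
    smodel: libsbml.Model, fbc
) -> Optional[Objective]:
    if fbc is not None and fbc.getNumObjectives() > 0:
        active = fbc.getActiveObjective() or fbc.getObjective(0)
        if active is not None and active.getNumFluxObjectives() > 0:
            coeffs = {
                active.getFluxObjective(i).getReaction(): active.getFluxObjective(i).getCoefficient()
                for i in range(active.getNumFluxObjectives())
            }
            sense = "MIN" if active.getType() == "minimize" else "MAX"
            return Objective(coeffs, sense)
    coeffs = {}
    for i in range(smodel.getNumReactions()):
        sr = smodel.getReaction(i)
        if sr.isSetKineticLaw():
            for k in range(sr.getKineticLaw().getNumParameters()):
                p = sr.getKineticLaw().getParameter(k)
                if p.getId() == "OBJECTIVE_COEFFICIENT" and p.getValue() != 0:
                    coeffs[sr.getId()] = p.getValue()
    if coeffs:
        return Objective(coeffs, "MAX")
    return None


# --------------------------------------------------------------------------
# SBML writing (L3 + fbc v2) — round-trip support and fixture export


def write_sbml_metabolic(model: MetabolicModel, path: str) -> None:
    model.validate()
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.id)
    mfbc = sm.getPlugin("fbc")
    mfbc.setStrict(True)

    compartments = sorted({m.compartment for m in model.metabolites.values()})
    for cid in compartments:
        c = sm.createCompartment()
        c.setId(cid)
        c.setConstant(True)

    for met in model.metabolites.values():
        sp = sm.createSpecies()
        sp.setId(met.id)
        if met.name:
            sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setBoundaryCondition(met.is_external)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)

    for gid in sorted(model.genes()):
        gp = mfbc.createGeneProduct()
        gp.setId(gid)
        gp.setLabel(gid)

    bounds_seen: Dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bounds_seen:
            pid = f"bnd_{len(bounds_seen)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bounds_seen[value] = pid
        return bounds_seen[value]

    for r in model.reactions.values():
        sr = sm.createReaction()
        sr.setId(r.id)
        if r.name:
            sr.setName(r.name)
        sr.setReversible(r.lower_bound < 0)
        sr.setFast(False)
        for mid, coeff in r.stoichiometry.items():
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies(mid)
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rfbc = sr.getPlugin("fbc")
        rfbc.setLowerFluxBound(bound_param(r.lower_bound))
        rfbc.setUpperFluxBound(bound_param(r.upper_bound))
        if r.gpr is not None:
            ga = rfbc.createGeneProductAssociation()
            ga.setAssociation(_gpr_to_string(r.gpr))

    if model.objective is not None:
        obj = mfbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize" if model.objective.sense == "MAX" else "minimize")
        mfbc.setActiveObjectiveId("obj")
        for rid, coeff in model.objective.coeffs.items():
            fo = obj.createFluxObjective()
            fo.setReaction(rid)
            fo.setCoefficient(coeff)

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise ModelError(f"cannot write SBML file to {path}")


# --------------------------------------------------------------------------
# Constraint file

_OBJ_RE = re.compile(r"^obj\s*:\s*(MAX|MIN)\s*\(\s*(.+?)\s*\)\s*$", re.IGNORECASE)


@dataclass
class ConstraintFile:
    """Objective plus id overrides from the plain-text constraint file.

    Overrides are a single value (an equality / initial value) or an
    ``(lb, ub)`` pair.  What a single value *means* depends on what the id
    resolves to: reaction → both bounds fixed; regulatory component →
    initial override; external metabolite → concentration in mmol/l.
    """

    objective: Optional[Objective] = None
    overrides: Dict[str, Union[float, Tuple[float, float]]] = field(default_factory=dict)


def _parse_obj_expr(text: str) -> Dict[str, float]:
    """`R1`, `2*R1 + R2`, `2 R1 - 0.5 R2` → coefficient mapping."""
    coeffs: Dict[str, float] = {}
    for sign, term in re.findall(r"([+-]?)\s*([^+-]+)", text):
        term = term.strip()
        if not term:
            continue
        mult = -1.0 if sign == "-" else 1.0
        m = re.match(r"^([0-9.eE+-]+)\s*\*?\s*([A-Za-z_]\w*)$", term)
        if m:
            coeff, rid = float(m.group(1)), m.group(2)
        elif re.match(r"^[A-Za-z_]\w*$", term):
            coeff, rid = 1.0, term
        else:
            raise ModelError(f"malformed objective term {term!r}")
        coeffs[rid] = coeffs.get(rid, 0.0) + mult * coeff
    if not coeffs:
        raise ModelError(f"empty objective expression {text!r}")
    return coeffs


def parse_constraint_file(path: str) -> ConstraintFile:
    """Parse the constraint file: objective, value and interval overrides."""
    cf = ConstraintFile()
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            m = _OBJ_RE.match(line)
            if m:
                if cf.objective is not None:
                    raise ModelError(f"line {line_no}: duplicate objective")
                cf.objective = Objective(_parse_obj_expr(m.group(2)), m.group(1).upper())
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise ModelError(f"line {line_no}: malformed constraint {raw.strip()!r}")
            cid = parts[0]
            if cid in cf.overrides:
                raise ModelError(f"line {line_no}: duplicate id {cid!r}")
            try:
                values = [float(v) for v in parts[1:]]
            except ValueError:
                raise ModelError(
                    f"line {line_no}: malformed number in {raw.strip()!r}"
                ) from None
            cf.overrides[cid] = values[0] if len(values) == 1 else (values[0], values[1])
    return cf


def split_overrides(
    cf: ConstraintFile,
    model: Optional[MetabolicModel],
    net=None,
) -> Tuple[Dict[str, Tuple[float, float]], Dict[str, float], Dict[str, float]]:
    """Route constraint-file overrides to their targets.

    Returns ``(reaction_bounds, regulatory_overrides, concentrations)``.
    Reaction ids get bound pairs (a single value fixes both bounds and
    replaces the SBML bounds — the file is an explicit user override);
    regulatory component ids become RSA initial overrides; remaining ids
    are treated as external metabolite concentrations (mmol/l), which
    also serve as dynamic-FBA initial conditions.
    """
    rxn_bounds: Dict[str, Tuple[float, float]] = {}
    reg: Dict[str, float] = {}
    conc: Dict[str, float] = {}
    for cid, val in cf.overrides.items():
        if model is not None and cid in model.reactions:
            rxn_bounds[cid] = (val, val) if not isinstance(val, tuple) else val
        elif net is not None and cid in net.species:
            if isinstance(val, tuple):
                raise ModelError(
                    f"regulatory component {cid!r} cannot take a bound pair"
                )
            reg[cid] = val
            if model is not None and cid in model.metabolites:
                conc[cid] = float(val)
        elif model is not None and cid in model.metabolites:
            if isinstance(val, tuple):
                raise ModelError(f"metabolite {cid!r} cannot take a bound pair")
            conc[cid] = float(val)
        else:
            log.warning("constraint-file id %r matches nothing; ignored", cid)
    return rxn_bounds, reg, conc


def find_exchange_reactions(
    model: MetabolicModel,
) -> Dict[str, Tuple[str, int]]:
    """Map each external metabolite to its exchange reaction and uptake sign.

    An exchange reaction either involves a single species, or couples
    external (boundary) metabolites to exactly one internal one.  The
    uptake direction is the flux sign that increases the internal pool:
    +1 when positive flux imports, −1 when positive flux exports.
    """
    out: Dict[str, Tuple[str, int]] = {}
    for r in model.reactions.values():
        mets = list(r.stoichiometry)
        internal = [m for m in mets if not model.metabolites[m].is_external]
        external = [m for m in mets if model.metabolites[m].is_external]
        if len(mets) == 1:
            mid = mets[0]
            direction = 1 if r.stoichiometry[mid] > 0 else -1
            if model.metabolites[mid].is_external and mid not in out:
                out[mid] = (r.id, direction)
            elif not model.metabolites[mid].is_external and mid not in out:
                # demand/supply reaction on an internal pool: still an
                # exchange in the boundary sense
                out[mid] = (r.id, direction)
        elif external and len(internal) == 1:
            direction = 1 if r.stoichiometry[internal[0]] > 0 else -1
            for mid in external:
                if mid not in out:
                    out[mid] = (r.id, direction)
    for mid, met in model.metabolites.items():
        if met.is_external and mid not in out:
            log.warning("external metabolite %r has no exchange reaction", mid)
    return out
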