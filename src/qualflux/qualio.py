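"""Qualitative multi-state regulatory networks and SBML-qual I/O.

A regulatory network is a set of qualitative species, each taking integer
levels in ``[0, max_level]``, together with at most one transition (logical
update rule) per regulated species.  Species without a transition are
constant inputs — typically environmental metabolites.

A species may carry *equivalences*: a declared mapping from each qualitative
level to a continuous interval (concentration in mmol/l, or flux in
mmol/(gDW·h)).  Equivalences are stored in the notes of the SBML-qual
``qualitativeSpecies`` element, one ``STATE`` directive per line::

    STATE 0 : [0, 0]
    STATE 1 : ]0, 8.8]
    STATE 2 : ]8.8, +inf[

Both the European ``]a,b]`` and the parenthesis ``(a,b]`` open-bracket
dialects are accepted.  ``#`` starts a comment.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import libsbml

__all__ = [
    "Interval",
    "Lit",
    "Cmp",
    "And",
    "Or",
    "Not",
    "LogicExpr",
    "Transition",
    "QualSpecies",
    "RegulatoryNetwork",
    "NetworkState",
    "QualModelError",
    "evaluate_expr",
    "apply_transition",
    "parse_equivalence_note",
    "format_equivalence_note",
    "read_sbml_qual",
    "write_sbml_qual",
]


class QualModelError(ValueError):
    """Raised for invalid network structure or unsupported file content."""


# --------------------------------------------------------------------------
# Intervals


@dataclass(frozen=True)
class Interval:
    """A continuous interval, optionally open at either end.

    ``upper`` may be ``math.inf``; an infinite endpoint is always open.
    A degenerate interval (``lower == upper``) is closed at both ends.
    """

    lower: float
    upper: float
    lower_open: bool = False
    upper_open: bool = False

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise QualModelError(
                f"interval lower bound {self.lower} exceeds upper bound {self.upper}"
            )
        if self.lower == self.upper and (self.lower_open or self.upper_open):
            raise QualModelError("a degenerate interval must be closed at both ends")
        if math.isinf(self.upper) and not self.upper_open:
            object.__setattr__(self, "upper_open", True)

    def contains(self, x: float) -> bool:
        if x < self.lower or (x == self.lower and self.lower_open):
            return False
        if x > self.upper or (x == self.upper and self.upper_open):
            return False
        return True

    def overlaps(self, other: "Interval") -> bool:
        lo = max(self.lower, other.lower)
        hi = min(self.upper, other.upper)
        if lo > hi:
            return False
        if lo < hi:
            return True
        # touching endpoints: overlap only if the shared point is in both
        return self.contains(lo) and other.contains(lo)

    def __str__(self) -> str:
        lo = "]" if self.lower_open else "["
        hi = "[" if self.upper_open else "]"
        up = "+inf" if math.isinf(self.upper) else repr(self.upper)
        return f"{lo}{self.lower}, {up}{hi}"


# --------------------------------------------------------------------------
# Logic expressions

_OPS = {
    "==": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
    ">=": lambda a, b: a >= b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    "<": lambda a, b: a < b,
}


@dataclass(frozen=True)
class Lit:
    value: bool


@dataclass(frozen=True)
class Cmp:
    """Comparison of one species level against an integer constant."""

    species: str
    op: str
    const: int

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise QualModelError(f"unknown comparison operator {self.op!r}")


@dataclass(frozen=True)
class And:
    args: Tuple["LogicExpr", ...]

    def __init__(self, *args: "LogicExpr"):
        object.__setattr__(self, "args", tuple(args))


@dataclass(frozen=True)
class Or:
    args: Tuple["LogicExpr", ...]

    def __init__(self, *args: "LogicExpr"):
        object.__setattr__(self, "args", tuple(args))


@dataclass(frozen=True)
class Not:
    arg: "LogicExpr"


LogicExpr = Union[Lit, Cmp, And, Or, Not]

NetworkState = Dict[str, int]


def expr_species(expr: LogicExpr) -> set:
    """All species ids referenced by an expression."""
    if isinstance(expr, Cmp):
        return {expr.species}
    if isinstance(expr, (And, Or)):
        out: set = set()
        for a in expr.args:
            out |= expr_species(a)
        return out
    if isinstance(expr, Not):
        return expr_species(expr.arg)
    return set()


def evaluate_expr(expr: LogicExpr, state: Mapping[str, int]) -> bool:
    """Evaluate a logic expression against a complete network state."""
    if isinstance(expr, Lit):
        return expr.value
    if isinstance(expr, Cmp):
        try:
            level = state[expr.species]
        except KeyError:
            raise QualModelError(
                f"expression references species {expr.species!r} absent from state"
            ) from None
        return _OPS[expr.op](level, expr.const)
    if isinstance(expr, And):
        return all(evaluate_expr(a, state) for a in expr.args)
    if isinstance(expr, Or):
        return any(evaluate_expr(a, state) for a in expr.args)
    if isinstance(expr, Not):
        return not evaluate_expr(expr.arg, state)
    raise QualModelError(f"not a logic expression: {expr!r}")


# --------------------------------------------------------------------------
# Transitions and species


@dataclass(frozen=True)
class Transition:
    """Update rule for one species: ordered function terms plus a default.

    The first term whose condition holds fixes the next level; if none
    holds, ``default_level`` applies.
    """

    target: str
    terms: Tuple[Tuple[LogicExpr, int], ...]
    default_level: int = 0

    def __init__(
        self,
        target: str,
        terms: Iterable[Tuple[LogicExpr, int]] = (),
        default_level: int = 0,
    ):
        object.__setattr__(self, "target", target)
        object.__setattr__(self, "terms", tuple((e, int(r)) for e, r in terms))
        object.__setattr__(self, "default_level", int(default_level))


def apply_transition(t: Transition, state: Mapping[str, int]) -> int:
    """Next level of ``t.target``: first matching term, else the default."""
    for cond, result in t.terms:
        if evaluate_expr(cond, state):
            return result
    return t.default_level


@dataclass
class QualSpecies:
    id: str
    name: str = ""
    max_level: int = 1
    initial_level: int = 0
    equivalences: Optional[Dict[int, Interval]] = None

    def __post_init__(self) -> None:
        if not 0 <= self.initial_level <= self.max_level:
            raise QualModelError(
                f"species {self.id!r}: initial level {self.initial_level} "
                f"outside [0, {self.max_level}]"
            )
        if self.equivalences is not None:
            levels = sorted(self.equivalences)
            if levels != list(range(self.max_level + 1)):
                raise QualModelError(
                    f"species {self.id!r}: equivalences must cover every level "
                    f"0..{self.max_level} exactly once (got {levels})"
                )
            _check_disjoint(self.equivalences, self.id)

    def level_for_value(self, value: float) -> int:
        """Translate a quantitative value to its qualitative level.

        If dialect mixing makes a boundary point belong to two intervals,
        the lowest matching level wins.
        """
        if self.equivalences is None:
            raise QualModelError(
                f"species {self.id!r} has no state/interval equivalences; "
                "cannot translate a quantitative value"
            )
        for level in sorted(self.equivalences):
            if self.equivalences[level].contains(value):
                return level
        raise QualModelError(
            f"value {value} of species {self.id!r} falls in no declared interval"
        )


def _check_disjoint(eqs: Mapping[int, Interval], species_id: str) -> None:
    levels = sorted(eqs)
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            if eqs[a].overlaps(eqs[b]):
                raise QualModelError(
                    f"species {species_id!r}: intervals for levels {a} and {b} "
                    f"overlap ({eqs[a]} vs {eqs[b]})"
                )


# --------------------------------------------------------------------------
# The network


@dataclass
class RegulatoryNetwork:
    """Qualitative network: species plus at most one transition per target."""

    species: Dict[str, QualSpecies] = field(default_factory=dict)
    transitions: Dict[str, Transition] = field(default_factory=dict)

    def add_species(self, sp: QualSpecies) -> None:
        if sp.id in self.species:
            raise QualModelError(f"duplicate species id {sp.id!r}")
        self.species[sp.id] = sp

    def add_transition(self, t: Transition) -> None:
        if t.target in self.transitions:
            raise QualModelError(f"duplicate transition for target {t.target!r}")
        self.transitions[t.target] = t

    def validate(self) -> None:
        for t in self.transitions.values():
            if t.target not in self.species:
                raise QualModelError(
                    f"transition targets undeclared species {t.target!r}"
                )
            tmax = self.species[t.target].max_level
            for expr, result in t.terms:
                for sid in expr_species(expr):
                    if sid not in self.species:
                        raise QualModelError(
                            f"transition for {t.target!r} references undeclared "
                            f"species {sid!r}"
                        )
                if not 0 <= result <= tmax:
                    raise QualModelError(
                        f"transition for {t.target!r}: result level {result} "
                        f"outside [0, {tmax}]"
                    )
            if not 0 <= t.default_level <= tmax:
                raise QualModelError(
                    f"transition for {t.target!r}: default level "
                    f"{t.default_level} outside [0, {tmax}]"
                )

    @property
    def inputs(self) -> List[str]:
        """Species with no update rule: constant environmental inputs."""
        return [sid for sid in self.species if sid not in self.transitions]

    def initial_state(self) -> NetworkState:
        return {sid: sp.initial_level for sid, sp in self.species.items()}

    def n_states(self) -> int:
        """Size of the full state space, ∏(max_level + 1)."""
        n = 1
        for sp in self.species.values():
            n *= sp.max_level + 1
        return n


# --------------------------------------------------------------------------
# Equivalence-note grammar

_STATE_RE = re.compile(
    r"""^STATE\s*(?P<level>\d+)\s*:\s*
        (?P<lb>[\[\]\(])\s*(?P<lo>[^,\s]+)\s*,\s*(?P<hi>[^\]\[\)\s]+)\s*(?P<ub>[\]\[\)])$""",
    re.VERBOSE,
)


def _parse_real(tok: str, line_no: int) -> float:
    tok = tok.strip()
    if tok.lower() in ("+inf", "inf", "+infinity", "infinity"):
        return math.inf
    try:
        return float(tok)
    except ValueError:
        raise QualModelError(f"line {line_no}: malformed number {tok!r}") from None


def parse_equivalence_note(text: str) -> Dict[int, Interval]:
    """Parse STATE directives mapping qualitative levels to intervals.

    Raises on duplicate levels, overlapping intervals, or malformed lines.
    """
    out: Dict[int, Interval] = {}
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if not line.upper().startswith("STATE"):
            continue
        m = _STATE_RE.match(line)
        if m is None:
            raise QualModelError(f"line {line_no}: malformed STATE directive {raw!r}")
        level = int(m.group("level"))
        if level in out:
            raise QualModelError(f"line {line_no}: duplicate STATE {level}")
        lo = _parse_real(m.group("lo"), line_no)
        hi = _parse_real(m.group("hi"), line_no)
        lower_open = m.group("lb") in ("]", "(")
        upper_open = m.group("ub") in ("[", ")")
        out[level] = Interval(lo, hi, lower_open=lower_open, upper_open=upper_open)
    _check_disjoint(out, "<note>")
    return out


def format_equivalence_note(eqs: Mapping[int, Interval]) -> str:
    lines = []
    for level in sorted(eqs):
        iv = eqs[level]
        lo = "]" if iv.lower_open else "["
        hi = "[" if iv.upper_open else "]"
        up = "+inf" if math.isinf(iv.upper) else _fmt_num(iv.upper)
        lines.append(f"STATE {level} : {lo}{_fmt_num(iv.lower)}, {up}{hi}")
    return "\n".join(lines)


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(x)


# --------------------------------------------------------------------------
# SBML-qual reading

_RELATIONAL = {
    libsbml.AST_RELATIONAL_EQ: "==",
    libsbml.AST_RELATIONAL_NEQ: "!=",
    libsbml.AST_RELATIONAL_GEQ: ">=",
    libsbml.AST_RELATIONAL_LEQ: "<=",
    libsbml.AST_RELATIONAL_GT: ">",
    libsbml.AST_RELATIONAL_LT: "<",
}

_FLIP = {"==": "==", "!=": "!=", ">=": "<=", "<=": ">=", ">": "<", "<": ">"}


def _ast_to_expr(node: libsbml.ASTNode) -> LogicExpr:
    typ = node.getType()
    if typ == libsbml.AST_CONSTANT_TRUE:
        return Lit(True)
    if typ == libsbml.AST_CONSTANT_FALSE:
        return Lit(False)
    if typ == libsbml.AST_LOGICAL_AND:
        return And(*(_ast_to_expr(node.getChild(i)) for i in range(node.getNumChildren())))
    if typ == libsbml.AST_LOGICAL_OR:
        return Or(*(_ast_to_expr(node.getChild(i)) for i in range(node.getNumChildren())))
    if typ == libsbml.AST_LOGICAL_NOT:
        if node.getNumChildren() != 1:
            raise QualModelError("MathML <not> must have exactly one child")
        return Not(_ast_to_expr(node.getChild(0)))
    if typ in _RELATIONAL:
        if node.getNumChildren() != 2:
            raise QualModelError("relational MathML node must have two children")
        left, right = node.getChild(0), node.getChild(1)
        op = _RELATIONAL[typ]
        if left.isName() and _is_int_node(right):
            return Cmp(left.getName(), op, _int_value(right))
        if right.isName() and _is_int_node(left):
            return Cmp(right.getName(), _FLIP[op], _int_value(left))
        raise QualModelError(
            "comparison must relate one species to one integer constant "
            f"(got {libsbml.formulaToL3String(node)!r})"
        )
    raise QualModelError(
        f"unsupported MathML construct {node.getName() or libsbml.formulaToL3String(node)!r}"
    )


def _is_int_node(node: libsbml.ASTNode) -> bool:
    if node.isInteger():
        return True
    return node.isReal() and float(node.getValue()).is_integer()


def _int_value(node: libsbml.ASTNode) -> int:
    return int(node.getValue())


def _notes_text(sbase: libsbml.SBase) -> str:
    """Plain-text content of an SBML notes element (XHTML stripped)."""
    if not sbase.isSetNotes():
        return ""
    node = sbase.getNotes()
    parts: List[str] = []

    def walk(n: libsbml.XMLNode) -> None:
        if n.isText():
            parts.append(n.getCharacters())
        for i in range(n.getNumChildren()):
            walk(n.getChild(i))
        # block-level XHTML elements separate directives
        if n.isElement() and n.getName() in ("p", "br", "div", "body", "pre"):
            parts.append("\n")

    walk(node)
    return "".join(parts)


def read_sbml_qual(path: str) -> RegulatoryNetwork:
    """Read a qualitative regulatory network from an SBML-qual file.

    Initial levels are mandatory; equivalences are parsed from STATE
    directives in species notes when present.  Unsupported MathML in a
    function term raises, naming the construct.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise QualModelError(f"cannot read {path}: {err.getMessage().strip()}")
    model = doc.getModel()
    if model is None:
        raise QualModelError(f"{path} contains no SBML model")
    qual = model.getPlugin("qual")
    if qual is None:
        raise QualModelError(f"{path} does not use the SBML qual package")

    net = RegulatoryNetwork()
    # (id, name, max_level or None, initial_level, equivalences or None);
    # construction is deferred until transitions reveal referenced levels
    pending: List[Tuple[str, str, Optional[int], int, Optional[Dict[int, Interval]]]] = []
    for i in range(qual.getNumQualitativeSpecies()):
        qs = qual.getQualitativeSpecies(i)
        sid = qs.getId()
        if not qs.isSetInitialLevel():
            raise QualModelError(f"species {sid!r} has no initial level")
        max_level = qs.getMaxLevel() if qs.isSetMaxLevel() else None
        note = _notes_text(qs)
        eqs = parse_equivalence_note(note) if "STATE" in note.upper() else None
        pending.append((sid, qs.getName() or "", max_level, qs.getInitialLevel(), eqs))

    transitions: Dict[str, Transition] = {}
    referenced_levels: Dict[str, int] = {}
    for i in range(qual.getNumTransitions()):
        tr = qual.getTransition(i)
        if tr.getNumOutputs() != 1:
            raise QualModelError(
                f"transition {tr.getId() or i} must have exactly one output"
            )
        target = tr.getOutput(0).getQualitativeSpecies()
        terms: List[Tuple[LogicExpr, int]] = []
        for j in range(tr.getNumFunctionTerms()):
            ft = tr.getFunctionTerm(j)
            math_node = ft.getMath()
            if math_node is None:
                raise QualModelError(
                    f"transition for {target!r}: function term without math"
                )
            expr = _ast_to_expr(math_node)
            terms.append((expr, ft.getResultLevel()))
            referenced_levels[target] = max(
                referenced_levels.get(target, 0), ft.getResultLevel()
            )
        default = tr.getDefaultTerm().getResultLevel() if tr.isSetDefaultTerm() else 0
        referenced_levels[target] = max(referenced_levels.get(target, 0), default)
        if target in transitions:
            raise QualModelError(f"duplicate transition for target {target!r}")
        transitions[target] = Transition(target, terms, default)

    for sid, name, max_level, init, eqs in pending:
        if max_level is None:
            # fall back to the largest level any rule or equivalence mentions
            max_level = referenced_levels.get(sid, 0)
            if eqs:
                max_level = max(max_level, max(eqs))
            max_level = max(max_level, init)
        net.add_species(
            QualSpecies(
                id=sid,
                name=name,
                max_level=max_level,
                initial_level=init,
                equivalences=eqs,
            )
        )
    for t in transitions.values():
        net.add_transition(t)
    net.validate()
    return net


# --------------------------------------------------------------------------
# SBML-qual writing


def _expr_to_l3(expr: LogicExpr) -> str:
    if isinstance(expr, Lit):
        return "true" if expr.value else "false"
    if isinstance(expr, Cmp):
        return f"({expr.species} {expr.op} {expr.const})"
    if isinstance(expr, And):
        if not expr.args:
            return "true"
        return "(" + " && ".join(_expr_to_l3(a) for a in expr.args) + ")"
    if isinstance(expr, Or):
        if not expr.args:
            return "false"
        return "(" + " || ".join(_expr_to_l3(a) for a in expr.args) + ")"
    if isinstance(expr, Not):
        return f"!({_expr_to_l3(expr.arg)})"
    raise QualModelError(f"not a logic expression: {expr!r}")


def write_sbml_qual(net: RegulatoryNetwork, path: str) -> None:
    """Write the network as SBML Level 3 with the qual package (v1)."""
    net.validate()
    ns = libsbml.QualPkgNamespaces(3, 1, 1)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("qual", True)
    model = doc.createModel()
    model.setId("regulatory_network")
    comp = model.createCompartment()
    comp.setId("default")
    comp.setConstant(True)
    qual = model.getPlugin("qual")

    for sp in net.species.values():
        qs = qual.createQualitativeSpecies()
        qs.setId(sp.id)
        if sp.name:
            qs.setName(sp.name)
        qs.setCompartment("default")
        qs.setConstant(sp.id not in net.transitions)
        qs.setMaxLevel(sp.max_level)
        qs.setInitialLevel(sp.initial_level)
        if sp.equivalences is not None:
            body = "\n".join(
                f"<p>{line}</p>" for line in format_equivalence_note(sp.equivalences).splitlines()
            )
            qs.setNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml">\n{body}\n</body>'
            )

    for t in net.transitions.values():
        tr = qual.createTransition()
        tr.setId(f"tr_{t.target}")
        regulators = set()
        for expr, _ in t.terms:
            regulators |= expr_species(expr)
        for rid in sorted(regulators):
            inp = tr.createInput()
            inp.setQualitativeSpecies(rid)
            inp.setTransitionEffect(
                libsbml.INPUT_TRANSITION_EFFECT_NONE
            )
        out = tr.createOutput()
        out.setQualitativeSpecies(t.target)
        out.setTransitionEffect(libsbml.OUTPUT_TRANSITION_EFFECT_ASSIGNMENT_LEVEL)
        for expr, result in t.terms:
            ft = tr.createFunctionTerm()
            ft.setResultLevel(result)
            ast = libsbml.parseL3Formula(_expr_to_l3(expr))
            if ast is None:
                raise QualModelError(
                    f"cannot serialise expression for {t.target!r}: "
                    f"{_expr_to_l3(expr)}"
                )
            ft.setMath(ast)
        dt = tr.createDefaultTerm()
        dt.setResultLevel(t.default_level)

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise QualModelError(f"cannot write SBML-qual file to {path}")
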