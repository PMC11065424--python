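"""Parsing and evaluation of KEGG-style module definition strings.

A KEGG module definition encodes the ordered reaction steps of a metabolic
module as a boolean expression over KEGG Ortholog (KO) identifiers:

* whitespace separates ordered steps (conjunction across steps);
* ``,`` separates alternative KOs or sub-expressions (disjunction);
* ``+`` joins the subunits of a protein complex (conjunction, binds
  tighter than ``,``);
* a leading ``-`` marks a non-essential (optional) component that never
  counts toward completeness;
* a bare ``--`` is a wildcard step (an unannotatable reaction) that is
  always considered satisfied;
* parentheses group arbitrarily.

The module exposes four operations: :func:`parse_definition`,
:func:`enumerate_completion_sets`, :func:`evaluate_module` and
:func:`gap_fill`.  A *completion set* is one minimal choice of KOs that
satisfies every step of a module; a genome completes a module when its KO
set contains at least one completion set.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterator, Optional as TOptional

__all__ = [
    "Atom",
    "AnyOf",
    "AllOf",
    "Complex",
    "Optional",
    "Wildcard",
    "ModuleAST",
    "ModuleEvaluation",
    "DefinitionSyntaxError",
    "EnumerationOverflow",
    "parse_definition",
    "serialize",
    "enumerate_completion_sets",
    "evaluate_module",
    "gap_fill",
    "atom_kos",
]

KO_TOKEN = re.compile(r"[A-Za-z0-9_.]+")


class DefinitionSyntaxError(ValueError):
    """Raised for malformed definition strings; carries the 0-based position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class EnumerationOverflow(RuntimeError):
    """Raised when a module has more completion sets than the caller's limit."""


# ---------------------------------------------------------------------------
# AST node types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    ko: str


@dataclass(frozen=True)
class AnyOf:
    options: tuple


@dataclass(frozen=True)
class AllOf:
    parts: tuple


@dataclass(frozen=True)
class Complex:
    parts: tuple


@dataclass(frozen=True)
class Optional:
    inner: object


@dataclass(frozen=True)
class Wildcard:
    pass


StepExpr = object  # Atom | AnyOf | AllOf | Complex | Optional | Wildcard


@dataclass(frozen=True)
class ModuleAST:
    """A parsed module definition: an ordered tuple of step expressions."""

    module_id: str
    steps: tuple

    @property
    def definition(self) -> str:
        return serialize_steps(self.steps)


@dataclass
class ModuleEvaluation:
    """Outcome of checking a KO set against a module definition."""

    module_id: str
    status: str  # "complete" | "incomplete"
    steps_total: int
    steps_satisfied: int
    completeness: float
    missing_kos: frozenset


# ---------------------------------------------------------------------------
# Parser (recursive descent; precedence: space < comma < plus/minus)
# ---------------------------------------------------------------------------

class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0
        self.n = len(text)

    def error(self, message: str) -> DefinitionSyntaxError:
        return DefinitionSyntaxError(message, self.pos)

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < self.n else ""

    def skip_ws(self) -> bool:
        start = self.pos
        while self.pos < self.n and self.text[self.pos].isspace():
            self.pos += 1
        return self.pos > start

    def parse_space_parts(self) -> list:
        """Whitespace-separated conjunction members; loosest binding."""
        parts = [self.parse_comma_list()]
        while True:
            mark = self.pos
            had_ws = self.skip_ws()
            if not had_ws or self.peek() in ("", ")"):
                self.pos = mark
                break
            parts.append(self.parse_comma_list())
        return parts

    def parse_space_list(self) -> StepExpr:
        parts = self.parse_space_parts()
        if len(parts) == 1:
            return parts[0]
        return AllOf(tuple(parts))

    def parse_comma_list(self) -> StepExpr:
        parts = [self.parse_plus_chain()]
        while self.peek() == ",":
            self.pos += 1
            if self.peek() in ("", ")", ",", " "):
                raise self.error("empty alternative after ','")
            parts.append(self.parse_plus_chain())
        if len(parts) == 1:
            return parts[0]
        # flatten nested disjunctions: (a,b),c === a,b,c
        flat = []
        for p in parts:
            if isinstance(p, AnyOf):
                flat.extend(p.options)
            else:
                flat.append(p)
        return AnyOf(tuple(flat))

    def parse_plus_chain(self) -> StepExpr:
        first = self.parse_primary(allow_optional=True)
        parts = [first]
        while self.peek() in ("+", "-"):
            op = self.text[self.pos]
            # a lone "--" wildcard is handled in parse_primary; here "-"
            # marks the next complex member as optional
            self.pos += 1
            member = self.parse_primary(allow_optional=False)
            parts.append(Optional(member) if op == "-" else member)
        if len(parts) == 1:
            return parts[0]
        return Complex(tuple(parts))

    def parse_primary(self, allow_optional: bool) -> StepExpr:
        c = self.peek()
        if c == "-":
            if self.text[self.pos : self.pos + 2] == "--" and not (
                self.pos + 2 < self.n and KO_TOKEN.match(self.text[self.pos + 2])
            ):
                self.pos += 2
                return Wildcard()
            if not allow_optional:
                raise self.error("unexpected '-'")
            self.pos += 1
            return Optional(self.parse_primary(allow_optional=False))
        if c == "(":
            open_pos = self.pos
            self.pos += 1
            self.skip_ws()
            inner = self.parse_space_list()
            self.skip_ws()
            if self.peek() != ")":
                self.pos = open_pos
                raise self.error("unbalanced '('")
            self.pos += 1
            return inner
        m = KO_TOKEN.match(self.text, self.pos)
        if not m:
            raise self.error(f"illegal token {c!r}" if c else "unexpected end of definition")
        self.pos = m.end()
        return Atom(m.group())


def parse_definition(module_id: str, definition: str) -> ModuleAST:
    """Parse a definition string into a :class:`ModuleAST`.

    Raises :class:`DefinitionSyntaxError` (with position) on unbalanced
    parentheses, empty alternatives or illegal tokens.
    """
    if not definition or not definition.strip():
        raise DefinitionSyntaxError("empty definition", 0)
    p = _Parser(definition.strip())
    # top-level whitespace-separated members are the ordered steps; a
    # parenthesised group stays one step even if it is itself a conjunction
    steps = p.parse_space_parts()
    if p.pos != p.n:
        if p.peek() == ")":
            raise DefinitionSyntaxError("unbalanced ')'", p.pos)
        raise DefinitionSyntaxError(f"trailing input {p.text[p.pos:]!r}", p.pos)
    return ModuleAST(module_id=module_id, steps=tuple(steps))


# ---------------------------------------------------------------------------
# Canonical serializer (inverse of the parser)
# ---------------------------------------------------------------------------

def _ser(expr: StepExpr, parent: str) -> str:
    """Serialize with parentheses wherever the child binds looser than its context."""
    if isinstance(expr, Atom):
        return expr.ko
    if isinstance(expr, Wildcard):
        return "--"
    if isinstance(expr, Optional):
        s = "-" + _ser(expr.inner, "unary")
        # "-" under another "-"/"+" must be grouped or it would read as "--"
        return f"({s})" if parent in ("unary", "plus") else s
    if isinstance(expr, Complex):
        out = [_ser(expr.parts[0], "plus")]
        for part in expr.parts[1:]:
            if isinstance(part, Optional):
                out.append("-" + _ser(part.inner, "unary"))
            else:
                out.append("+" + _ser(part, "plus"))
        s = "".join(out)
        # a complex nested in another plus-chain needs parentheses, or it
        # would reparse as one flat chain
        return f"({s})" if parent in ("unary", "plus") else s
    if isinstance(expr, AnyOf):
        s = ",".join(_ser(o, "comma") for o in expr.options)
        return f"({s})" if parent in ("plus", "unary") else s
    if isinstance(expr, AllOf):
        s = " ".join(_ser(p, "space") for p in expr.parts)
        return f"({s})" if parent in ("comma", "plus", "unary", "space") else s
    raise TypeError(f"not an AST node: {expr!r}")


def serialize_steps(steps: tuple) -> str:
    return " ".join(_ser(s, "space") for s in steps)


def serialize(ast: ModuleAST) -> str:
    """Render the AST back to a definition string; reparsing yields an equal AST."""
    return serialize_steps(ast.steps)


# ---------------------------------------------------------------------------
# Completion-set enumeration
# ---------------------------------------------------------------------------

def _count_upper(expr: StepExpr) -> int:
    if isinstance(expr, (Atom, Wildcard, Optional)):
        return 1
    if isinstance(expr, AnyOf):
        return sum(_count_upper(o) for o in expr.options)
    if isinstance(expr, (AllOf, Complex)):
        total = 1
        for p in expr.parts:
            total *= _count_upper(p)
        return total
    raise TypeError(expr)


def _enum(expr: StepExpr) -> list:
    if isinstance(expr, Atom):
        return [frozenset((expr.ko,))]
    if isinstance(expr, (Wildcard, Optional)):
        return [frozenset()]
    if isinstance(expr, AnyOf):
        out = []
        for o in expr.options:
            out.extend(_enum(o))
        return out
    if isinstance(expr, (AllOf, Complex)):
        out = [frozenset()]
        for p in expr.parts:
            out = [a | b for a, b in itertools.product(out, _enum(p))]
        return out
    raise TypeError(expr)


def _sort_key(s: frozenset):
    return (len(s), tuple(sorted(s)))


def enumerate_completion_sets(ast: ModuleAST, limit: int = 10_000) -> list:
    """Every distinct KO set obtained by choosing one branch in each
    alternative and taking all members of each conjunction/complex.

    Optional components and wildcards contribute nothing.  Output is
    deduplicated, pruned of strict supersets, and sorted by set size then
    lexicographically.  Raises :class:`EnumerationOverflow` when the number
    of branch choices exceeds ``limit``.
    """
    if limit < 1:
        raise ValueError("limit must be >= 1")
    whole = AllOf(ast.steps) if len(ast.steps) > 1 else ast.steps[0]
    if _count_upper(whole) > limit:
        raise EnumerationOverflow(
            f"module {ast.module_id}: more than {limit} completion sets"
        )
    sets = sorted(set(_enum(whole)), key=_sort_key)
    kept: list = []
    for s in sets:
        if not any(k < s for k in kept):
            kept.append(s)
    return kept


# ---------------------------------------------------------------------------
# Evaluation (satisfiability + minimal-remainder recursion)
# ---------------------------------------------------------------------------

def _satisfied(expr: StepExpr, kos: frozenset) -> bool:
    if isinstance(expr, Atom):
        return expr.ko in kos
    if isinstance(expr, (Optional, Wildcard)):
        return True
    if isinstance(expr, AnyOf):
        return any(_satisfied(o, kos) for o in expr.options)
    if isinstance(expr, (AllOf, Complex)):
        return all(_satisfied(p, kos) for p in expr.parts)
    raise TypeError(expr)


def _remainder(expr: StepExpr, kos: frozenset) -> frozenset:
    """Smallest KO set to add so that ``expr`` is satisfied (per-branch greedy;
    exact when branch KO sets do not overlap)."""
    if isinstance(expr, Atom):
        return frozenset() if expr.ko in kos else frozenset((expr.ko,))
    if isinstance(expr, (Optional, Wildcard)):
        return frozenset()
    if isinstance(expr, AnyOf):
        return min((_remainder(o, kos) for o in expr.options), key=_sort_key)
    if isinstance(expr, (AllOf, Complex)):
        out: frozenset = frozenset()
        for p in expr.parts:
            out |= _remainder(p, kos)
        return out
    raise TypeError(expr)


def evaluate_module(ast: ModuleAST, kos, limit: int = 10_000) -> ModuleEvaluation:
    """Check a KO set against a module.

    A module is *complete* when every step is satisfied, equivalently when
    the KO set contains at least one completion set.  ``completeness`` is
    the fraction of top-level steps satisfied.  ``missing_kos`` is the
    smallest-cardinality remainder over all completion choices (ties broken
    on the lexicographically smallest sorted KO tuple); when the module
    has more completion sets than ``limit`` the remainder falls back to a
    per-branch recursion that is sound but not always globally minimal.
    """
    kos = frozenset(kos)
    total = len(ast.steps)
    satisfied = sum(1 for s in ast.steps if _satisfied(s, kos))
    complete = satisfied == total
    if complete:
        missing: frozenset = frozenset()
    else:
        try:
            sets = enumerate_completion_sets(ast, limit=limit)
            missing = min((s - kos for s in sets), key=_sort_key)
        except EnumerationOverflow:
            whole = AllOf(ast.steps) if len(ast.steps) > 1 else ast.steps[0]
            missing = _remainder(whole, kos)
    return ModuleEvaluation(
        module_id=ast.module_id,
        status="complete" if complete else "incomplete",
        steps_total=total,
        steps_satisfied=satisfied,
        completeness=satisfied / total,
        missing_kos=missing,
    )


def gap_fill(ast: ModuleAST, kos, limit: int = 10_000) -> frozenset:
    """KOs to add to ``kos`` so the module evaluates complete (empty iff
    already complete)."""
    return evaluate_module(ast, kos, limit=limit).missing_kos


def atom_kos(ast: ModuleAST, include_optional: bool = False) -> frozenset:
    """All KO identifiers appearing as atoms in the definition."""

    def walk(expr: StepExpr) -> Iterator[str]:
        if isinstance(expr, Atom):
            yield expr.ko
        elif isinstance(expr, Optional):
            if include_optional:
                yield from walk(expr.inner)
        elif isinstance(expr, AnyOf):
            for o in expr.options:
                yield from walk(o)
        elif isinstance(expr, (AllOf, Complex)):
            for p in expr.parts:
                yield from walk(p)

    out: set = set()
    for step in ast.steps:
        out.update(walk(step))
    return frozenset(out)
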