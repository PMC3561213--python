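"""Parser for the boolean rule language of the knowledge base.

Conditions (reusable named groups of codes) and indication/contraindication
rules share one expression grammar::

    expr   := term ("|" term)*          # disjunction, lowest precedence
    term   := factor ("&" factor)*      # conjunction binds tighter
    factor := atom | "(" expr ")"
    atom   := prefix "/" code           # i/ a/ u/ s/ c/

Rule lines add a polarity marker and optional demographic annotations::

    [+|-]substance = expr [@age:g1|g2] [@sex:g]

An absent marker means indication; ``-`` means contraindication.  The
original line text is preserved on every parsed definition so that rule
firings can be traced back to the exact authored sentence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from graphlib import CycleError, TopologicalSorter
from typing import Iterable, Iterator, Union

from .errors import ConditionCycleError, DslSyntaxError, UndefinedConditionError
from .terminology import CodeRef, Scheme, TerminologyError

#: default demographic vocabularies; both are configurable per parse
AGE_GROUPS = ("infant", "child", "adolescent", "adult", "elder")
SEX_GROUPS = ("male", "female")

_PREFIXES = {s.value: s for s in Scheme}


@dataclass(frozen=True)
class Atom:
    ref: CodeRef


@dataclass(frozen=True)
class And:
    children: tuple["Expr", ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("And needs >= 2 children")


@dataclass(frozen=True)
class Or:
    children: tuple["Expr", ...]

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("Or needs >= 2 children")


Expr = Union[Atom, And, Or]


class Polarity(Enum):
    INDICATION = "indication"
    CONTRAINDICATION = "contraindication"


@dataclass(frozen=True)
class ConditionDef:
    """A named defined class: ``name = expr`` over code and condition atoms."""

    name: str
    body: Expr
    source_text: str
    line: int = 0


@dataclass(frozen=True)
class RuleDef:
    """An authored indication or contraindication for one substance."""

    substance: CodeRef
    polarity: Polarity
    body: Expr
    age_groups: frozenset[str] = frozenset()  # empty = unrestricted
    sex_groups: frozenset[str] = frozenset()
    source_text: str = ""
    rule_id: str = ""


# ---------------------------------------------------------------------------
# lexing / parsing

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<atom>[iausc]/[^\s&|()@=]+)
  | (?P<op>[&|()])
    """,
    re.VERBOSE,
)


def _tokenize(text: str, line: int | None = None) -> Iterator[tuple[str, str, int]]:
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise DslSyntaxError(
                f"unexpected character {text[pos]!r}", line=line, column=pos + 1
            )
        if m.lastgroup != "ws":
            yield m.lastgroup, m.group(), pos + 1
        pos = m.end()


class _Parser:
    def __init__(self, text: str, line: int | None = None):
        self.text = text
        self.line = line
        self.tokens = list(_tokenize(text, line))
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, "", len(self.text) + 1)

    def next(self):
        tok = self.peek()
        self.i += 1
        return tok

    def error(self, msg, col):
        raise DslSyntaxError(msg, line=self.line, column=col)

    def parse(self) -> Expr:
        expr = self.parse_or()
        kind, val, col = self.peek()
        if kind is not None:
            self.error(f"unexpected {val!r}", col)
        return expr

    def parse_or(self) -> Expr:
        children = [self.parse_and()]
        while self.peek()[:2] == ("op", "|"):
            self.next()
            children.append(self.parse_and())
        return children[0] if len(children) == 1 else Or(tuple(children))

    def parse_and(self) -> Expr:
        children = [self.parse_factor()]
        while self.peek()[:2] == ("op", "&"):
            self.next()
            children.append(self.parse_factor())
        return children[0] if len(children) == 1 else And(tuple(children))

    def parse_factor(self) -> Expr:
        kind, val, col = self.next()
        if kind == "atom":
            prefix, code = val.split("/", 1)
            try:
                return Atom(CodeRef(_PREFIXES[prefix], code))
            except TerminologyError as exc:
                self.error(str(exc), col)
        if (kind, val) == ("op", "("):
            expr = self.parse_or()
            kind2, val2, col2 = self.next()
            if (kind2, val2) != ("op", ")"):
                self.error("expected ')'", col2)
            return expr
        self.error(f"expected atom or '(', got {val!r}" if kind else "unexpected end of input", col)


def parse_expression(text: str, line: int | None = None) -> Expr:
    """Parse a DSL boolean expression into an AST.

    ``&`` binds tighter than ``|``; parentheses group; whitespace is
    ignored; the Unicode minus in typeset ranges is accepted.
    """
    if not text.strip():
        raise DslSyntaxError("empty expression", line=line)
    return _Parser(text, line).parse()


def to_dsl(expr: Expr) -> str:
    """Serialize an AST back to surface syntax (structure-preserving)."""
    if isinstance(expr, Atom):
        return str(expr.ref)
    if isinstance(expr, And):
        parts = [
            f"({to_dsl(c)})" if isinstance(c, (And, Or)) else to_dsl(c)
            for c in expr.children
        ]
        return "&".join(parts)
    parts = [f"({to_dsl(c)})" if isinstance(c, Or) else to_dsl(c) for c in expr.children]
    return "|".join(parts)


def walk_atoms(expr: Expr) -> Iterator[CodeRef]:
    """Yield every atom reference, left to right, duplicates included."""
    if isinstance(expr, Atom):
        yield expr.ref
    else:
        for child in expr.children:
            yield from walk_atoms(child)


# ---------------------------------------------------------------------------
# file formats

def _content_lines(lines: Iterable[str]) -> Iterator[tuple[int, str]]:
    for no, raw in enumerate(lines, start=1):
        text = raw.split("#", 1)[0].strip()
        if text:
            yield no, text


def parse_condition_lines(lines: Iterable[str], filename=None) -> list[ConditionDef]:
    defs: list[ConditionDef] = []
    seen: dict[str, int] = {}
    for no, text in _content_lines(lines):
        if "=" not in text:
            raise DslSyntaxError("expected 'name=expr'", line=no, filename=filename)
        name, body_text = text.split("=", 1)
        name = name.strip().lower()
        if not re.match(r"^[a-z0-9][a-z0-9._-]*$", name):
            raise DslSyntaxError(f"invalid condition name {name!r}", line=no, filename=filename)
        if name in seen:
            raise DslSyntaxError(
                f"duplicate condition name {name!r} (first defined on line {seen[name]})",
                line=no,
                filename=filename,
            )
        seen[name] = no
        body = parse_expression(body_text, line=no)
        defs.append(ConditionDef(name=name, body=body, source_text=text, line=no))
    return defs


def parse_condition_file(path) -> list[ConditionDef]:
    """Parse a ``.cond`` file: one ``name=expr`` per line, ``#`` comments."""
    with open(path, encoding="utf-8") as fh:
        return parse_condition_lines(fh, filename=path)


_RULE_HEAD_RE = re.compile(r"^(?P<pol>[+-]?)\s*(?P<sub>[^\s=]+)\s*=\s*(?P<rest>.+)$")
_ANNOT_RE = re.compile(r"@(?P<kind>age|sex):(?P<groups>[A-Za-z|]+)")


def parse_rule_lines(
    lines: Iterable[str],
    filename=None,
    age_vocab: tuple[str, ...] = AGE_GROUPS,
    sex_vocab: tuple[str, ...] = SEX_GROUPS,
) -> list[RuleDef]:
    rules: list[RuleDef] = []
    for no, text in _content_lines(lines):
        m = _RULE_HEAD_RE.match(text)
        if m is None:
            raise DslSyntaxError("expected '[+|-]substance = expr'", line=no, filename=filename)
        polarity = Polarity.CONTRAINDICATION if m.group("pol") == "-" else Polarity.INDICATION
        try:
            substance = CodeRef(Scheme.SUBSTANCE, m.group("sub"))
        except TerminologyError as exc:
            raise DslSyntaxError(str(exc), line=no, filename=filename) from exc

        rest = m.group("rest")
        groups: dict[str, list[str]] = {"age": [], "sex": []}
        for am in _ANNOT_RE.finditer(rest):
            vocab = age_vocab if am.group("kind") == "age" else sex_vocab
            for g in am.group("groups").lower().split("|"):
                if g not in vocab:
                    raise DslSyntaxError(
                        f"unknown {am.group('kind')} group {g!r}", line=no, filename=filename
                    )
                groups[am.group("kind")].append(g)
        body_text = _ANNOT_RE.sub("", rest).strip()
        body = parse_expression(body_text, line=no)
        rules.append(
            RuleDef(
                substance=substance,
                polarity=polarity,
                body=body,
                age_groups=frozenset(groups["age"]),
                sex_groups=frozenset(groups["sex"]),
                source_text=text,
                rule_id=f"R{no:04d}-{substance.code}",
            )
        )
    return rules


def parse_rule_file(path, age_vocab=AGE_GROUPS, sex_vocab=SEX_GROUPS) -> list[RuleDef]:
    """Parse a ``.rules`` file of indication/contraindication definitions."""
    with open(path, encoding="utf-8") as fh:
        return parse_rule_lines(fh, filename=path, age_vocab=age_vocab, sex_vocab=sex_vocab)


def condition_references(expr: Expr) -> set[str]:
    return {ref.code for ref in walk_atoms(expr) if ref.scheme == Scheme.CONDITION}


def check_conditions_acyclic(defs: Iterable[ConditionDef]) -> list[str]:
    """Dependency-check condition definitions; return a topological order.

    Every ``c/`` atom must resolve to a defined condition, and the reference
    graph must be a DAG (a condition may appear as a premise of another, but
    not of itself, directly or transitively).  The returned order lists
    prerequisites before the conditions that use them; ties are broken
    alphabetically so the order is deterministic.
    """
    table = {d.name: d for d in defs}
    graph: dict[str, set[str]] = {}
    for d in table.values():
        refs = condition_references(d.body)
        for ref in refs:
            if ref not in table:
                raise UndefinedConditionError(ref, referenced_from=d.name)
        graph[d.name] = refs
    sorter = TopologicalSorter(graph)
    try:
        sorter.prepare()
    except CycleError as exc:
        raise ConditionCycleError(set(exc.args[1])) from exc
    order: list[str] = []
    while sorter.is_active():
        ready = sorted(sorter.get_ready())
        order.extend(ready)
        sorter.done(*ready)
    return order
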