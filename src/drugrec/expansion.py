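"""Compilation of authored rules into flat conjunctive production rules.

Production-rule engines without a disjunction operator need one rule per
disjunct, so each authored body is rewritten to disjunctive normal form and
crossed with the demographic constraints: a body with two DNF conjuncts
restricted to two age groups compiles to four flat rules.  For engines that
also lack class reasoning, named conditions are recursively inlined and
hierarchy knowledge is materialized into the premise list itself
(``populate_upper_levels``); the inference module's canonical semantics
instead closes *patient facts* upward, which coincides on leaf-coded data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .dsl import And, Atom, ConditionDef, Expr, Or, Polarity, RuleDef
from .errors import UndefinedConditionError
from .terminology import CodeRef, CodeSystems, Scheme, TerminologyError


@dataclass(frozen=True)
class FlatRule:
    """One conjunctive production rule: premises -> substance recommendation.

    ``age_group``/``sex_group`` hold a single group token or ``None`` for an
    unrestricted slot.  ``source_text`` carries the authored rule line the
    flat rule was compiled from, for firing traces.
    """

    substance: CodeRef
    polarity: Polarity
    premises: tuple[CodeRef, ...]
    age_group: Optional[str] = None
    sex_group: Optional[str] = None
    source_rule_id: str = ""
    source_text: str = ""
    flat_id: str = ""

    def __post_init__(self):
        if not self.premises:
            raise ValueError("flat rule needs >= 1 premise")
        if len(set(self.premises)) != len(self.premises):
            raise ValueError("duplicate premises in flat rule")


def to_dnf(body: Expr) -> list[tuple[CodeRef, ...]]:
    """Rewrite a body into a list of conjunctive premise sets.

    The disjunction of the returned conjuncts is logically equivalent to the
    body.  Distribution is left-to-right and stable, duplicate atoms within
    a conjunct are merged (first occurrence kept), and conjuncts equal as
    sets are deduplicated.  No further minimization (absorption etc.) is
    performed — a 13-way disjunction yields 13 conjuncts.
    """
    def rec(e: Expr) -> list[tuple[CodeRef, ...]]:
        if isinstance(e, Atom):
            return [(e.ref,)]
        if isinstance(e, Or):
            out: list[tuple[CodeRef, ...]] = []
            for child in e.children:
                out.extend(rec(child))
            return out
        # And: cartesian product of the children's conjunct lists
        prod: list[tuple[CodeRef, ...]] = [()]
        for child in e.children:
            prod = [p + c for p in prod for c in rec(child)]
        return prod

    conjuncts: list[tuple[CodeRef, ...]] = []
    seen: set[frozenset[CodeRef]] = set()
    for conj in rec(body):
        deduped = tuple(dict.fromkeys(conj))
        key = frozenset(deduped)
        if key not in seen:
            seen.add(key)
            conjuncts.append(deduped)
    return conjuncts


def expand_rule(rule: RuleDef) -> list[FlatRule]:
    """Cross the DNF conjuncts with the demographic constraints.

    Produces ``|DNF| * max(1, |age_groups|) * max(1, |sex_groups|)`` flat
    rules; an unrestricted demographic dimension contributes one
    unrestricted slot.  Group order within a dimension is alphabetical so
    output is deterministic.
    """
    conjuncts = to_dnf(rule.body)
    age_slots: list[Optional[str]] = sorted(rule.age_groups) or [None]
    sex_slots: list[Optional[str]] = sorted(rule.sex_groups) or [None]
    out: list[FlatRule] = []
    k = 0
    for conj in conjuncts:
        for age in age_slots:
            for sex in sex_slots:
                k += 1
                out.append(
                    FlatRule(
                        substance=rule.substance,
                        polarity=rule.polarity,
                        premises=conj,
                        age_group=age,
                        sex_group=sex,
                        source_rule_id=rule.rule_id,
                        source_text=rule.source_text,
                        flat_id=f"{rule.rule_id}#{k}",
                    )
                )
    return out


def materialize_expr(
    body: Expr, defs: Mapping[str, ConditionDef], _stack: tuple[str, ...] = ()
) -> Expr:
    """Inline every condition atom with its (recursively inlined) body."""
    if isinstance(body, Atom):
        if body.ref.scheme != Scheme.CONDITION:
            return body
        name = body.ref.code
        if name in _stack:
            # check_conditions_acyclic is the primary guard; this is defensive
            from .errors import ConditionCycleError

            raise ConditionCycleError(_stack[_stack.index(name):])
        if name not in defs:
            raise UndefinedConditionError(name)
        return materialize_expr(defs[name].body, defs, _stack + (name,))
    children = tuple(materialize_expr(c, defs, _stack) for c in body.children)
    return And(children) if isinstance(body, And) else Or(children)


def materialize_condition(name: str, defs: Mapping[str, ConditionDef]) -> Expr:
    """The condition's body with every nested condition inlined.

    The result contains only primitive (ICD-10/ATC/UNII/substance) atoms.
    """
    if name not in defs:
        raise UndefinedConditionError(name)
    return materialize_expr(defs[name].body, defs, (name,))


def materialize_rule(rule: RuleDef, defs: Mapping[str, ConditionDef]) -> RuleDef:
    """A copy of the rule with condition atoms inlined (same provenance)."""
    return RuleDef(
        substance=rule.substance,
        polarity=rule.polarity,
        body=materialize_expr(rule.body, defs),
        age_groups=rule.age_groups,
        sex_groups=rule.sex_groups,
        source_text=rule.source_text,
        rule_id=rule.rule_id,
    )


def populate_upper_levels(
    premises: Iterable[CodeRef], terminology: CodeSystems
) -> set[CodeRef]:
    """Premises plus every hierarchy ancestor of the ICD-10/ATC premises.

    Reproduces the premise lists of fully materialized production rules, in
    which class/subclass knowledge is written into the rule body because the
    target engine cannot reason over it.  Idempotent: ancestors of ancestors
    are already included.
    """
    out: set[CodeRef] = set()
    for ref in premises:
        out.add(ref)
        system = terminology.get(ref.scheme)
        if ref.scheme in (Scheme.ICD10, Scheme.ATC):
            if system is None or ref.code not in system:
                raise TerminologyError(
                    f"unknown {ref.scheme.name} code in premises: {ref.code!r}"
                )
            out.update(system.ancestors(ref, reflexive=False))
    return out


def arrow_notation(flat: FlatRule) -> str:
    """Debug rendering of a flat rule as a readable implication."""
    parts = [f"hasData({p})" for p in flat.premises]
    if flat.age_group:
        parts.append(f"hasAgeGroup({flat.age_group})")
    if flat.sex_group:
        parts.append(f"hasSexGroup({flat.sex_group})")
    verb = "canTake" if flat.polarity == Polarity.INDICATION else "cannotTake"
    return f"{', '.join(parts)} -> {verb}({flat.substance.code})"
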