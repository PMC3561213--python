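"""Forward-chaining evaluation of flat rules over patient facts.

The pipeline per patient: (1) close the patient's codes over substance<->ATC
equivalence and hierarchy ancestors so class-level premises match specific
data; (2) satisfy named conditions to a least fixpoint; (3) match flat
rules against the closed facts and the patient's demographic groups;
(4) derive conflicts (substances both indicated and contraindicated) and the
cleared list (indications minus conflicts — the actionable output).  The
report also carries per-datum sub-reports (each datum inserted alone) and a
trace of every fired rule with its authored source text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from .dsl import And, Atom, ConditionDef, Expr, Or, Polarity
from .expansion import FlatRule
from .errors import KnowledgeBaseError
from .terminology import CodeRef, CodeSystems, EquivalenceTable, Scheme, TerminologyError


@dataclass(frozen=True)
class PatientRecord:
    """Patient input: coded data plus demographic group membership."""

    id: str
    diseases: tuple[CodeRef, ...] = ()
    allergies: tuple[CodeRef, ...] = ()
    medications: tuple[CodeRef, ...] = ()
    age_group: Optional[str] = None
    sex_group: Optional[str] = None

    def data(self) -> tuple[CodeRef, ...]:
        return self.diseases + self.allergies + self.medications


_FIELD_DEFAULT_SCHEME = {
    "diseases": Scheme.ICD10,
    "allergies": Scheme.SUBSTANCE,
    "medications": Scheme.SUBSTANCE,
}


def parse_datum(token: str, fieldname: str) -> CodeRef:
    """Parse one patient datum token.

    A ``prefix/code`` token is explicit; a bare token takes the field's
    default scheme (diseases: ICD-10; allergies and medications: substance
    name).
    """
    token = token.strip()
    if "/" in token:
        prefix, code = token.split("/", 1)
        schemes = {s.value: s for s in Scheme}
        if prefix not in schemes or schemes[prefix] == Scheme.CONDITION:
            raise TerminologyError(f"bad datum prefix in {token!r}")
        return CodeRef(schemes[prefix], code)
    return CodeRef(_FIELD_DEFAULT_SCHEME[fieldname], token)


def patient_from_dict(doc: dict) -> PatientRecord:
    """Build a record from the JSON patient format."""
    def refs(fieldname):
        return tuple(parse_datum(t, fieldname) for t in doc.get(fieldname, []))

    return PatientRecord(
        id=str(doc.get("id", "patient")),
        diseases=refs("diseases"),
        allergies=refs("allergies"),
        medications=refs("medications"),
        age_group=doc.get("age_group"),
        sex_group=doc.get("sex_group"),
    )


def load_patient(path) -> PatientRecord:
    with open(path, encoding="utf-8") as fh:
        return patient_from_dict(json.load(fh))


@dataclass
class FactSet:
    """Closed patient facts: data codes, satisfied conditions, demographics."""

    data: set[CodeRef] = field(default_factory=set)
    satisfied_conditions: set[str] = field(default_factory=set)
    age_group: Optional[str] = None
    sex_group: Optional[str] = None


def close_facts(
    patient: PatientRecord,
    terminology: CodeSystems,
    eq: EquivalenceTable,
    close_medication_atc: bool = True,
) -> FactSet:
    """Reflexive-ancestor closure of the patient's codes.

    Each code is first resolved through the substance<->ATC equivalence
    table; every resulting code that lives in a hierarchical system (ICD-10,
    ATC) is closed upward so that a specific diagnosis or drug also counts
    as a member of every broader class.  ``close_medication_atc=False``
    turns off the ATC upward closure (drug-class premises then match only
    exact codes).  Codes of schemes for which a system is loaded must exist
    in it.
    """
    facts = FactSet(age_group=patient.age_group, sex_group=patient.sex_group)
    for code in patient.data():
        for ref in sorted(eq.resolve(code)):
            system = terminology.get(ref.scheme)
            if system is None:
                facts.data.add(ref)
                continue
            if ref.code not in system:
                raise TerminologyError(
                    f"patient {patient.id!r}: unknown {ref.scheme.name} code {ref.code!r}"
                )
            if ref.scheme == Scheme.ICD10 or (
                ref.scheme == Scheme.ATC and close_medication_atc
            ):
                facts.data.update(system.ancestors(ref, reflexive=True))
            else:
                facts.data.add(ref)
    return facts


def eval_expr(expr: Expr, data: set[CodeRef], satisfied: set[str]) -> bool:
    """Direct recursive evaluation of a body over closed facts."""
    if isinstance(expr, Atom):
        if expr.ref.scheme == Scheme.CONDITION:
            return expr.ref.code in satisfied
        return expr.ref in data
    if isinstance(expr, And):
        return all(eval_expr(c, data, satisfied) for c in expr.children)
    return any(eval_expr(c, data, satisfied) for c in expr.children)


def satisfy_conditions(facts: FactSet, defs: Iterable[ConditionDef]) -> FactSet:
    """Least fixpoint of condition evaluation over the closed data.

    A condition holds iff its body evaluates true over the data plus the
    conditions already satisfied.  Bodies are monotone (no negation), so
    iterating to quiescence yields the unique least fixpoint.
    """
    defs = list(defs)
    satisfied = set(facts.satisfied_conditions)
    changed = True
    while changed:
        changed = False
        for d in defs:
            if d.name not in satisfied and eval_expr(d.body, facts.data, satisfied):
                satisfied.add(d.name)
                changed = True
    return FactSet(
        data=set(facts.data),
        satisfied_conditions=satisfied,
        age_group=facts.age_group,
        sex_group=facts.sex_group,
    )


@dataclass(frozen=True)
class Trace:
    """One rule firing: which flat rule recommended what, and its source."""

    substance: str
    polarity: str
    flat_rule_id: str
    source_text: str


@dataclass
class RecommendationReport:
    """The four-list output plus firing traces and per-datum breakdown."""

    indications: tuple[str, ...] = ()
    contraindications: tuple[str, ...] = ()
    conflicts: tuple[str, ...] = ()
    cleared: tuple[str, ...] = ()
    traces: tuple[Trace, ...] = ()
    per_datum: dict[str, "RecommendationReport"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        doc = {
            "indications": list(self.indications),
            "contraindications": list(self.contraindications),
            "conflicts": list(self.conflicts),
            "cleared": list(self.cleared),
            "traces": [
                {
                    "substance": t.substance,
                    "polarity": t.polarity,
                    "flat_rule_id": t.flat_rule_id,
                    "source_text": t.source_text,
                }
                for t in self.traces
            ],
        }
        if self.per_datum:
            doc["per_datum"] = {k: v.to_dict() for k, v in sorted(self.per_datum.items())}
        return doc

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"


def _demographics_match(flat: FlatRule, facts: FactSet) -> bool:
    if flat.age_group is not None and flat.age_group != facts.age_group:
        return False
    if flat.sex_group is not None and flat.sex_group != facts.sex_group:
        return False
    return True


def match_rules(
    facts: FactSet, flat_rules: Iterable[FlatRule], mode: str = "semantic"
) -> RecommendationReport:
    """Fire every flat rule whose premises and demographics are satisfied.

    In ``semantic`` mode condition premises are checked against the
    satisfied-condition set; in ``materialized`` mode flat rules must be
    condition-free (conditions were inlined at compile time).  One trace is
    recorded per fired flat rule.
    """
    if mode not in ("semantic", "materialized"):
        raise ValueError(f"unknown mode {mode!r}")
    indications: set[str] = set()
    contraindications: set[str] = set()
    traces: list[Trace] = []
    for flat in flat_rules:
        if not _demographics_match(flat, facts):
            continue
        fired = True
        for premise in flat.premises:
            if premise.scheme == Scheme.CONDITION:
                if mode == "materialized":
                    raise KnowledgeBaseError(
                        f"condition premise {premise.code!r} in materialized mode "
                        f"(flat rule {flat.flat_id})"
                    )
                if premise.code not in facts.satisfied_conditions:
                    fired = False
                    break
            elif premise not in facts.data:
                fired = False
                break
        if not fired:
            continue
        target = indications if flat.polarity == Polarity.INDICATION else contraindications
        target.add(flat.substance.code)
        traces.append(
            Trace(
                substance=flat.substance.code,
                polarity=flat.polarity.value,
                flat_rule_id=flat.flat_id,
                source_text=flat.source_text,
            )
        )
    return RecommendationReport(
        indications=tuple(sorted(indications)),
        contraindications=tuple(sorted(contraindications)),
        traces=tuple(traces),
    )


def derive_conflicts(report: RecommendationReport) -> RecommendationReport:
    """Fill the conflict and cleared lists from the first two.

    conflicts = indications ∩ contraindications;
    cleared   = indications ∖ conflicts (the valid prescriptions).
    """
    ind = set(report.indications)
    contra = set(report.contraindications)
    conflicts = ind & contra
    return replace(
        report,
        conflicts=tuple(sorted(conflicts)),
        cleared=tuple(sorted(ind - conflicts)),
    )


def recommend(
    patient: PatientRecord,
    flat_rules: Iterable[FlatRule],
    terminology: CodeSystems,
    eq: EquivalenceTable,
    conditions: Iterable[ConditionDef] = (),
    mode: str = "semantic",
    close_medication_atc: bool = True,
) -> RecommendationReport:
    """Full evaluation: per-datum sub-reports, then the combined report.

    Each datum is first inserted alone (keeping the patient's demographics,
    which are intrinsic rather than list data) so the user can see which
    recommendation each datum is responsible for; the top-level lists come
    from inserting all data simultaneously.
    """
    flat_rules = list(flat_rules)
    conditions = list(conditions)

    def evaluate(p: PatientRecord) -> RecommendationReport:
        facts = close_facts(p, terminology, eq, close_medication_atc=close_medication_atc)
        if mode == "semantic":
            facts = satisfy_conditions(facts, conditions)
        return derive_conflicts(match_rules(facts, flat_rules, mode=mode))

    combined = evaluate(patient)
    per_datum: dict[str, RecommendationReport] = {}
    for fieldname in ("diseases", "allergies", "medications"):
        for ref in getattr(patient, fieldname):
            sub = PatientRecord(
                id=f"{patient.id}/{ref}",
                age_group=patient.age_group,
                sex_group=patient.sex_group,
                **{fieldname: (ref,)},
            )
            per_datum[str(ref)] = evaluate(sub)
    combined.per_datum = per_datum
    return combined
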