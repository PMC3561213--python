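"""Knowledge-base assembly, validation, and N-Triples export.

A :class:`KnowledgeBase` bundles the loaded code systems, the substance<->ATC
equivalence table, the condition definitions and the authored rules, caches
their flat expansions per mode, and validates the whole before inference:
acyclic conditions, resolvable atoms, known demographic tokens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import yaml

from . import dsl, expansion, inference
from .dsl import AGE_GROUPS, SEX_GROUPS, ConditionDef, RuleDef, walk_atoms
from .errors import ConditionCycleError, DrugrecError, KnowledgeBaseError, UndefinedConditionError
from .terminology import (
    CodeSystem,
    EquivalenceTable,
    Scheme,
    load_code_system,
    load_equivalence_table,
)


@dataclass(frozen=True)
class Diagnostic:
    severity: str  # "error" | "warning"
    message: str
    file: Optional[str] = None
    line: Optional[int] = None

    def __str__(self) -> str:
        where = f"{self.file or '<kb>'}" + (f":{self.line}" if self.line else "")
        return f"{self.severity}: {where}: {self.message}"


@dataclass
class KnowledgeBase:
    systems: dict[Scheme, CodeSystem] = field(default_factory=dict)
    equivalences: EquivalenceTable = field(default_factory=EquivalenceTable)
    conditions: list[ConditionDef] = field(default_factory=list)
    rules: list[RuleDef] = field(default_factory=list)
    age_vocab: tuple[str, ...] = AGE_GROUPS
    sex_vocab: tuple[str, ...] = SEX_GROUPS
    provenance: dict[str, str] = field(default_factory=dict)
    _flat_cache: dict[str, list[expansion.FlatRule]] = field(default_factory=dict, repr=False)

    @property
    def condition_table(self) -> dict[str, ConditionDef]:
        return {c.name: c for c in self.conditions}

    # -- loading ---------------------------------------------------------

    @classmethod
    def from_paths(
        cls,
        icd10=None,
        atc=None,
        unii=None,
        substances=None,
        equivalences=None,
        conditions=None,
        rules=None,
        age_vocab=AGE_GROUPS,
        sex_vocab=SEX_GROUPS,
    ) -> "KnowledgeBase":
        kb = cls(age_vocab=tuple(age_vocab), sex_vocab=tuple(sex_vocab))
        for scheme, path in (
            (Scheme.ICD10, icd10),
            (Scheme.ATC, atc),
            (Scheme.UNII, unii),
            (Scheme.SUBSTANCE, substances),
        ):
            if path is not None:
                kb.systems[scheme] = load_code_system(path, scheme)
                kb.provenance[scheme.name.lower()] = str(path)
        if equivalences is not None:
            kb.equivalences = load_equivalence_table(equivalences)
            kb.provenance["equivalences"] = str(equivalences)
        if conditions is not None:
            kb.conditions = dsl.parse_condition_file(conditions)
            kb.provenance["conditions"] = str(conditions)
        if rules is not None:
            kb.rules = dsl.parse_rule_file(rules, age_vocab=kb.age_vocab, sex_vocab=kb.sex_vocab)
            kb.provenance["rules"] = str(rules)
        return kb

    # -- validation ------------------------------------------------------

    def _check_atom(self, ref, diags: list[Diagnostic], context: str, file=None, line=None):
        if ref.scheme == Scheme.CONDITION:
            if ref.code not in self.condition_table:
                diags.append(
                    Diagnostic("error", f"{context}: undefined condition {ref.code!r}", file, line)
                )
            return
        system = self.systems.get(ref.scheme)
        if system is not None and ref.code not in system:
            diags.append(
                Diagnostic(
                    "error",
                    f"{context}: unknown {ref.scheme.name} code {ref.code!r}",
                    file,
                    line,
                )
            )

    def validate(self) -> list[Diagnostic]:
        """All diagnostics for the assembled KB; empty means clean."""
        diags: list[Diagnostic] = []
        cond_file = self.provenance.get("conditions")
        rule_file = self.provenance.get("rules")
        try:
            dsl.check_conditions_acyclic(self.conditions)
        except ConditionCycleError as exc:
            diags.append(Diagnostic("error", str(exc), cond_file))
        except UndefinedConditionError as exc:
            diags.append(Diagnostic("error", str(exc), cond_file))
        table = self.condition_table
        for cond in self.conditions:
            for ref in walk_atoms(cond.body):
                if not (ref.scheme == Scheme.CONDITION and ref.code not in table):
                    self._check_atom(ref, diags, f"condition {cond.name!r}", cond_file, cond.line)
        for rule in self.rules:
            for ref in walk_atoms(rule.body):
                self._check_atom(ref, diags, f"rule {rule.rule_id!r}", rule_file)
            sub_system = self.systems.get(Scheme.SUBSTANCE)
            if sub_system is not None and rule.substance.code not in sub_system:
                diags.append(
                    Diagnostic(
                        "error",
                        f"rule {rule.rule_id!r}: unknown substance {rule.substance.code!r}",
                        rule_file,
                    )
                )
        return diags

    def ensure_valid(self) -> None:
        diags = [d for d in self.validate() if d.severity == "error"]
        if diags:
            raise KnowledgeBaseError("; ".join(str(d) for d in diags))

    # -- compilation and inference ---------------------------------------

    def flat_rules(self, mode: str = "semantic") -> list[expansion.FlatRule]:
        """Flat conjunctive rules, cached per mode.

        ``semantic``: bodies are expanded as authored and condition premises
        are evaluated at run time against the satisfied-condition set.
        ``materialized``: conditions are recursively inlined first, so flat
        rules contain only primitive atoms.
        """
        if mode not in ("semantic", "materialized"):
            raise ValueError(f"unknown mode {mode!r}")
        if mode not in self._flat_cache:
            table = self.condition_table
            flats: list[expansion.FlatRule] = []
            for rule in self.rules:
                src = rule if mode == "semantic" else expansion.materialize_rule(rule, table)
                flats.extend(expansion.expand_rule(src))
            self._flat_cache[mode] = flats
        return self._flat_cache[mode]

    def recommend(
        self,
        patient: inference.PatientRecord,
        mode: str = "semantic",
        close_medication_atc: bool = True,
    ) -> inference.RecommendationReport:
        self.ensure_valid()
        return inference.recommend(
            patient,
            self.flat_rules(mode),
            self.systems,
            self.equivalences,
            conditions=self.conditions,
            mode=mode,
            close_medication_atc=close_medication_atc,
        )


# ---------------------------------------------------------------------------
# configuration file

def load_config(path) -> dict:
    """Read the declarative YAML config naming the KB input files.

    Relative paths are resolved against the config file's directory.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise DrugrecError(f"config {path} must be a mapping")
    base = path.parent

    def resolve(p):
        return str((base / p).resolve()) if p else None

    term = doc.get("terminology", {}) or {}
    return {
        "icd10": resolve(term.get("icd10")),
        "atc": resolve(term.get("atc")),
        "unii": resolve(term.get("unii")),
        "substances": resolve(term.get("substances")),
        "equivalences": resolve(doc.get("equivalences")),
        "conditions": resolve(doc.get("conditions")),
        "rules": resolve(doc.get("rules")),
        "mode": doc.get("mode", "semantic"),
        "close_medication_atc": bool(doc.get("close_medication_atc", True)),
        "age_groups": tuple(doc.get("age_groups", AGE_GROUPS)),
        "sex_groups": tuple(doc.get("sex_groups", SEX_GROUPS)),
    }


def kb_from_config(path) -> tuple[KnowledgeBase, dict]:
    cfg = load_config(path)
    kb = KnowledgeBase.from_paths(
        icd10=cfg["icd10"],
        atc=cfg["atc"],
        unii=cfg["unii"],
        substances=cfg["substances"],
        equivalences=cfg["equivalences"],
        conditions=cfg["conditions"],
        rules=cfg["rules"],
        age_vocab=cfg["age_groups"],
        sex_vocab=cfg["sex_groups"],
    )
    return kb, cfg


# ---------------------------------------------------------------------------
# N-Triples export

_NS = "urn:drugrec:"
_SUBCLASS = "<http://www.w3.org/2000/01/rdf-schema#subClassOf>"
_EQUIV = "<http://www.w3.org/2002/07/owl#equivalentClass>"
_SOURCE_TEXT = f"<{_NS}vocab:hasTextualRepresentation>"


def _uri(scheme: Scheme, code: str) -> str:
    from urllib.parse import quote

    return f"<{_NS}{scheme.name.lower()}:{quote(code, safe='.-')}>"


def _escape_literal(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"').replace("\n", "\\n")


def export_triples(kb: KnowledgeBase, out_path) -> int:
    """Write the KB as N-Triples; returns the number of triples.

    Convention (one line per fact, stable ordering): one rdfs:subClassOf
    triple per parent edge, one owl:equivalentClass triple per
    substance->ATC pair (single direction; the property is symmetric), and
    one triple per authored rule carrying its source text as a literal.
    Line count therefore equals parent edges + equivalence pairs + rules.
    """
    lines: list[str] = []
    for scheme in (Scheme.ICD10, Scheme.ATC, Scheme.UNII, Scheme.SUBSTANCE):
        system = kb.systems.get(scheme)
        if system is None:
            continue
        for code in sorted(system.parent):
            parent = system.parent[code]
            if parent is not None:
                lines.append(f"{_uri(scheme, code)} {_SUBCLASS} {_uri(scheme, parent)} .")
    for substance, atc in kb.equivalences.pairs():
        lines.append(f"{_uri(Scheme.SUBSTANCE, substance)} {_EQUIV} {_uri(Scheme.ATC, atc)} .")
    for rule in kb.rules:
        subject = f"<{_NS}rule:{rule.rule_id}>"
        lines.append(f'{subject} {_SOURCE_TEXT} "{_escape_literal(rule.source_text)}" .')
    with open(out_path, "w", encoding="utf-8") as fh:
        for line in lines:
            fh.write(line + "\n")
    return len(lines)
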