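"""Medical code systems as rooted class hierarchies.

Models ICD-10-like disease codes (chapter -> block-range -> category ->
subcategory), ATC-like drug codes (5 levels encoded in prefix lengths
1/3/4/5/7), flat ingredient identifiers (UNII-like), substance names and
condition names.  Provides ancestor closure, range-block membership and
substance<->ATC class equivalence — the pieces a rule engine needs so that a
class-level rule premise (e.g. the block N80-N98) matches a specific patient
diagnosis (e.g. N94.4).
"""

from __future__ import annotations

import csv
import re
import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

from .errors import HierarchyCycleError, TerminologyError


class Scheme(str, Enum):
    """The code families the engine understands.

    The single-letter value doubles as the atom prefix of the rule DSL
    (``i/E11``, ``a/N05CA``, ``u/...``, ``s/rimonabant``, ``c/...``).
    """

    ICD10 = "i"
    ATC = "a"
    UNII = "u"
    SUBSTANCE = "s"
    CONDITION = "c"


# ICD-10: letter + 2 digits, optional ".d+" subcategory, or a range block.
_ICD_SINGLE_RE = re.compile(r"^[A-Z]\d{2}(\.\d+)?$")
_ICD_RANGE_RE = re.compile(r"^[A-Z]\d{2}-[A-Z]\d{2}$")
# ATC levels: anatomical (1), therapeutic (3), pharmacological (4),
# chemical subgroup (5), chemical substance (7).
_ATC_RE = re.compile(r"^[A-Z](\d{2}([A-Z]([A-Z](\d{2})?)?)?)?$")
_TOKEN_RE = re.compile(r"^[A-Za-z0-9][A-Za-z0-9._-]*$")

#: prefix length sequence of the ATC hierarchy, finest level first
ATC_LEVEL_LENGTHS = (7, 5, 4, 3, 1)


def _normalize(scheme: Scheme, code: str) -> str:
    # The Unicode minus sometimes found in typeset range codes is folded to
    # the ASCII hyphen; substance names are case-insensitive INN tokens.
    code = unicodedata.normalize("NFKC", code.strip()).replace("−", "-").replace("–", "-")
    if scheme in (Scheme.SUBSTANCE, Scheme.CONDITION):
        code = code.lower()
    elif scheme in (Scheme.ICD10, Scheme.ATC):
        code = code.upper()
    return code


def _check_syntax(scheme: Scheme, code: str) -> None:
    if scheme == Scheme.ICD10:
        ok = bool(_ICD_SINGLE_RE.match(code) or _ICD_RANGE_RE.match(code))
    elif scheme == Scheme.ATC:
        ok = bool(_ATC_RE.match(code))
    else:
        ok = bool(_TOKEN_RE.match(code))
    if not ok:
        raise TerminologyError(f"malformed {scheme.name} code: {code!r}")


@dataclass(frozen=True, order=True)
class CodeRef:
    """A scheme-qualified terminology code, normalized and validated."""

    scheme: Scheme
    code: str

    def __post_init__(self):
        norm = _normalize(self.scheme, self.code)
        _check_syntax(self.scheme, norm)
        object.__setattr__(self, "code", norm)

    @property
    def is_range(self) -> bool:
        """True for an ICD-10 block such as ``N80-N98``."""
        return self.scheme == Scheme.ICD10 and "-" in self.code

    def __str__(self) -> str:  # the DSL surface form
        return f"{self.scheme.value}/{self.code}"


def _range_bounds(block_code: str) -> tuple[tuple[str, int], tuple[str, int]]:
    if not _ICD_RANGE_RE.match(block_code):
        raise TerminologyError(f"malformed ICD-10 range: {block_code!r}")
    lo, hi = block_code.split("-")
    return (lo[0], int(lo[1:3])), (hi[0], int(hi[1:3]))


def range_contains(block: CodeRef | str, category: CodeRef | str) -> bool:
    """Whether a 3-character ICD-10 category falls inside a range block.

    Comparison is lexicographic on (letter, 2-digit number), so blocks that
    span letters (e.g. A00-B99) are handled by the same rule.  Bounds are
    inclusive.
    """
    block_code = block.code if isinstance(block, CodeRef) else _normalize(Scheme.ICD10, block)
    cat_code = category.code if isinstance(category, CodeRef) else _normalize(Scheme.ICD10, category)
    lo, hi = _range_bounds(block_code)
    if not re.match(r"^[A-Z]\d{2}$", cat_code):
        raise TerminologyError(f"not an ICD-10 category: {cat_code!r}")
    key = (cat_code[0], int(cat_code[1:3]))
    return lo <= key <= hi


def _block_contains_block(outer: str, inner: str) -> bool:
    olo, ohi = _range_bounds(outer)
    ilo, ihi = _range_bounds(inner)
    return olo <= ilo and ihi <= ohi and (olo, ohi) != (ilo, ihi)


def _range_width(block_code: str) -> int:
    lo, hi = _range_bounds(block_code)
    return (ord(hi[0]) - ord(lo[0])) * 100 + hi[1] - lo[1]


@dataclass
class CodeSystem:
    """A rooted, acyclic hierarchy of codes of a single scheme.

    ``parent`` maps every node to its parent code, or ``None`` for roots.
    Flat vocabularies (substances, ingredient identifiers) are systems in
    which every node is a root.
    """

    scheme: Scheme
    parent: dict[str, Optional[str]] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.parent)

    def __contains__(self, code: CodeRef | str) -> bool:
        c = code.code if isinstance(code, CodeRef) else code
        return c in self.parent

    def roots(self) -> list[str]:
        return sorted(c for c, p in self.parent.items() if p is None)

    def add(self, code: str, parent: Optional[str] = None, label: Optional[str] = None) -> None:
        code = _normalize(self.scheme, code)
        _check_syntax(self.scheme, code)
        self.parent[code] = _normalize(self.scheme, parent) if parent else None
        if label:
            self.labels[code] = label

    def validate(self) -> None:
        """Raise unless every parent resolves and the relation is acyclic."""
        for code, par in self.parent.items():
            _check_syntax(self.scheme, code)
            if par is not None and par not in self.parent:
                raise TerminologyError(
                    f"dangling parent {par!r} of {code!r} in {self.scheme.name} system"
                )
        # cycle check: walk each chain marking visit epochs
        state: dict[str, int] = {}  # 0 = on current path, 1 = done
        for start in self.parent:
            path = []
            node: Optional[str] = start
            while node is not None and state.get(node) != 1:
                if state.get(node) == 0:
                    cycle_start = path.index(node)
                    raise HierarchyCycleError(path[cycle_start:] + [node])
                state[node] = 0
                path.append(node)
                node = self.parent[node]
            for n in path:
                state[n] = 1

    def ancestors(self, code: CodeRef | str, reflexive: bool = False) -> list[CodeRef]:
        """Transitive parent closure, ordered from the code upward.

        Includes the code itself first iff ``reflexive``.  Raises for a code
        not present in the system.
        """
        c = code.code if isinstance(code, CodeRef) else _normalize(self.scheme, code)
        if c not in self.parent:
            raise TerminologyError(f"unknown {self.scheme.name} code: {c!r}")
        out: list[CodeRef] = []
        if reflexive:
            out.append(CodeRef(self.scheme, c))
        seen = {c}
        node = self.parent[c]
        while node is not None:
            if node in seen:  # defensive; validate() normally rules this out
                raise HierarchyCycleError(list(seen) + [node])
            seen.add(node)
            out.append(CodeRef(self.scheme, node))
            node = self.parent[node]
        return out


def load_code_system(path, scheme: Scheme) -> CodeSystem:
    """Read a ``code<TAB>parent<TAB>label`` TSV (header row required).

    An empty parent field marks a root.  The returned system is validated:
    all parents resolve and the hierarchy is acyclic.
    """
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = list(reader)
    if rows and [c.strip().lower() for c in rows[0][:1]] == ["code"]:
        rows = rows[1:]
    return code_system_from_rows(
        ((r[0], r[1] if len(r) > 1 else "", r[2] if len(r) > 2 else "") for r in rows if r and r[0].strip()),
        scheme,
    )


def code_system_from_rows(rows: Iterable[tuple[str, str, str]], scheme: Scheme) -> CodeSystem:
    system = CodeSystem(scheme)
    for code, parent, label in rows:
        system.add(code, parent.strip() or None, label.strip() or None)
    system.validate()
    return system


def code_system_to_rows(system: CodeSystem) -> list[tuple[str, str, str]]:
    """Deterministic TSV-ready serialization (sorted by code)."""
    return [
        (code, system.parent[code] or "", system.labels.get(code, ""))
        for code in sorted(system.parent)
    ]


def infer_parents(codes: Iterable[CodeRef | str], scheme: Scheme) -> CodeSystem:
    """Build a hierarchy syntactically from a bag of codes.

    ATC: the parent is the prefix truncation along levels 7 -> 5 -> 4 -> 3
    -> 1; missing intermediate levels are created.  ICD-10: a subcategory
    ``Xnn.d`` hangs under its category ``Xnn``; a category hangs under the
    smallest *declared* range block that contains it; declared blocks nest
    by interval containment.  Codes with no enclosing ancestor become roots.
    """
    if scheme not in (Scheme.ICD10, Scheme.ATC):
        raise TerminologyError(f"cannot infer parents for scheme {scheme.name}")
    refs = [c if isinstance(c, CodeRef) else CodeRef(scheme, c) for c in codes]
    system = CodeSystem(scheme)

    if scheme == Scheme.ATC:
        todo = {r.code for r in refs}
        done: set[str] = set()
        while todo:
            code = todo.pop()
            if code in done:
                continue
            done.add(code)
            shorter = [n for n in ATC_LEVEL_LENGTHS if n < len(code)]
            parent = code[: shorter[0]] if shorter else None
            system.parent[code] = parent
            if parent is not None:
                todo.add(parent)
        system.validate()
        return system

    blocks = sorted({r.code for r in refs if "-" in r.code})
    singles = sorted({r.code for r in refs if "-" not in r.code})
    categories = {c for c in singles if "." not in c} | {c.split(".")[0] for c in singles if "." in c}

    def narrowest_block(candidates: list[str]) -> Optional[str]:
        return min(candidates, key=lambda b: (_range_width(b), b)) if candidates else None

    for block in blocks:
        enclosing = [b for b in blocks if _block_contains_block(b, block)]
        system.parent[block] = narrowest_block(enclosing)
    for cat in sorted(categories):
        containing = [b for b in blocks if range_contains(b, cat)]
        system.parent[cat] = narrowest_block(containing)
    for code in singles:
        if "." in code:
            system.parent[code] = code.split(".")[0]
    system.validate()
    return system


@dataclass
class EquivalenceTable:
    """One-to-one substance-name <-> ATC-code class equivalences.

    Mirrors the OWL modelling in which a substance class and its ATC class
    are declared equivalent (acetazolamide == S01EC01), so a fact stated in
    either vocabulary satisfies premises stated in the other.
    """

    substance_to_atc: dict[str, str] = field(default_factory=dict)
    atc_to_substance: dict[str, str] = field(default_factory=dict)

    def add(self, substance: str, atc_code: str) -> None:
        s = _normalize(Scheme.SUBSTANCE, substance)
        a = _normalize(Scheme.ATC, atc_code)
        _check_syntax(Scheme.SUBSTANCE, s)
        _check_syntax(Scheme.ATC, a)
        if self.substance_to_atc.get(s, a) != a or self.atc_to_substance.get(a, s) != s:
            raise TerminologyError(f"equivalence is not one-to-one at ({s!r}, {a!r})")
        self.substance_to_atc[s] = a
        self.atc_to_substance[a] = s

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(self.substance_to_atc.items())

    def resolve(self, code: CodeRef) -> set[CodeRef]:
        """``{code}`` plus its equivalent in the other scheme, if any."""
        out = {code}
        if code.scheme == Scheme.SUBSTANCE and code.code in self.substance_to_atc:
            out.add(CodeRef(Scheme.ATC, self.substance_to_atc[code.code]))
        elif code.scheme == Scheme.ATC and code.code in self.atc_to_substance:
            out.add(CodeRef(Scheme.SUBSTANCE, self.atc_to_substance[code.code]))
        return out


def resolve_equivalents(eq: EquivalenceTable, code: CodeRef) -> set[CodeRef]:
    """Functional alias for :meth:`EquivalenceTable.resolve`."""
    return eq.resolve(code)


def load_equivalence_table(path) -> EquivalenceTable:
    """Read a ``substance<TAB>atc_code`` TSV (header row required)."""
    table = EquivalenceTable()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = list(reader)
    if rows and rows[0][:1] and rows[0][0].strip().lower() == "substance":
        rows = rows[1:]
    for row in rows:
        if not row or not row[0].strip():
            continue
        if len(row) < 2:
            raise TerminologyError(f"equivalence row needs two columns: {row!r}")
        table.add(row[0], row[1])
    return table


CodeSystems = Mapping[Scheme, CodeSystem]


def ancestors(system: CodeSystem, code: CodeRef | str, reflexive: bool = False) -> list[CodeRef]:
    """Functional alias for :meth:`CodeSystem.ancestors`."""
    return system.ancestors(code, reflexive=reflexive)
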