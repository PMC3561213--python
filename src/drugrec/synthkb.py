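"""Fixture and random knowledge bases for testing every pipeline stage.

``demo_fixture`` ships a small hand-written knowledge base built around the
classic worked examples of rule compilation for drug recommendation engines:
an obesity-drug indication whose body needs DNF expansion and an age
restriction, a 13-way disjunctive anxiolytic indication, an NSAID rule that
exercises condition inlining and hierarchy materialization, a barbiturate
drug-group condition, and a nested post-operative-hemorrhage condition.

``generate`` produces seeded random knowledge bases (terminologies,
conditions, rules, patients) honouring all structural invariants, so
property tests can run at any size without external data.
"""

from __future__ import annotations

import json
import random
import string
from dataclasses import dataclass
from pathlib import Path

from . import dsl
from .dsl import AGE_GROUPS, SEX_GROUPS, And, Atom, Expr, Or, to_dsl
from .errors import DrugrecError
from .inference import PatientRecord, patient_from_dict
from .kb import KnowledgeBase
from .terminology import CodeRef, EquivalenceTable, Scheme, code_system_from_rows

# ---------------------------------------------------------------------------
# fixture file texts (synthetic stand-ins for licensed terminology content)

FIXTURE_ICD10_TSV = """\
code	parent	label
E00-E90		Endocrine, nutritional and metabolic diseases
E65-E68	E00-E90	Obesity and other hyperalimentation
E66	E65-E68	Obesity
E11	E00-E90	Type 2 diabetes mellitus
E78	E00-E90	Disorders of lipoprotein metabolism
M00-M99		Diseases of the musculoskeletal system
M05-M14	M00-M99	Inflammatory polyarthropathies
M15-M19	M00-M99	Arthrosis
M05	M05-M14	Rheumatoid arthritis with rheumatoid factor
M05.1	M05	Rheumatoid lung disease
N00-N99		Diseases of the genitourinary system
N80-N98	N00-N99	Noninflammatory disorders of female genital tract
N94	N80-N98	Pain and other conditions associated with female genital organs
N94.4	N94	Primary dysmenorrhoea
R58		Haemorrhage, not elsewhere classified
Z01		Other special examinations
Z01.2	Z01	Dental examination
F00-F99		Mental and behavioural disorders
F40-F48	F00-F99	Neurotic, stress-related and somatoform disorders
F40	F40-F48	Phobic anxiety disorders
F41	F40-F48	Other anxiety disorders
F42	F40-F48	Obsessive-compulsive disorder
F40.0	F40	Agoraphobia
F40.1	F40	Social phobias
F40.2	F40	Specific phobias
F41.0	F41	Panic disorder
F41.1	F41	Generalized anxiety disorder
F41.2	F41	Mixed anxiety and depressive disorder
F41.3	F41	Other mixed anxiety disorders
F41.8	F41	Other specified anxiety disorders
F41.9	F41	Anxiety disorder, unspecified
F42.0	F42	Predominantly obsessional thoughts
F42.1	F42	Predominantly compulsive acts
F42.2	F42	Mixed obsessional thoughts and acts
F42.9	F42	Obsessive-compulsive disorder, unspecified
"""

FIXTURE_ATC_TSV = """\
code	parent	label
N		Nervous system
N01	N	Anesthetics
N01A	N01	Anesthetics, general
N01AF	N01A	Barbiturates, plain
N01AG	N01A	Barbiturates in combination with other drugs
N03	N	Antiepileptics
N03A	N03	Antiepileptics
N03AA	N03A	Barbiturates and derivatives
N05	N	Psycholeptics
N05C	N05	Hypnotics and sedatives
N05CA	N05C	Barbiturates, plain
N05CB	N05C	Barbiturates, combinations
N05CX	N05C	Hypnotics and sedatives in combination
N06	N	Psychoanaleptics
N06D	N06	Anti-dementia drugs
N06DA	N06D	Anticholinesterases
N06DA02	N06DA	Donepezil
S		Sensory organs
S01	S	Ophthalmologicals
S01E	S01	Antiglaucoma preparations and miotics
S01EC	S01E	Carbonic anhydrase inhibitors
S01EC01	S01EC	Acetazolamide
"""

FIXTURE_UNII_TSV = """\
code	parent	label
BUSP001		Buspirone ingredient (synthetic identifier)
MEFE001		Mefenamic acid ingredient (synthetic identifier)
"""

FIXTURE_SUBSTANCES_TSV = """\
code	parent	label
rimonabant		Rimonabant
mefenamic		Mefenamic acid
buspirone		Buspirone
acetazolamide		Acetazolamide
donepezil		Donepezil
"""

FIXTURE_EQUIVALENCES_TSV = """\
substance	atc_code
acetazolamide	S01EC01
donepezil	N06DA02
"""

FIXTURE_CONDITIONS = """\
# Named groups of codes (defined classes), reusable across rules.
barbituratesdrugs=a/N01AF|a/N01AG|a/N03AA|a/N05CA|a/N05CB|a/N05CX
arthropathy-inflammatory-indication=i/M05-M14|i/M15-M19
hemorrhage-nos=i/R58
surgical-dental-procedures=i/Z01.2
hemorrhage-postoperative=c/hemorrhage-nos&c/surgical-dental-procedures
"""

FIXTURE_RULES = """\
# Indications (+ or bare) and contraindications (-).
+rimonabant=i/E65-E68&(i/E11|i/E78) @age:adult|elder
+mefenamic=c/arthropathy-inflammatory-indication|i/N94.4
-mefenamic=c/hemorrhage-postoperative
+buspirone=i/F40.0|i/F40.1|i/F40.2|i/F41.0|i/F41.1|i/F41.2|i/F41.3|i/F41.8|i/F41.9|i/F42.0|i/F42.1|i/F42.2|i/F42.9
-buspirone=u/BUSP001
-acetazolamide=c/barbituratesdrugs
"""

FIXTURE_PATIENTS = [
    {
        "id": "obese-diabetic-adult",
        "diseases": ["E66", "E11"],
        "age_group": "adult",
        "sex_group": "male",
    },
    {
        "id": "dysmenorrhoea",
        "diseases": ["N94.4"],
        "age_group": "adult",
        "sex_group": "female",
    },
    {
        "id": "arthritis-with-postop-bleeding",
        "diseases": ["M05.1", "R58", "Z01.2"],
        "age_group": "elder",
        "sex_group": "female",
    },
    {
        "id": "anxious-on-barbiturate",
        "diseases": ["F41.1"],
        "allergies": ["u/BUSP001"],
        "medications": ["a/N05CA"],
        "age_group": "adult",
        "sex_group": "male",
    },
]


def _system_from_tsv(text: str, scheme: Scheme):
    rows = [line.split("\t") for line in text.splitlines()[1:] if line.strip()]
    return code_system_from_rows(
        ((r[0], r[1] if len(r) > 1 else "", r[2] if len(r) > 2 else "") for r in rows), scheme
    )


def demo_fixture() -> tuple[KnowledgeBase, list[PatientRecord]]:
    """The built-in worked-example knowledge base and its demo patients."""
    kb = KnowledgeBase()
    kb.systems[Scheme.ICD10] = _system_from_tsv(FIXTURE_ICD10_TSV, Scheme.ICD10)
    kb.systems[Scheme.ATC] = _system_from_tsv(FIXTURE_ATC_TSV, Scheme.ATC)
    kb.systems[Scheme.UNII] = _system_from_tsv(FIXTURE_UNII_TSV, Scheme.UNII)
    kb.systems[Scheme.SUBSTANCE] = _system_from_tsv(FIXTURE_SUBSTANCES_TSV, Scheme.SUBSTANCE)
    eq = EquivalenceTable()
    for line in FIXTURE_EQUIVALENCES_TSV.splitlines()[1:]:
        if line.strip():
            substance, atc = line.split("\t")
            eq.add(substance, atc)
    kb.equivalences = eq
    kb.conditions = dsl.parse_condition_lines(FIXTURE_CONDITIONS.splitlines())
    kb.rules = dsl.parse_rule_lines(FIXTURE_RULES.splitlines())
    kb.provenance["source"] = "demo_fixture"
    patients = [patient_from_dict(doc) for doc in FIXTURE_PATIENTS]
    return kb, patients


def write_demo_files(out_dir) -> Path:
    """Write the fixture as the on-disk formats plus a config; returns the config path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "icd10.tsv": FIXTURE_ICD10_TSV,
        "atc.tsv": FIXTURE_ATC_TSV,
        "unii.tsv": FIXTURE_UNII_TSV,
        "substances.tsv": FIXTURE_SUBSTANCES_TSV,
        "equivalences.tsv": FIXTURE_EQUIVALENCES_TSV,
        "conditions.cond": FIXTURE_CONDITIONS,
        "rules.rules": FIXTURE_RULES,
    }
    for name, text in files.items():
        (out / name).write_text(text, encoding="utf-8")
    for doc in FIXTURE_PATIENTS:
        (out / f"patient-{doc['id']}.json").write_text(
            json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    config = (
        "terminology:\n"
        "  icd10: icd10.tsv\n"
        "  atc: atc.tsv\n"
        "  unii: unii.tsv\n"
        "  substances: substances.tsv\n"
        "equivalences: equivalences.tsv\n"
        "conditions: conditions.cond\n"
        "rules: rules.rules\n"
        "mode: semantic\n"
    )
    (out / "config.yaml").write_text(config, encoding="utf-8")
    return out / "config.yaml"


# ---------------------------------------------------------------------------
# random generator

@dataclass
class GeneratorSpec:
    """Knobs for the random knowledge-base generator.

    One integer seed drives every sub-generator; identical specs produce
    byte-identical serialized output.  Defaults give a small KB (a few
    hundred codes, 5 conditions, 20 rules) that exercises every code path —
    nested blocks, multi-level ATC, equivalences, nested conditions,
    demographic restrictions — in well under a second.
    """

    seed: int = 0
    n_icd_chapters: int = 3
    n_blocks_per_chapter: int = 3
    n_categories_per_block: int = 4
    n_subcategories_per_category: int = 2
    n_atc_roots: int = 2
    atc_branching: tuple[int, int, int, int] = (2, 2, 2, 2)
    n_unii: int = 5
    n_substances: int = 10
    equivalence_fraction: float = 0.5
    n_conditions: int = 5
    max_condition_depth: int = 2
    max_body_atoms: int = 4
    n_rules: int = 20
    contraindication_fraction: float = 0.3
    max_disjuncts: int = 3
    demographic_probability: float = 0.3
    n_patients: int = 5
    max_patient_data: int = 4

    def validate(self) -> None:
        numeric = {k: v for k, v in vars(self).items() if isinstance(v, (int, float))}
        for name, value in numeric.items():
            if value < 0:
                raise DrugrecError(f"generator spec: {name} must be >= 0")
        if self.n_conditions > 0 and (self.n_icd_chapters + self.n_atc_roots) == 0:
            raise DrugrecError("generator spec: conditions need primitive codes to reference")


def _gen_icd(rng: random.Random, spec: GeneratorSpec):
    rows = []  # (code, parent)
    leaves = []
    letters = string.ascii_uppercase[: spec.n_icd_chapters]
    for letter in letters:
        chapter = f"{letter}00-{letter}99"
        rows.append((chapter, ""))
        n_blocks = max(1, spec.n_blocks_per_chapter)
        width = 100 // n_blocks
        for b in range(n_blocks):
            lo, hi = b * width, min(99, (b + 1) * width - 1)
            block = f"{letter}{lo:02d}-{letter}{hi:02d}"
            if block == chapter:
                continue
            rows.append((block, chapter))
            numbers = rng.sample(range(lo, hi + 1), min(spec.n_categories_per_block, hi - lo + 1))
            for num in sorted(numbers):
                cat = f"{letter}{num:02d}"
                rows.append((cat, block))
                digits = rng.sample(range(10), min(spec.n_subcategories_per_category, 10))
                for d in sorted(digits):
                    sub = f"{cat}.{d}"
                    rows.append((sub, cat))
                    leaves.append(sub)
                if not digits:
                    leaves.append(cat)
    return rows, leaves


def _gen_atc(rng: random.Random, spec: GeneratorSpec):
    rows = []
    leaves = []
    letters = string.ascii_uppercase[: spec.n_atc_roots]
    b2, b3, b4, b5 = spec.atc_branching
    for root in letters:
        rows.append((root, ""))
        for i in range(b2):
            l2 = f"{root}{i + 1:02d}"
            rows.append((l2, root))
            for j in range(b3):
                l3 = l2 + string.ascii_uppercase[j]
                rows.append((l3, l2))
                for k in range(b4):
                    l4 = l3 + string.ascii_uppercase[k]
                    rows.append((l4, l3))
                    for m in range(b5):
                        l5 = f"{l4}{m + 1:02d}"
                        rows.append((l5, l4))
                        leaves.append(l5)
    return rows, leaves


def _rand_subset(rng: random.Random, vocab, max_size):
    size = rng.randint(1, max(1, min(max_size, len(vocab))))
    return sorted(rng.sample(list(vocab), size))


def _rand_conjunct(rng: random.Random, atoms: list[CodeRef], max_atoms: int) -> Expr:
    chosen = rng.sample(atoms, rng.randint(1, max(1, min(max_atoms, len(atoms)))))
    if len(chosen) == 1:
        return Atom(chosen[0])
    return And(tuple(Atom(c) for c in chosen))


def _rand_body(rng: random.Random, atoms: list[CodeRef], max_disjuncts: int, max_atoms: int) -> Expr:
    n = rng.randint(1, max(1, max_disjuncts))
    conjuncts = [_rand_conjunct(rng, atoms, max_atoms) for _ in range(n)]
    if len(conjuncts) == 1:
        return conjuncts[0]
    return Or(tuple(conjuncts))


def generate(spec: GeneratorSpec) -> tuple[KnowledgeBase, list[PatientRecord]]:
    """A reproducible random KB plus patients whose codes it can resolve."""
    spec.validate()
    rng = random.Random(spec.seed)

    icd_rows, icd_leaves = _gen_icd(rng, spec)
    atc_rows, atc_leaves = _gen_atc(rng, spec)
    unii_codes = [f"ING{i:04d}" for i in range(spec.n_unii)]
    substances = [f"drug{i:03d}" for i in range(spec.n_substances)]

    kb = KnowledgeBase()
    kb.systems[Scheme.ICD10] = code_system_from_rows(
        ((c, p, "") for c, p in icd_rows), Scheme.ICD10
    )
    kb.systems[Scheme.ATC] = code_system_from_rows(
        ((c, p, "") for c, p in atc_rows), Scheme.ATC
    )
    kb.systems[Scheme.UNII] = code_system_from_rows(
        ((c, "", "") for c in unii_codes), Scheme.UNII
    )
    kb.systems[Scheme.SUBSTANCE] = code_system_from_rows(
        ((s, "", "") for s in substances), Scheme.SUBSTANCE
    )

    n_equiv = int(spec.equivalence_fraction * spec.n_substances)
    if n_equiv > len(atc_leaves):
        raise DrugrecError("generator spec: not enough ATC leaf codes for equivalences")
    eq = EquivalenceTable()
    for substance, atc in zip(substances[:n_equiv], rng.sample(atc_leaves, n_equiv)):
        eq.add(substance, atc)
    kb.equivalences = eq

    primitive_atoms = (
        [CodeRef(Scheme.ICD10, c) for c in icd_leaves]
        + [CodeRef(Scheme.ATC, c) for c in atc_leaves]
        + [CodeRef(Scheme.UNII, c) for c in unii_codes]
    )
    if spec.n_conditions > 0 and not primitive_atoms:
        raise DrugrecError("generator spec: conditions requested but no primitive codes exist")

    # conditions: DAG by construction — a body may only reference earlier names
    cond_lines = []
    cond_names: list[str] = []
    for i in range(spec.n_conditions):
        name = f"cond{i:03d}"
        pool = list(primitive_atoms)
        depth_ok = [n for n in cond_names[-spec.max_condition_depth:]] if cond_names else []
        pool += [CodeRef(Scheme.CONDITION, n) for n in depth_ok]
        body = _rand_body(rng, pool, spec.max_disjuncts, spec.max_body_atoms)
        cond_lines.append(f"{name}={to_dsl(body)}")
        cond_names.append(name)
    kb.conditions = dsl.parse_condition_lines(cond_lines)

    rule_pool = primitive_atoms + [CodeRef(Scheme.CONDITION, n) for n in cond_names]
    rule_lines = []
    for _ in range(spec.n_rules):
        substance = rng.choice(substances)
        polarity = "-" if rng.random() < spec.contraindication_fraction else "+"
        body = _rand_body(rng, rule_pool, spec.max_disjuncts, spec.max_body_atoms)
        line = f"{polarity}{substance}={to_dsl(body)}"
        if rng.random() < spec.demographic_probability:
            line += " @age:" + "|".join(_rand_subset(rng, AGE_GROUPS, 2))
        if rng.random() < spec.demographic_probability:
            line += " @sex:" + "|".join(_rand_subset(rng, SEX_GROUPS, 1))
        rule_lines.append(line)
    kb.rules = dsl.parse_rule_lines(rule_lines)
    kb.provenance["source"] = f"generate(seed={spec.seed})"

    patients = []
    for i in range(spec.n_patients):
        diseases = tuple(
            CodeRef(Scheme.ICD10, c)
            for c in _rand_subset(rng, icd_leaves, spec.max_patient_data)
        ) if icd_leaves else ()
        medications = tuple(
            CodeRef(Scheme.ATC, c) for c in _rand_subset(rng, atc_leaves, 2)
        ) if atc_leaves and rng.random() < 0.7 else ()
        allergies = tuple(
            CodeRef(Scheme.UNII, c) for c in _rand_subset(rng, unii_codes, 1)
        ) if unii_codes and rng.random() < 0.3 else ()
        patients.append(
            PatientRecord(
                id=f"patient{i:03d}",
                diseases=diseases,
                allergies=allergies,
                medications=medications,
                age_group=rng.choice(AGE_GROUPS),
                sex_group=rng.choice(SEX_GROUPS),
            )
        )
    return kb, patients


def serialize_kb(kb: KnowledgeBase, patients: list[PatientRecord]) -> dict[str, str]:
    """Deterministic text serialization of a KB (filename -> content)."""
    from .terminology import code_system_to_rows

    files: dict[str, str] = {}
    names = {
        Scheme.ICD10: "icd10.tsv",
        Scheme.ATC: "atc.tsv",
        Scheme.UNII: "unii.tsv",
        Scheme.SUBSTANCE: "substances.tsv",
    }
    for scheme, filename in names.items():
        system = kb.systems.get(scheme)
        if system is None:
            continue
        lines = ["code\tparent\tlabel"]
        lines += ["\t".join(row) for row in code_system_to_rows(system)]
        files[filename] = "\n".join(lines) + "\n"
    eq_lines = ["substance\tatc_code"]
    eq_lines += [f"{s}\t{a}" for s, a in kb.equivalences.pairs()]
    files["equivalences.tsv"] = "\n".join(eq_lines) + "\n"
    files["conditions.cond"] = "".join(c.source_text + "\n" for c in kb.conditions)
    files["rules.rules"] = "".join(r.source_text + "\n" for r in kb.rules)
    patient_docs = []
    for p in patients:
        doc: dict = {"id": p.id}
        for fieldname in ("diseases", "allergies", "medications"):
            refs = getattr(p, fieldname)
            if refs:
                doc[fieldname] = [str(r) for r in refs]
        doc["age_group"] = p.age_group
        doc["sex_group"] = p.sex_group
        patient_docs.append(doc)
    files["patients.json"] = json.dumps(patient_docs, indent=2, sort_keys=True) + "\n"
    return files


def write_kb(kb: KnowledgeBase, patients: list[PatientRecord], out_dir) -> Path:
    """Write a generated KB as the on-disk formats plus a config file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = serialize_kb(kb, patients)
    for name, text in files.items():
        (out / name).write_text(text, encoding="utf-8")
    config_lines = ["terminology:"]
    for key, filename in (
        ("icd10", "icd10.tsv"),
        ("atc", "atc.tsv"),
        ("unii", "unii.tsv"),
        ("substances", "substances.tsv"),
    ):
        if filename in files:
            config_lines.append(f"  {key}: {filename}")
    config_lines += [
        "equivalences: equivalences.tsv",
        "conditions: conditions.cond",
        "rules: rules.rules",
        "mode: semantic",
    ]
    (out / "config.yaml").write_text("\n".join(config_lines) + "\n", encoding="utf-8")
    return out / "config.yaml"
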