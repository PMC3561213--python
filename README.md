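# drugrec

A rule-based drug indication/contraindication recommendation engine over
hierarchical medical terminologies, for people building or studying clinical
decision-support knowledge bases.

Drug–disease and drug–drug interaction knowledge is authored as boolean
rules over standard code systems — an ICD-10-like disease classification
(chapter → block range → category → subcategory), an ATC-like drug
classification (5 levels encoded in code-prefix lengths 1/3/4/5/7), flat
ingredient identifiers, and substance names tied to ATC codes by class
equivalence. `drugrec` parses that rule language, compiles it for a
production-rule engine, and evaluates patients against it.

## The model

A rule assigns a substance *s* a polarity (indication or contraindication)
and a boolean body over prefixed atoms, optionally restricted to demographic
groups:

```
+rimonabant = i/E65-E68 & (i/E11 | i/E78)   @age:adult|elder
```

`&` binds tighter than `|`; `i/`, `a/`, `u/`, `s/`, `c/` mark ICD-10, ATC,
ingredient, substance and *condition* atoms. Conditions are named, reusable
defined classes (`barbituratesdrugs = a/N01AF | a/N01AG | ...`) that may
reference each other acyclically.

Compilation rewrites each body to disjunctive normal form — conjunction-only
engines need one rule per disjunct — and crosses the conjuncts with the
demographic constraints, so the rule above becomes

|DNF| × |ages| × |sexes| = 2 × 2 × 1 = **4** flat rules:

```
hasData(i/E65-E68), hasData(i/E11), hasAgeGroup(adult) -> canTake(rimonabant)
hasData(i/E65-E68), hasData(i/E11), hasAgeGroup(elder) -> canTake(rimonabant)
hasData(i/E65-E68), hasData(i/E78), hasAgeGroup(adult) -> canTake(rimonabant)
hasData(i/E65-E68), hasData(i/E78), hasAgeGroup(elder) -> canTake(rimonabant)
```

Inference closes patient facts upward (a diagnosis of E66 *Obesity* is also
a member of the block E65-E68, a drug coded S01EC01 is also S01EC, S01E, …,
and substance↔ATC equivalents are interchangeable), satisfies conditions to
a least fixpoint, fires every flat rule whose premises and demographic slots
match, and reports four lists:

- **indications** — substances some indication rule recommends,
- **contraindications** — substances some contraindication rule forbids,
- **conflicts** = indications ∩ contraindications,
- **cleared** = indications ∖ conflicts — the actionable recommendations,

plus a trace of every fired rule carrying its original authored text, and a
per-datum breakdown (each disease/allergy/medication inserted alone).

Two compilation modes exist and provably agree: `semantic` evaluates
condition atoms at run time against the satisfied-condition set (the
description-logic reading, conditions as defined classes); `materialized`
recursively inlines condition definitions into rule bodies at compile time
(the business-rule-engine reading). `populate_upper_levels` additionally
writes hierarchy ancestors into premise lists, reproducing fully
materialized production-rule bodies.

## Worked example

```
$ drugrec gen --fixture --out-dir demo
$ drugrec validate -c demo/config.yaml
ok: 6 rules, 5 conditions
$ drugrec recommend -c demo/config.yaml -p demo/patient-obese-diabetic-adult.json
```

The patient has diseases E66 (obesity, a member of E65-E68) and E11 (type 2
diabetes) and age group `adult`, so exactly one of the four rimonabant flat
rules fires; no contraindication targets it, so it is cleared:

```json
{
  "cleared": ["rimonabant"],
  "conflicts": [],
  "contraindications": [],
  "indications": ["rimonabant"],
  ...
  "traces": [
    {
      "flat_rule_id": "R0002-rimonabant#1",
      "polarity": "indication",
      "source_text": "+rimonabant=i/E65-E68&(i/E11|i/E78) @age:adult|elder",
      "substance": "rimonabant"
    }
  ]
}
```

The fixture also demonstrates a conflict: the patient
`arthritis-with-postop-bleeding` is both indicated (inflammatory
arthropathy) and contraindicated (post-operative hemorrhage condition) for
mefenamic, so `conflicts = ["mefenamic"]` and `cleared = []`.

Other subcommands: `drugrec expand` (flat rules as TSV or implication
notation), `drugrec gen --seed N` (seeded random knowledge bases for
testing), `drugrec export-triples` (the KB as N-Triples: one subclass triple
per parent edge, one equivalence triple per substance↔ATC pair, one
source-text triple per rule).

## Library use

```python
import drugrec as dr

kb, patients = dr.demo_fixture()
report = kb.recommend(patients[0])
print(report.cleared)          # ('rimonabant',)
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes, from scratch, the flat-rule count obtained by parsing the
rimonabant indication definition and expanding it (DNF × age groups), after
running a seeded random-KB self-check of the full pipeline, and writes the
result as JSON.
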