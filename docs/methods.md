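# Methods

## Terminologies as class hierarchies

Each code system is a rooted forest: `parent` maps every node to at most one
parent; ancestor closure is the transitive walk upward. ICD-10-like codes
are `Xnn` categories, `Xnn.d` subcategories and `Xnn-Ymm` range blocks;
ATC-like codes encode their five levels in prefix lengths 1/3/4/5/7;
ingredient identifiers (UNII-like) and substance names are flat
vocabularies. Substance names normalize to lowercase; disease/drug codes to
uppercase; the Unicode minus occasionally found in typeset ranges is folded
to the ASCII hyphen at input.

Hierarchies are either loaded explicitly (TSV `code	parent	label`) or
inferred syntactically: ATC parents by prefix truncation along
7 → 5 → 4 → 3 → 1; an ICD subcategory under its category; a category under
the *narrowest declared* range block containing it; blocks nested by
interval containment. Range membership compares `(letter, number)` tuples
lexicographically with inclusive bounds, so blocks that span letters
(A00-B99) need no special case. When several declared blocks contain a
category, the narrowest wins (ties broken alphabetically) — this mirrors
how WHO-style chapters contain blocks contain categories.

Substance↔ATC equivalence is a one-to-one table per loaded KB; resolution
returns the code plus its counterpart and is symmetric by construction.
The ingredient scheme is treated as flat (no published sub-hierarchy to
model); nothing in the engine depends on that choice — give UNII rows
parents and ancestors close over them too.

## The rule language

```
expr   := term ("|" term)*        # | = union / or
term   := factor ("&" factor)*    # & = intersection / and, binds tighter
factor := atom | "(" expr ")"
atom   := ("i"|"a"|"u"|"s"|"c") "/" code
```

Conditions are `name=expr` lines; rules are `[+|-]substance=expr` with
optional `@age:g1|g2` / `@sex:g` annotations. The polarity marker and the
demographic annotations are this package's surface syntax: source systems
state that rules carry age/sex restrictions without fixing an encoding, so
the format was chosen minimal and backward-compatible — every bare
`substance=expr` line parses unchanged as an indication. Operator
precedence (`&` over `|`) is likewise fixed by convention here; authored
examples in the field always parenthesize mixed operators, so no published
rule changes meaning. Contraindication bodies use the same grammar as
indications (nothing suggests otherwise). The age vocabulary defaults to
infant/child/adolescent/adult/elder and is configurable, since published
examples only ever show `adult` and `elder`.

Parsing is a hand-written tokenizer + recursive-descent parser (the grammar
is five productions; a parser-generator dependency would outweigh it).
Errors carry line/column. Every definition keeps its verbatim source line,
which round-trips through the parser (`parse(to_dsl(e)) == e`, a property
test) and is attached to every rule firing for traceability.

Condition definitions may reference other conditions; the reference graph
must be a DAG. `check_conditions_acyclic` returns a deterministic
topological order (ready sets processed alphabetically) and names the cycle
members on failure.

## Compilation

`to_dnf` rewrites a body to a disjunction of conjunctions by left-to-right
distribution, stable and deterministic. Duplicate atoms within a conjunct
and set-equal duplicate conjuncts are merged; no further minimization
(absorption, Quine–McCluskey) is attempted, deliberately: the compilation
target is a naive conjunction-only rule engine, and a 13-way disjunction is
*meant* to become 13 rules. `expand_rule` crosses the conjuncts with each
age and sex group (alphabetical order; an unrestricted dimension contributes
one unrestricted slot), so the flat-rule count obeys
`|DNF| × max(1,|ages|) × max(1,|sexes|)` exactly — asserted as a property
over random rules.

Two treatments of condition atoms:

- **semantic mode** keeps `c/` atoms in flat-rule premises and checks them
  at match time against the satisfied-condition set — conditions behave as
  defined classes.
- **materialized mode** recursively inlines condition bodies before
  expansion, so flat rules contain only primitive atoms — what a
  business-rule engine without class reasoning requires.

`populate_upper_levels` additionally unions hierarchy ancestors into a
premise set. Note an asymmetry: fully materialized production rules write
ancestor codes into an *or*-list of the rule body, whereas this engine's
canonical semantics closes *patient facts* upward instead. The two coincide
when patient data are leaf codes (the normal case — patients are coded at
the finest level); fact closure is the description-logic-faithful reading
and avoids a coarse premise matching a patient coded only with a broader
class. `populate_upper_levels` is therefore provided as the replication of
the materialized surface form (and tested against the classic 7-code
example), while inference uses fact closure in both modes — which is also
why the two modes agree, a property asserted on 200 generated KB/patient
pairs.

## Inference

`close_facts` resolves each patient code through the equivalence table and
closes every ICD-10/ATC result upward reflexively (a specific diagnosis
entails its own code and all broader classes). Medication ATC closure can
be disabled (`close_medication_atc=False`) for engines that want drug-class
premises to match exact codes only; it defaults to on, the reading
consistent with class-membership semantics. Allergies carry no special
semantics: an allergy code enters the fact set like any datum and typically
triggers `u/`-premise contraindication rules.

`satisfy_conditions` iterates condition evaluation to quiescence. Bodies
are negation-free, hence monotone, so the fixpoint exists, is unique and
least; iteration order cannot change the result, only the number of sweeps
(bounded by the condition count). Equality with direct evaluation of the
inlined bodies is oracle-tested exhaustively on small instances.

A flat rule fires iff every premise is in the closed data (or the
satisfied-condition set) and each demographic slot is unrestricted or equals
the patient's group — exact token equality, no group hierarchy. Each firing
appends one trace `(substance, polarity, flat-rule id, source text)`,
deduplicated per flat rule by construction (each flat rule is tested once).

`derive_conflicts` computes `conflicts = indications ∩ contraindications`
and `cleared = indications ∖ conflicts`. `recommend` evaluates each datum
alone (keeping the patient's demographics, which are intrinsic rather than
list data) for the per-datum breakdown, then all data together for the
top-level lists. All rule premises are positive, so adding a datum never
shrinks the indication or contraindication sets (asserted as a property);
the cleared list may shrink, which is exactly the clinical point of the
conflict check. Reports serialize with sorted keys and sorted substance
lists, so identical inputs give byte-identical output.

## Synthetic knowledge bases

`demo_fixture()` is the stated worked-example world: the rimonabant
indication (AND-over-OR body, age-restricted to adult|elder), a 13-disjunct
buspirone indication, the mefenamic rule exercising condition inlining and
hierarchy materialization, the barbiturate ATC-union condition, the nested
post-operative-hemorrhage condition (with single-code stub definitions for
its two leaf sub-conditions, since their real definitions are not
published), the E/M/N/F ICD chains these need, the ATC chains for the
barbiturate groups, donepezil and acetazolamide, and the
acetazolamide≡S01EC01 equivalence. Labels and the two ingredient
identifiers are synthetic stand-ins — no licensed terminology content is
shipped, only the handful of codes the worked examples name.

`generate(GeneratorSpec)` produces seeded random KBs: ICD chapters split
into equal-width blocks with sampled categories/subcategories, a full ATC
tree from per-level branching counts, substances with a configurable
fraction mapped one-to-one onto ATC leaves, condition DAGs built so bodies
reference only earlier names (acyclic by construction), rules as bounded
disjunctions of bounded conjunctions with probabilistic demographic
restrictions, and patients drawn from codes the terminologies contain.
Defaults (3 chapters, 2 ATC roots, 10 substances, 5 conditions, 20 rules,
5 patients) are sized so a full generate-validate-recommend cycle runs in
milliseconds; one `random.Random(seed)` drives everything, and serialized
output is byte-identical per seed. The generator emulates structure, not
epidemiology: code shapes, hierarchy depth, rule arity and DAG nesting are
realistic, prevalence and clinical plausibility are not — so a green
property suite establishes logical correctness of parsing, compilation and
inference, not clinical validity of any recommendation.

## Numerical and edge-case choices

- Deterministic ordering everywhere user-visible: DNF left-to-right,
  demographic slots alphabetical, report lists sorted, triple export sorted
  by scheme then code; diffable golden files fall out for free.
- Empty inputs are legal: an empty code system, condition file, rule list or
  patient yields empty structures and empty report lists, never errors.
- Duplicate condition names, hierarchy cycles, dangling parents, malformed
  codes, unknown demographic tokens and undefined condition references are
  hard errors at load/validate time; inference refuses to run on a KB with
  error diagnostics.
- Unknown patient codes are errors when a system for their scheme is
  loaded; schemes without a loaded system pass through (the KB owner may
  intentionally run without, say, an ingredient registry).
- N-Triples export convention: one `rdfs:subClassOf` triple per parent
  edge, one `owl:equivalentClass` triple per substance→ATC pair (single
  direction; the property is symmetric), one source-text literal triple per
  rule — so the line count is exactly `edges + pairs + rules`.

## Limitations

- No negation, cardinality or severity operators in the rule language, and
  no interaction prioritization — out of scope by design.
- No truth maintenance: facts are inserted, never retracted; re-evaluate
  from scratch per patient (cheap at desk scale).
- Rule matching is a linear scan over flat rules per patient; no Rete-style
  indexing. Fine to ~10^4 flat rules; beyond that, premise indexing would
  be the first optimization.
- Demographic matching is exact-token; age-group hierarchies (e.g. elder ⊂
  adult) are not modelled.
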