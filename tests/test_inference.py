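"""Forward chaining: fact closure, condition fixpoint, matching, reports."""

import random

import pytest

from drugrec.expansion import expand_rule
from drugrec.inference import (
    FactSet,
    PatientRecord,
    RecommendationReport,
    close_facts,
    derive_conflicts,
    eval_expr,
    match_rules,
    parse_datum,
    patient_from_dict,
    recommend,
    satisfy_conditions,
)
from drugrec.synthkb import GeneratorSpec, generate
from drugrec.terminology import CodeRef, Scheme, TerminologyError


def icd(code):
    return CodeRef(Scheme.ICD10, code)


class TestCloseFacts:
    def test_disease_closes_up_the_hierarchy(self, fixture_kb):
        patient = PatientRecord(id="p", diseases=(icd("N94.4"),))
        facts = close_facts(patient, fixture_kb.systems, fixture_kb.equivalences)
        assert {icd(c) for c in ("N94.4", "N94", "N80-N98", "N00-N99")} <= facts.data

    def test_empty_patient(self, fixture_kb):
        facts = close_facts(PatientRecord(id="p"), fixture_kb.systems, fixture_kb.equivalences)
        assert facts.data == set()

    def test_substance_medication_resolves_and_closes_atc(self, fixture_kb):
        patient = PatientRecord(
            id="p", medications=(CodeRef(Scheme.SUBSTANCE, "acetazolamide"),)
        )
        facts = close_facts(patient, fixture_kb.systems, fixture_kb.equivalences)
        expected = {CodeRef(Scheme.SUBSTANCE, "acetazolamide")} | {
            CodeRef(Scheme.ATC, c) for c in ("S01EC01", "S01EC", "S01E", "S01", "S")
        }
        assert expected <= facts.data

    def test_atc_closure_flag_off(self, fixture_kb):
        patient = PatientRecord(id="p", medications=(CodeRef(Scheme.ATC, "N05CA"),))
        facts = close_facts(
            patient, fixture_kb.systems, fixture_kb.equivalences, close_medication_atc=False
        )
        assert CodeRef(Scheme.ATC, "N05CA") in facts.data
        assert CodeRef(Scheme.ATC, "N05C") not in facts.data

    def test_unknown_code_raises(self, fixture_kb):
        patient = PatientRecord(id="p", diseases=(icd("Q99"),))
        with pytest.raises(TerminologyError, match="unknown"):
            close_facts(patient, fixture_kb.systems, fixture_kb.equivalences)

    def test_demographics_carried(self, fixture_kb):
        patient = PatientRecord(id="p", age_group="adult", sex_group="female")
        facts = close_facts(patient, fixture_kb.systems, fixture_kb.equivalences)
        assert (facts.age_group, facts.sex_group) == ("adult", "female")


class TestSatisfyConditions:
    def test_union_condition_fires_on_single_member(self, fixture_kb):
        facts = FactSet(data={CodeRef(Scheme.ATC, "N05CA")})
        out = satisfy_conditions(facts, fixture_kb.conditions)
        assert "barbituratesdrugs" in out.satisfied_conditions

    def test_conjunction_needs_both_subconditions(self, fixture_kb):
        only_bleeding = satisfy_conditions(
            FactSet(data={icd("R58")}), fixture_kb.conditions
        )
        assert "hemorrhage-nos" in only_bleeding.satisfied_conditions
        assert "hemorrhage-postoperative" not in only_bleeding.satisfied_conditions
        both = satisfy_conditions(
            FactSet(data={icd("R58"), icd("Z01.2")}), fixture_kb.conditions
        )
        assert "hemorrhage-postoperative" in both.satisfied_conditions

    def test_fixpoint_matches_materialized_oracle(self):
        """The fixpoint agrees with direct evaluation of inlined bodies on
        random fact sets of a generated KB."""
        from drugrec.expansion import materialize_condition

        kb, _ = generate(GeneratorSpec(seed=13, n_conditions=8, n_rules=0, n_patients=0))
        table = kb.condition_table
        atoms = sorted(
            {ref for c in kb.conditions for ref in _primitive_atoms(c.body, table)}
        )
        rng = random.Random(4)
        for _ in range(30):
            data = set(rng.sample(atoms, rng.randint(0, min(6, len(atoms)))))
            out = satisfy_conditions(FactSet(data=data), kb.conditions)
            for cond in kb.conditions:
                direct = eval_expr(materialize_condition(cond.name, table), data, set())
                assert (cond.name in out.satisfied_conditions) == direct


def _primitive_atoms(body, table, seen=None):
    from drugrec.dsl import walk_atoms

    seen = seen if seen is not None else set()
    out = set()
    for ref in walk_atoms(body):
        if ref.scheme == Scheme.CONDITION:
            if ref.code not in seen:
                seen.add(ref.code)
                out |= _primitive_atoms(table[ref.code].body, table, seen)
        else:
            out.add(ref)
    return out


class TestMatchRules:
    def _rimonabant_flats(self, fixture_kb):
        rule = next(r for r in fixture_kb.rules if r.substance.code == "rimonabant")
        return expand_rule(rule)

    def test_adult_with_obesity_and_diabetes(self, fixture_kb):
        facts = FactSet(
            data={icd("E66"), icd("E65-E68"), icd("E11")}, age_group="adult"
        )
        report = match_rules(facts, self._rimonabant_flats(fixture_kb))
        assert report.indications == ("rimonabant",)
        assert len(report.traces) == 1  # only rule variant 1 fires
        assert "rimonabant" in report.traces[0].source_text

    def test_child_is_excluded_by_age_slot(self, fixture_kb):
        facts = FactSet(
            data={icd("E66"), icd("E65-E68"), icd("E11")}, age_group="child"
        )
        report = match_rules(facts, self._rimonabant_flats(fixture_kb))
        assert report.indications == ()

    def test_trace_records_flat_rule_and_source(self, fixture_kb):
        facts = FactSet(
            data={icd("E65-E68"), icd("E11"), icd("E78")}, age_group="elder"
        )
        report = match_rules(facts, self._rimonabant_flats(fixture_kb))
        # both disjuncts fire for the elder slot -> two distinct traces
        assert len(report.traces) == 2
        assert len({t.flat_rule_id for t in report.traces}) == 2


class TestDeriveConflicts:
    def test_overlap(self):
        report = derive_conflicts(
            RecommendationReport(indications=("x", "y"), contraindications=("y", "z"))
        )
        assert report.conflicts == ("y",)
        assert report.cleared == ("x",)

    def test_disjoint(self):
        report = derive_conflicts(
            RecommendationReport(indications=("a", "b"), contraindications=("c",))
        )
        assert report.conflicts == ()
        assert report.cleared == ("a", "b")

    def test_set_identities_on_random_lists(self):
        rng = random.Random(8)
        pool = [f"s{i}" for i in range(12)]
        for _ in range(100):
            ind = tuple(sorted(rng.sample(pool, rng.randint(0, 8))))
            contra = tuple(sorted(rng.sample(pool, rng.randint(0, 8))))
            r = derive_conflicts(
                RecommendationReport(indications=ind, contraindications=contra)
            )
            assert set(r.cleared) | set(r.conflicts) == set(ind)
            assert not set(r.cleared) & set(contra)


class TestRecommend:
    def test_single_datum_equals_combined(self, fixture_kb):
        patient = PatientRecord(id="p", diseases=(icd("N94.4"),), age_group="adult")
        report = fixture_kb.recommend(patient)
        assert list(report.per_datum) == ["i/N94.4"]
        sub = report.per_datum["i/N94.4"]
        assert sub.indications == report.indications
        assert sub.cleared == report.cleared

    def test_combined_contains_each_per_datum(self, fixture_kb, fixture_patients):
        for patient in fixture_patients.values():
            report = fixture_kb.recommend(patient)
            for sub in report.per_datum.values():
                assert set(sub.indications) <= set(report.indications)
                assert set(sub.contraindications) <= set(report.contraindications)

    def test_rimonabant_cleared_for_fixture_patient(self, fixture_kb, fixture_patients):
        report = fixture_kb.recommend(fixture_patients["obese-diabetic-adult"])
        assert "rimonabant" in report.cleared

    def test_conflicted_substance_excluded_from_cleared(self, fixture_kb, fixture_patients):
        report = fixture_kb.recommend(fixture_patients["arthritis-with-postop-bleeding"])
        assert report.conflicts == ("mefenamic",)
        assert report.cleared == ()

    def test_allergy_triggers_contraindication(self, fixture_kb, fixture_patients):
        report = fixture_kb.recommend(fixture_patients["anxious-on-barbiturate"])
        assert "buspirone" in report.contraindications  # u/BUSP001 allergy
        assert "acetazolamide" in report.contraindications  # barbiturate co-medication
        assert report.conflicts == ("buspirone",)

    def test_monotone_in_added_data(self, fixture_kb):
        base = PatientRecord(id="p", diseases=(icd("N94.4"),), age_group="elder")
        more = PatientRecord(
            id="p", diseases=(icd("N94.4"), icd("R58"), icd("Z01.2")), age_group="elder"
        )
        r1, r2 = fixture_kb.recommend(base), fixture_kb.recommend(more)
        assert set(r1.indications) <= set(r2.indications)
        assert set(r1.contraindications) <= set(r2.contraindications)

    def test_report_serialization_deterministic(self, fixture_kb, fixture_patients):
        patient = fixture_patients["anxious-on-barbiturate"]
        assert fixture_kb.recommend(patient).to_json() == fixture_kb.recommend(patient).to_json()


class TestPatientIo:
    def test_bare_tokens_take_field_scheme(self):
        patient = patient_from_dict(
            {"id": "p", "diseases": ["E66"], "medications": ["acetazolamide"]}
        )
        assert patient.diseases == (icd("E66"),)
        assert patient.medications == (CodeRef(Scheme.SUBSTANCE, "acetazolamide"),)

    def test_prefixed_tokens_override(self):
        assert parse_datum("a/N05CA", "medications") == CodeRef(Scheme.ATC, "N05CA")
        assert parse_datum("u/ING0001", "allergies") == CodeRef(Scheme.UNII, "ING0001")

    def test_condition_prefix_rejected_as_datum(self):
        with pytest.raises(TerminologyError):
            parse_datum("c/barbituratesdrugs", "diseases")
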