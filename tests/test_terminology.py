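"""Code systems: hierarchy loading, ancestor closure, ranges, equivalences."""

import random

import pytest
from hypothesis import given, strategies as st

from drugrec.errors import HierarchyCycleError, TerminologyError
from drugrec.terminology import (
    CodeRef,
    EquivalenceTable,
    Scheme,
    code_system_from_rows,
    infer_parents,
    load_code_system,
    range_contains,
    resolve_equivalents,
)


def tsv(path, rows):
    path.write_text("code\tparent\tlabel\n" + "".join(f"{c}\t{p}\t{l}\n" for c, p, l in rows))
    return path


class TestCodeRef:
    @pytest.mark.parametrize(
        "scheme,code,norm",
        [
            (Scheme.ICD10, "E65−E68", "E65-E68"),  # Unicode minus folded
            (Scheme.ICD10, "n94.4", "N94.4"),
            (Scheme.ATC, "n06da02", "N06DA02"),
            (Scheme.SUBSTANCE, "Rimonabant", "rimonabant"),
        ],
    )
    def test_normalization(self, scheme, code, norm):
        assert CodeRef(scheme, code).code == norm

    @pytest.mark.parametrize(
        "scheme,code",
        [
            (Scheme.ICD10, "E6"),
            (Scheme.ICD10, "E65-E"),
            (Scheme.ATC, "N06DA0"),  # length 6 is not an ATC level
            (Scheme.ATC, "N0"),
            (Scheme.SUBSTANCE, ""),
        ],
    )
    def test_malformed_codes_rejected(self, scheme, code):
        with pytest.raises(TerminologyError):
            CodeRef(scheme, code)


class TestLoadCodeSystem:
    def test_four_node_chain(self, tmp_path):
        path = tsv(
            tmp_path / "icd.tsv",
            [("N94.4", "N94", ""), ("N94", "N80-N98", ""), ("N80-N98", "N00-N99", ""), ("N00-N99", "", "")],
        )
        system = load_code_system(path, Scheme.ICD10)
        assert system.nodes == {"N94.4", "N94", "N80-N98", "N00-N99"}
        assert system.roots() == ["N00-N99"]

    def test_empty_file(self, tmp_path):
        path = (tmp_path / "empty.tsv")
        path.write_text("code\tparent\tlabel\n")
        assert load_code_system(path, Scheme.ICD10).nodes == set()

    def test_two_node_cycle_detected(self, tmp_path):
        path = tsv(tmp_path / "cyc.tsv", [("A01", "B01", ""), ("B01", "A01", "")])
        with pytest.raises(HierarchyCycleError):
            load_code_system(path, Scheme.ICD10)

    def test_dangling_parent_detected(self, tmp_path):
        path = tsv(tmp_path / "dangle.tsv", [("A01", "A00-A09", "")])
        with pytest.raises(TerminologyError, match="dangling"):
            load_code_system(path, Scheme.ICD10)


class TestInferParents:
    def test_atc_prefix_chain(self):
        system = infer_parents(["N06DA02"], Scheme.ATC)
        assert system.ancestors("N06DA02", reflexive=True) == [
            CodeRef(Scheme.ATC, c) for c in ("N06DA02", "N06DA", "N06D", "N06", "N")
        ]

    def test_category_without_declared_block_is_root(self):
        system = infer_parents(["E11"], Scheme.ICD10)
        assert system.parent["E11"] is None

    def test_subcategory_under_nested_blocks(self):
        system = infer_parents(["M05.1", "M05-M14", "M00-M99"], Scheme.ICD10)
        chain = [r.code for r in system.ancestors("M05.1", reflexive=True)]
        assert chain == ["M05.1", "M05", "M05-M14", "M00-M99"]

    def test_narrowest_block_agrees_with_brute_force(self):
        """The assigned parent block must be the narrowest containing one."""
        rng = random.Random(5)
        blocks = ["A00-A99", "A00-A49", "A10-A29", "A50-A99", "B00-B49"]
        cats = [f"{letter}{n:02d}" for letter in "AB" for n in rng.sample(range(100), 12)]
        system = infer_parents(blocks + cats, Scheme.ICD10)
        for cat in cats:
            containing = [b for b in blocks if range_contains(b, cat)]
            if not containing:
                assert system.parent[cat] is None
            else:
                widths = {
                    b: (ord(b[4]) - ord(b[0])) * 100 + int(b[5:7]) - int(b[1:3])
                    for b in containing
                }
                assert system.parent[cat] == min(containing, key=lambda b: (widths[b], b))

    def test_output_passes_validation(self):
        # validate() runs inside infer_parents; re-validate explicitly
        system = infer_parents(["N05CA", "N01AF", "S01EC01"], Scheme.ATC)
        system.validate()
        assert "N05C" in system and "S" in system


class TestAncestors:
    def test_reflexive_chain(self, fixture_kb):
        icd = fixture_kb.systems[Scheme.ICD10]
        assert [r.code for r in icd.ancestors("N94.4", reflexive=True)] == [
            "N94.4",
            "N94",
            "N80-N98",
            "N00-N99",
        ]

    def test_root_reflexive_is_singleton(self, fixture_kb):
        icd = fixture_kb.systems[Scheme.ICD10]
        assert [r.code for r in icd.ancestors("N00-N99", reflexive=True)] == ["N00-N99"]

    def test_unknown_code_raises(self, fixture_kb):
        with pytest.raises(TerminologyError, match="unknown"):
            fixture_kb.systems[Scheme.ICD10].ancestors("Q99")

    def test_agrees_with_single_step_lookup(self):
        """Closure equals iterating the parent map to its fixpoint."""
        rng = random.Random(11)
        codes = [f"A{n:02d}" for n in range(30)]
        rows = []
        for i, code in enumerate(codes):
            parent = rng.choice(codes[:i]) if i and rng.random() < 0.8 else ""
            rows.append((code, parent, ""))
        system = code_system_from_rows(rows, Scheme.ICD10)
        for code in codes:
            expected = []
            node = system.parent[code]
            while node is not None:
                expected.append(node)
                node = system.parent[node]
            assert [r.code for r in system.ancestors(code)] == expected

    def test_closure_is_idempotent(self, fixture_kb):
        icd = fixture_kb.systems[Scheme.ICD10]
        closed = set()
        for code in icd.nodes:
            closed.update(r.code for r in icd.ancestors(code, reflexive=True))
        reclosed = set()
        for code in closed:
            reclosed.update(r.code for r in icd.ancestors(code, reflexive=True))
        assert reclosed == closed


class TestRangeContains:
    @pytest.mark.parametrize(
        "block,cat,expected",
        [
            ("N80-N98", "N94", True),
            ("E65-E68", "E65", True),  # boundary inclusive
            ("E65-E68", "E68", True),
            ("M00-M99", "N20", False),
            ("A00-B99", "B50", True),  # letter-crossing block
        ],
    )
    def test_examples(self, block, cat, expected):
        assert range_contains(block, cat) is expected

    def test_malformed_range_raises(self):
        with pytest.raises(TerminologyError):
            range_contains("N80N98", "N94")

    @given(
        lo=st.integers(0, 99),
        width=st.integers(0, 60),
        letter=st.sampled_from("AEN"),
        n=st.integers(0, 99),
    )
    def test_agrees_with_enumeration(self, lo, width, letter, n):
        """Membership matches brute-force enumeration of the whole range."""
        hi = min(99, lo + width)
        block = f"{letter}{lo:02d}-{letter}{hi:02d}"
        members = {f"{letter}{k:02d}" for k in range(lo, hi + 1)}
        cat = f"{letter}{n:02d}"
        assert range_contains(block, cat) == (cat in members)


class TestEquivalence:
    def test_known_substance(self, fixture_kb):
        out = resolve_equivalents(fixture_kb.equivalences, CodeRef(Scheme.SUBSTANCE, "acetazolamide"))
        assert out == {CodeRef(Scheme.SUBSTANCE, "acetazolamide"), CodeRef(Scheme.ATC, "S01EC01")}

    def test_unknown_code_is_singleton(self, fixture_kb):
        ref = CodeRef(Scheme.SUBSTANCE, "rimonabant")
        assert resolve_equivalents(fixture_kb.equivalences, ref) == {ref}

    def test_symmetric_over_whole_table(self, fixture_kb):
        eq = fixture_kb.equivalences
        for substance, atc in eq.pairs():
            s_ref = CodeRef(Scheme.SUBSTANCE, substance)
            a_ref = CodeRef(Scheme.ATC, atc)
            assert a_ref in resolve_equivalents(eq, s_ref)
            assert s_ref in resolve_equivalents(eq, a_ref)

    def test_one_to_one_enforced(self):
        eq = EquivalenceTable()
        eq.add("acetazolamide", "S01EC01")
        with pytest.raises(TerminologyError, match="one-to-one"):
            eq.add("acetazolamide", "N06DA02")
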