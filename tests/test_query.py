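import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codelistkit import (
    build_query,
    match_code_prefix,
    match_description,
    parse_term,
    run_search,
)
from codelistkit.errors import EmptyQueryError, TermParseError
from codelistkit.lookups import lookup_from_records
from codelistkit.query import SearchQuery, read_term_file
from helpers import oracle_search, random_lookup, random_query


class TestParseTerm:
    @pytest.mark.parametrize(
        "raw, kind, stubs",
        [
            ("alcohol+depend", "word_query", ("alcohol", "depend")),
            ("ischemic_cardiomyopathy", "word_query", ("ischemic cardiomyopathy",)),
            ("angin", "word_query", ("angin",)),
            ("$hypersplenism", "exclusion", ("hypersplenism",)),
            ("a_b+c_d", "word_query", ("a b", "c d")),
        ],
    )
    def test_word_syntax(self, raw, kind, stubs):
        term = parse_term(raw, "word")
        assert term.kind == kind
        assert term.stubs == stubs

    def test_code_hint_keeps_special_characters_literal(self):
        term = parse_term("H33+_$x", "code")
        assert term.kind == "code_stub"
        assert term.stubs == ("H33+_$x",)

    @pytest.mark.parametrize("raw", ["", "   ", "+", "$", "a++b", "$a+b", "mid$dollar", "_"])
    def test_malformed_terms_rejected(self, raw):
        with pytest.raises(TermParseError):
            parse_term(raw, "word")


class TestMatchDescription:
    @pytest.mark.parametrize(
        "raw, description, expected",
        [
            ("angin", "Ludwig's angina", True),
            ("angin", "Head-banging", True),  # plain substring, no word boundaries
            ("stroke", "sunstroke", True),  # the classic false positive
            ("alcohol+depend", "Alcohol dependence syndrome", True),
            ("alcohol+depend", "Alcohol intake", False),
            ("ischemic_cardiomyopathy", "chronic ischemic cardiomyopathy", True),
            ("ischemic_cardiomyopathy", "ischemic dilated cardiomyopathy", False),
            ("angin", "", False),
        ],
    )
    def test_examples(self, raw, description, expected):
        assert match_description(parse_term(raw, "word"), description) is expected

    def test_case_folding_is_configurable(self):
        term = parse_term("ANGIN", "word")
        assert match_description(term, "ludwig's angina") is True
        assert match_description(term, "ludwig's angina", case_sensitive=True) is False


class TestMatchCodePrefix:
    @pytest.mark.parametrize(
        "stub, code, expected",
        [
            ("H33", "H331.11", True),
            ("H33", "8H33.00", False),  # prefix, not infix
            ("H331.11", "H331.11", True),
            ("h33", "H331.11", False),  # codes are case-significant
        ],
    )
    def test_examples(self, stub, code, expected):
        assert match_code_prefix(stub, code) is expected

    def test_agrees_with_character_comparator_over_fixture(self, printed_lookup):
        stubs = ["H", "H33", "H331.11", "8H3", "13HV", "J0833", "h33", "E2731000"]
        for stub in stubs:
            for e in printed_lookup:
                by_chars = len(e.code) >= len(stub) and all(
                    e.code[i] == stub[i] for i in range(len(stub))
                )
                assert match_code_prefix(stub, e.code) is by_chars


class TestRunSearch:
    def test_code_stub_returns_prefix_hit_only(self, printed_lookup):
        result = run_search(build_query(code_terms=["H33"]), printed_lookup)
        assert [e.code for e in result.hits] == ["H331.11"]

    def test_word_stub_returns_true_and_false_positives(self, printed_lookup):
        result = run_search(build_query(word_terms=["angin"]), printed_lookup)
        assert sorted(e.code for e in result.hits) == ["E273100", "J083300"]

    def test_exclusion_removes_matching_rows(self, splen_lookup):
        result = run_search(
            build_query(word_terms=["splen", "$hypersplenism"]), splen_lookup
        )
        assert sorted(e.description for e in result.hits) == [
            "Splenectomy",
            "Splenomegaly",
        ]

    def test_exclusions_also_veto_code_stub_hits(self):
        table = lookup_from_records([("H331.11", "Hypersplenism note")])
        result = run_search(
            build_query(word_terms=["$hypersplenism"], code_terms=["H33"]), table
        )
        assert len(result.hits) == 0

    def test_absent_stub_gives_empty_hits(self, printed_lookup):
        assert len(run_search(build_query(word_terms=["zzz-absent"]), printed_lookup)) == 0

    def test_exclusion_only_query_rejected(self, printed_lookup):
        query = build_query(word_terms=["$angin"])
        with pytest.raises(EmptyQueryError):
            run_search(query, printed_lookup)

    def test_every_hit_has_a_matching_include_term(self, printed_lookup):
        result = run_search(
            build_query(word_terms=["angin", "asthma"], code_terms=["13"]), printed_lookup
        )
        assert set(result.matched_by) == {e.row_id for e in result.hits}
        assert all(result.matched_by[e.row_id] for e in result.hits)

    def test_output_sorted_and_deterministic(self, printed_lookup):
        query = build_query(word_terms=["a"])
        r1 = run_search(query, printed_lookup)
        r2 = run_search(query, printed_lookup)
        keys = [(e.code, e.description, e.row_id) for e in r1.hits]
        assert keys == sorted(keys)
        assert r1.to_frame().equals(r2.to_frame())


class TestAlgebraicProperties:
    """Monotonicity and set-algebra laws on randomised instances."""

    def test_inclusion_monotonicity(self):
        rng = random.Random(11)
        for _ in range(30):
            table = random_lookup(rng, rng.randint(10, 200))
            q = random_query(rng, table, max_terms=4)
            extra = random_query(rng, table, max_terms=1)
            bigger = SearchQuery(
                includes=q.includes + extra.includes, excludes=q.excludes
            )
            small = {e.row_id for e in run_search(q, table).hits}
            big = {e.row_id for e in run_search(bigger, table).hits}
            assert small <= big

    def test_exclusion_monotonicity(self):
        rng = random.Random(12)
        for _ in range(30):
            table = random_lookup(rng, rng.randint(10, 200))
            q = random_query(rng, table, max_terms=4)
            extra = parse_term("$" + rng.choice(table.entries).description.split()[0], "word")
            narrower = SearchQuery(includes=q.includes, excludes=q.excludes + (extra,))
            base = {e.row_id for e in run_search(q, table).hits}
            fewer = {e.row_id for e in run_search(narrower, table).hits}
            assert fewer <= base

    def test_conjunction_is_intersection(self):
        rng = random.Random(13)
        for _ in range(30):
            table = random_lookup(rng, rng.randint(10, 200))
            words = [w for e in table.entries for w in e.description.split()]
            a, b = rng.choice(words)[:4], rng.choice(words)[:4]
            both = {
                e.row_id for e in run_search(build_query(word_terms=[f"{a}+{b}"]), table).hits
            }
            only_a = {e.row_id for e in run_search(build_query(word_terms=[a]), table).hits}
            only_b = {e.row_id for e in run_search(build_query(word_terms=[b]), table).hits}
            assert both == only_a & only_b

    def test_substring_dominance(self):
        rng = random.Random(14)
        for _ in range(30):
            table = random_lookup(rng, rng.randint(10, 200))
            words = [w for e in table.entries for w in e.description.split() if len(w) >= 4]
            w = rng.choice(words)
            shorter, longer = w[:3], w[:5]
            hits_long = {
                e.row_id for e in run_search(build_query(word_terms=[longer]), table).hits
            }
            hits_short = {
                e.row_id for e in run_search(build_query(word_terms=[shorter]), table).hits
            }
            assert hits_long <= hits_short

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_oracle_equivalence_randomised(self, seed):
        rng = random.Random(seed)
        table = random_lookup(rng, rng.randint(5, 300))
        query = random_query(rng, table, max_terms=5)
        result = run_search(query, table)
        hits, matched_by = oracle_search(query, table)
        assert [e.row_id for e in result.hits] == [e.row_id for e in hits]
        assert result.matched_by == matched_by


def test_term_file_reading_skips_comments(tmp_path):
    path = tmp_path / "terms.txt"
    path.write_text("# clinician word stubs\nangin\n\n$hypersplenism\nalcohol+depend\n")
    includes, excludes = read_term_file(path, "word")
    assert [t.raw for t in includes] == ["angin", "alcohol+depend"]
    assert [t.raw for t in excludes] == ["$hypersplenism"]
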