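"""Module-definition parsing, completion-set enumeration, evaluation and
gap-filling."""

import numpy as np
import pytest

from modcast.grammar import (
    AllOf,
    AnyOf,
    Atom,
    Complex,
    DefinitionSyntaxError,
    EnumerationOverflow,
    Optional,
    Wildcard,
    atom_kos,
    enumerate_completion_sets,
    evaluate_module,
    gap_fill,
    parse_definition,
    serialize,
)
from modcast.synthetic_data import random_module_ast


def sets(defn, limit=10_000):
    return enumerate_completion_sets(parse_definition("M", defn), limit=limit)


class TestParse:
    def test_whitespace_separates_steps(self):
        ast = parse_definition("M1", "K00001 K00002")
        assert ast.steps == (Atom("K00001"), Atom("K00002"))

    def test_comma_is_alternative_within_parens(self):
        ast = parse_definition("M2", "K00001 (K00002,K00003)")
        assert ast.steps == (
            Atom("K00001"),
            AnyOf((Atom("K00002"), Atom("K00003"))),
        )

    def test_complex_with_optional_subunit(self):
        ast = parse_definition("M3", "K00001+K00002-K00003")
        assert ast.steps == (
            Complex((Atom("K00001"), Atom("K00002"), Optional(Atom("K00003")))),
        )

    def test_comma_binds_tighter_than_space(self):
        ast = parse_definition("M", "K1 K2,K3")
        assert ast.steps == (Atom("K1"), AnyOf((Atom("K2"), Atom("K3"))))

    def test_plus_binds_tighter_than_comma(self):
        ast = parse_definition("M", "K1+K2,K3")
        assert ast.steps == (AnyOf((Complex((Atom("K1"), Atom("K2"))), Atom("K3"))),)

    def test_wildcard_step(self):
        ast = parse_definition("M", "K1 -- K2")
        assert ast.steps == (Atom("K1"), Wildcard(), Atom("K2"))

    def test_optional_step_prefix(self):
        ast = parse_definition("M", "-K1 K2")
        assert ast.steps == (Optional(Atom("K1")), Atom("K2"))

    def test_grouped_step_counts_once(self):
        ast = parse_definition("M", "(K1 K2) K3")
        assert ast.steps == (AllOf((Atom("K1"), Atom("K2"))), Atom("K3"))

    @pytest.mark.parametrize(
        "bad",
        ["", "   ", "(K1 K2", "K1)", "K1 (K2,)", "K1 (,K2)", "K1 & K2", "K1,,K2"],
    )
    def test_syntax_errors_carry_position(self, bad):
        with pytest.raises(DefinitionSyntaxError) as err:
            parse_definition("M", bad)
        assert "position" in str(err.value)

    @pytest.mark.parametrize(
        "defn",
        [
            "K00001 K00002",
            "K00001 (K00002,K00003)",
            "K00001+K00002-K00003",
            "(K1,K2) (K3,K4)",
            "-(K1,K2) K3 --",
            "(K1 K2),K3 K4+K5",
            "((K1,K2+K6) K3) -K7",
        ],
    )
    def test_serialize_reparse_is_identity_on_ast(self, defn):
        ast = parse_definition("M", defn)
        again = parse_definition("M", serialize(ast))
        assert again == ast

    def test_serialize_reparse_on_random_asts(self):
        rng = np.random.default_rng(99)
        for _ in range(300):
            ast = random_module_ast(rng)
            assert parse_definition(ast.module_id, serialize(ast)) == ast


class TestEnumerate:
    def test_single_alternative(self):
        assert sets("K1 (K2,K3)") == [
            frozenset({"K1", "K2"}),
            frozenset({"K1", "K3"}),
        ]

    def test_cartesian_product_of_alternatives(self):
        assert set(sets("(K1,K2) (K3,K4)")) == {
            frozenset({"K1", "K3"}),
            frozenset({"K1", "K4"}),
            frozenset({"K2", "K3"}),
            frozenset({"K2", "K4"}),
        }

    def test_complex_is_single_conjunctive_set(self):
        assert sets("K1+K2") == [frozenset({"K1", "K2"})]

    def test_optional_and_wildcard_ignored(self):
        assert sets("K1-K2 --") == [frozenset({"K1"})]

    def test_sorted_by_size_then_lexicographically(self):
        out = sets("(K2,K1,K3+K4)")
        assert out == [
            frozenset({"K1"}),
            frozenset({"K2"}),
            frozenset({"K3", "K4"}),
        ]

    def test_overflow_signalled(self):
        defn = " ".join(f"(A{i},B{i})" for i in range(15))  # 2^15 sets
        with pytest.raises(EnumerationOverflow):
            sets(defn, limit=10_000)

    def test_count_equals_product_for_disjoint_branches(self):
        # 2 * 3 * 2 alternatives with disjoint KO sets
        out = sets("(A1,A2) (B1,B2,B3) (C1,C2)")
        assert len(out) == 12

    def test_shared_kos_deduplicate_and_prune_supersets(self):
        # choosing K1 alone dominates the K1+K2 branch
        assert sets("(K1,K1+K2)") == [frozenset({"K1"})]


class TestEvaluate:
    def test_complete_membership(self):
        ast = parse_definition("M", "K1 (K2,K3)")
        ev = evaluate_module(ast, {"K1", "K3"})
        assert ev.status == "complete"
        assert ev.completeness == 1.0
        assert ev.missing_kos == frozenset()

    def test_half_complete(self):
        ast = parse_definition("M", "K1 (K2,K3)")
        ev = evaluate_module(ast, {"K3"})
        assert ev.status == "incomplete"
        assert ev.completeness == 0.5
        assert ev.missing_kos == frozenset({"K1"})

    def test_empty_ko_set(self):
        ast = parse_definition("M", "K1 K2+K3")
        ev = evaluate_module(ast, set())
        assert ev.steps_satisfied == 0
        assert ev.completeness == 0.0
        assert ev.status == "incomplete"

    def test_optional_and_wildcard_steps_always_satisfied(self):
        ast = parse_definition("M", "-K1 -- K2")
        ev = evaluate_module(ast, set())
        assert ev.steps_total == 3
        assert ev.steps_satisfied == 2  # optional + wildcard
        ev2 = evaluate_module(ast, {"K2"})
        assert ev2.status == "complete"

    def test_status_iff_steps_iff_missing(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            ast = random_module_ast(rng, max_atoms=8)
            pool = sorted(atom_kos(ast, include_optional=True)) or ["K00001"]
            kos = {k for k in pool if rng.random() < 0.5}
            ev = evaluate_module(ast, kos)
            assert (ev.status == "complete") == (ev.steps_satisfied == ev.steps_total)
            assert (ev.status == "complete") == (not ev.missing_kos)

    def test_recursion_agrees_with_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            ast = random_module_ast(rng, max_atoms=10)
            csets = enumerate_completion_sets(ast)
            pool = sorted(atom_kos(ast, include_optional=True)) or ["K00001"]
            for _ in range(5):
                kos = {k for k in pool if rng.random() < 0.4}
                brute = any(s <= kos for s in csets)
                assert (evaluate_module(ast, kos).status == "complete") == brute

    def test_monotone_in_ko_set(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            ast = random_module_ast(rng, max_atoms=10)
            pool = sorted(atom_kos(ast, include_optional=True)) or ["K00001"]
            small = {k for k in pool if rng.random() < 0.3}
            big = small | {k for k in pool if rng.random() < 0.5}
            ev_small = evaluate_module(ast, small)
            ev_big = evaluate_module(ast, big)
            assert ev_small.completeness <= ev_big.completeness
            if ev_small.status == "complete":
                assert ev_big.status == "complete"


class TestGapFill:
    def test_single_missing_gene(self):
        assert gap_fill(parse_definition("M", "K1 K2"), {"K1"}) == frozenset({"K2"})

    def test_lexicographic_tie_break(self):
        out = gap_fill(parse_definition("M", "(K1,K2) (K3,K4)"), {"K2"})
        assert out == frozenset({"K3"})

    def test_empty_when_complete(self):
        assert gap_fill(parse_definition("M", "K1 (K2,K3)"), {"K1", "K2"}) == frozenset()

    def test_soundness_on_random_asts(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            ast = random_module_ast(rng, max_atoms=10)
            pool = sorted(atom_kos(ast, include_optional=True)) or ["K00001"]
            kos = {k for k in pool if rng.random() < 0.4}
            fill = gap_fill(ast, kos)
            assert evaluate_module(ast, kos | fill).status == "complete"

    def test_minimal_under_enumeration(self):
        # with an explicit small alternative the fill never picks the big branch
        ast = parse_definition("M", "(K1,K5+K6+K7) K9")
        assert gap_fill(ast, set()) == frozenset({"K1", "K9"})


def test_atom_kos_respects_optional_flag():
    ast = parse_definition("M", "K1+K2-K3 (K4,K5)")
    assert atom_kos(ast) == frozenset({"K1", "K2", "K4", "K5"})
    assert atom_kos(ast, include_optional=True) == frozenset(
        {"K1", "K2", "K3", "K4", "K5"}
    )
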