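import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgram import (
    Config,
    Rule,
    WarpedSequence,
    arc_diagram,
    chunked_phenotype,
    compress,
    count_nonoverlapping,
    decompress,
    dendrogram,
    expand_cgram,
    find_most_compressive,
    nesting_depth,
    savings,
)
from cgram.compression import CompressionResult

label_lists = st.lists(st.integers(min_value=1, max_value=8), max_size=80)


# ------------------------------------------------------------------ oracle


def oracle_best(seq, w_max):
    """Exhaustive search for the most compressive subsequence.

    Enumerates every unique subsequence with 2 <= W <= w_max, counts
    non-overlapping occurrences with a plain stepping scan, and picks the
    maximum-savings candidate; ties resolved by (length, labels) ascending.
    Independent of the library's grouped-window scan.
    """
    seq = list(seq)
    best = None  # (S, W, body)
    for w in range(2, w_max + 1):
        subs = sorted({tuple(seq[i : i + w]) for i in range(len(seq) - w + 1)})
        for sub in subs:
            n, i = 0, 0
            while i + w <= len(seq):
                if tuple(seq[i : i + w]) == sub:
                    n += 1
                    i += w
                else:
                    i += 1
            if n < 2:
                continue
            s = w * n - (w + 1 + n)
            if s < 1:
                continue
            key = (-s, w, sub)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    return best[2], -best[0]


# -------------------------------------------------------------- operations


class TestSavings:
    @pytest.mark.parametrize(
        "w, n, expected", [(3, 5, 6), (2, 3, 0), (2, 2, -1), (10, 11, 88)]
    )
    def test_formula(self, w, n, expected):
        assert savings(w, n) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            savings(0, 5)


class TestCountNonoverlapping:
    def test_greedy_scan_resumes_after_match(self, worked_example):
        n, starts = count_nonoverlapping(worked_example, [1, 2, 1])
        assert n == 5
        assert starts == (1, 4, 9, 12, 17)

    def test_overlaps_forbidden(self):
        assert count_nonoverlapping([1, 1, 1, 1], [1, 1]) == (2, (1, 3))

    def test_absent_pattern(self):
        assert count_nonoverlapping([1, 2, 3], [4, 5]) == (0, ())

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            count_nonoverlapping([1, 2], [])


class TestFindMostCompressive:
    def test_worked_example_first_iteration(self, worked_example):
        cand = find_most_compressive(worked_example)
        assert cand.body == (1, 2, 1)
        assert cand.savings == 6
        assert cand.N == 5

    def test_tie_resolved_by_canonical_order(self):
        # both 4-grams save exactly 1 symbol; lexicographically smaller wins
        cand = find_most_compressive([3, 3, 2, 2, 3, 3, 2, 2, 3])
        assert cand.body == (3, 2, 2, 3)
        assert cand.savings == 1

    def test_no_repeats_gives_none(self):
        assert find_most_compressive([1, 2, 3, 4, 5]) is None

    @settings(max_examples=300)
    @given(label_lists, st.integers(min_value=2, max_value=6))
    def test_agrees_with_exhaustive_oracle(self, seq, w_max):
        cand = find_most_compressive(seq, Config(w_max=w_max))
        expected = oracle_best(seq, w_max)
        if expected is None:
            assert cand is None
        else:
            assert (cand.body, cand.savings) == expected


class TestCompress:
    def test_worked_example_accounting(self, worked_example):
        res = compress(worked_example)
        assert res.l == 19
        assert res.total_savings == 7
        assert len(res.compressed) == 3
        assert res.dictionary_size == 9
        assert res.compressibility == pytest.approx(7 / 19)
        assert [r.body for r in res.rules] == [(1, 2, 1), (3, 2, 2, 3)]
        assert res.rules[0].symbol == 3 and res.rules[1].symbol == 4

    def test_empty_sequence(self):
        res = compress([])
        assert res.compressibility == 0.0 and not res.rules

    def test_all_distinct_labels_incompressible(self):
        res = compress(list(range(1, 40)))
        assert res.compressibility == 0.0 and not res.rules

    def test_warped_sequence_alphabet_sets_symbol_base(self):
        ws = WarpedSequence([1, 2, 1, 2, 1, 2, 1, 2, 1], alphabet_size=90)
        res = compress(ws)
        assert all(r.symbol > 90 for r in res.rules)

    @given(label_lists)
    def test_lossless_and_accounting_identity(self, seq):
        res = compress(seq)
        assert decompress(res) == list(seq)
        assert res.l == len(res.compressed) + res.dictionary_size + res.total_savings
        assert 0 <= res.compressibility < 1
        for rule in res.rules:
            assert rule.savings >= 1
            assert rule.N >= 2
            assert 2 <= rule.W <= 10
            assert all(tok < rule.symbol for tok in rule.body)

    @given(label_lists)
    def test_deterministic(self, seq):
        assert compress(seq) == compress(seq)

    @given(label_lists)
    def test_cgram_expansions_occur_in_input(self, seq):
        res = compress(seq)
        seq = list(seq)
        for rule in res.rules:
            exp = list(expand_cgram(res.rules, rule.symbol, res.alphabet_size))
            assert any(
                seq[i : i + len(exp)] == exp
                for i in range(len(seq) - len(exp) + 1)
            )


class TestDecompressAndExpansion:
    @pytest.fixture
    def example_rules(self):
        return (
            Rule(symbol=3, body=(1, 2, 1), N=5, savings=6,
                 starts=(1, 4, 9, 12, 17), orig_starts=(1, 4, 9, 12, 17)),
            Rule(symbol=4, body=(3, 2, 2, 3), N=2, savings=1,
                 starts=(2, 6), orig_starts=(4, 12)),
        )

    def test_manual_expansion(self, example_rules, worked_example):
        res = CompressionResult(
            compressed=(3, 4, 4), rules=example_rules, l=19,
            compressibility=7 / 19, alphabet_size=2,
        )
        assert decompress(res) == worked_example

    def test_no_rules_is_identity(self):
        res = CompressionResult(
            compressed=(1, 2, 3), rules=(), l=3,
            compressibility=0.0, alphabet_size=5,
        )
        assert decompress(res) == [1, 2, 3]

    def test_unknown_symbol_raises(self, example_rules):
        res = CompressionResult(
            compressed=(3, 9), rules=example_rules, l=19,
            compressibility=0.0, alphabet_size=2,
        )
        with pytest.raises(KeyError):
            decompress(res)

    def test_expand_cgram(self, example_rules):
        assert expand_cgram(example_rules, 17, alphabet_size=90) == (17,)
        assert expand_cgram(example_rules, 3, alphabet_size=2) == (1, 2, 1)
        assert expand_cgram(example_rules, 4, alphabet_size=2) == (
            1, 2, 1, 2, 2, 1, 2, 1,
        )
        with pytest.raises(KeyError):
            expand_cgram(example_rules, 99, alphabet_size=2)

    def test_nesting_depth(self, example_rules):
        assert nesting_depth(example_rules, 1, alphabet_size=2) == 0
        assert nesting_depth(example_rules, 3, alphabet_size=2) == 1
        assert nesting_depth(example_rules, 4, alphabet_size=2) == 2

    def test_most_nested_rule_of_worked_example(self, worked_example):
        res = compress(worked_example)
        depths = {r.symbol: nesting_depth(res.rules, r.symbol, 2) for r in res.rules}
        deepest = max(depths, key=depths.get)
        by_symbol = {r.symbol: r for r in res.rules}
        assert by_symbol[deepest].body == (3, 2, 2, 3)

    def test_dendrogram_structure(self, example_rules):
        tree = dendrogram(example_rules, 4, alphabet_size=2)
        assert tree.symbol == 4 and tree.count == 2
        assert [c.symbol for c in tree.children] == [3, 2, 2, 3]
        assert tree.children[0].count == 5  # nested rule keeps its own N
        assert tree.leaves() == [1, 2, 1, 2, 2, 1, 2, 1]
        assert all(
            1 <= leaf <= 2 for leaf in tree.leaves()
        )  # leaves are base labels


class TestArcDiagram:
    def test_adjacent_occurrence_pairs(self, worked_example):
        res = compress(worked_example)
        arcs = [a for a in arc_diagram(res) if a.symbol == 3]
        assert [(a.start_a, a.start_b) for a in arcs] == [
            (1, 4), (4, 9), (9, 12), (12, 17),
        ]
        assert all(a.width == 3 for a in arcs)

    def test_nested_rule_arcs_in_original_coordinates(self, worked_example):
        res = compress(worked_example)
        arcs = [a for a in arc_diagram(res) if a.symbol == 4]
        assert [(a.start_a, a.start_b) for a in arcs] == [(4, 12)]
        assert arcs[0].width == 8  # fully expanded length

    def test_no_rules_no_arcs(self):
        assert arc_diagram(compress([1, 2, 3])) == []

    def test_structured_sequence_has_more_arcs_than_shuffled(self, rng):
        from cgram import cyclic_deterministic, shuffle

        # full 90-label alphabet: shuffling then leaves few chance repeats
        structured = cyclic_deterministic(90, 1700)
        shuffled = shuffle(structured, seed=rng)
        n_structured = len(arc_diagram(compress(structured)))
        n_shuffled = len(arc_diagram(compress(shuffled)))
        assert n_shuffled < n_structured


class TestChunkedPhenotype:
    def test_partial_chunk_discarded(self):
        ws = WarpedSequence(
            [(i % 89) + 1 for i in range(1234)], alphabet_size=90
        )
        assert len(chunked_phenotype(ws, chunk_len=500)) == 2

    def test_incompressible_chunk_reports_zero_and_mean_duration(self):
        ws = WarpedSequence(
            list(range(1, 11)), durations=[2.0] * 10, alphabet_size=90
        )
        assert chunked_phenotype(ws, chunk_len=10) == [(0.0, 2.0)]

    def test_mean_duration_of_alternating_dwells(self):
        labels = [1, 2] * 5
        ws = WarpedSequence(labels, durations=[1.0, 3.0] * 5, alphabet_size=90)
        [(comp, dur)] = chunked_phenotype(ws, chunk_len=10)
        assert dur == pytest.approx(2.0)
        assert comp > 0  # alternation is compressible

    def test_short_sequence_gives_empty_list(self):
        ws = WarpedSequence([1, 2, 3], alphabet_size=90)
        assert chunked_phenotype(ws, chunk_len=500) == []

    def test_chunk_len_validation(self):
        with pytest.raises(ValueError):
            chunked_phenotype(WarpedSequence([1, 2], alphabet_size=90), chunk_len=1)


class TestConfig:
    def test_w_max_bound_is_respected(self):
        # a 4-gram repeat is invisible at w_max=2 unless its 2-grams pay
        seq = [1, 2, 3, 4, 9, 1, 2, 3, 4, 8, 1, 2, 3, 4]
        res2 = compress(seq, Config(w_max=2))
        res10 = compress(seq, Config(w_max=10))
        assert all(r.W <= 2 for r in res2.rules)
        assert res10.total_savings >= res2.total_savings

    def test_invalid_w_max(self):
        with pytest.raises(ValueError):
            Config(w_max=1)
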