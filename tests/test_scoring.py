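"""Presence matrix and tf-idf scoring: worked values, invariances."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trophomine.corpus import Subcorpus
from trophomine.io_formats import DocumentRecord
from trophomine.mentions import GeneLexicon, MentionIndex
from trophomine.scoring import (
    presence_matrix,
    rank_and_select,
    tfidf_scores,
)


def index_of(n, GF, D, N):
    return MentionIndex(n=n, GF=GF, D=D, N=N)


class TestTfidf:
    def test_worked_example(self):
        """Gene in two subcorpora of sizes 6 and 4 with 2 mentions total,
        D=1000, GF=10: tf = 2/10, idf = ln(100), w = 0.2 * ln(100).

        Frozen from an independent hand evaluation of the formulas:
        tf = 0.2, idf = 4.605170186, w = 0.9210340372.
        """
        index = index_of(
            n={("G", "A"): 1, ("G", "B"): 1},
            GF={"G": 10},
            D=1000,
            N={"A": 6, "B": 4},
        )
        (score,) = tfidf_scores(index)
        assert score.tf == pytest.approx(0.2)
        assert score.idf == pytest.approx(4.6051701860, abs=1e-9)
        assert score.w == pytest.approx(0.9210340372, abs=1e-9)

    def test_sc_excludes_subcorpora_without_the_gene(self):
        """N_j of a subcorpus where the gene never occurs does not dilute tf."""
        index = index_of(
            n={("G", "A"): 2, ("G", "B"): 0},
            GF={"G": 10},
            D=1000,
            N={"A": 10, "B": 90},
        )
        (score,) = tfidf_scores(index)
        assert score.tf == pytest.approx(0.2)

    def test_background_saturated_gene_scores_zero(self):
        index = index_of(n={("G", "A"): 1}, GF={"G": 50}, D=50, N={"A": 5})
        (score,) = tfidf_scores(index)
        assert score.idf == 0.0 and score.w == 0.0

    def test_doubling_mentions_doubles_w(self):
        base = index_of(n={("G", "A"): 2}, GF={"G": 10}, D=1000, N={"A": 20})
        double = index_of(n={("G", "A"): 4}, GF={"G": 10}, D=1000, N={"A": 20})
        (s1,), (s2,) = tfidf_scores(base), tfidf_scores(double)
        assert s2.w == pytest.approx(2 * s1.w)

    def test_gene_missing_from_background_excluded_with_warning(self, caplog):
        import logging

        index = index_of(
            n={("G", "A"): 1, ("H", "A"): 1}, GF={"G": 10, "H": 0},
            D=100, N={"A": 5},
        )
        with caplog.at_level(logging.WARNING):
            scores = tfidf_scores(index)
        assert [s.gene for s in scores] == ["G"]
        assert any("H" in m for m in caplog.messages)

    def test_gene_absent_from_all_subcorpora_ranked_last_with_zero(self):
        index = index_of(
            n={("G", "A"): 1, ("H", "A"): 0}, GF={"G": 10, "H": 10},
            D=100, N={"A": 5},
        )
        scores = tfidf_scores(index)
        assert scores[-1].gene == "H" and scores[-1].w == 0.0

    def test_gf_above_d_is_error(self):
        index = index_of(n={("G", "A"): 1}, GF={"G": 10}, D=100, N={"A": 5})
        index.GF = {"G": 200}  # bypass constructor check to hit the scorer's
        with pytest.raises(ValueError, match="exceeds D"):
            tfidf_scores(index)

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_ranking_invariant_to_log_base(self, data):
        """Any log base > 1 yields the same gene order."""
        genes = [f"G{i}" for i in range(data.draw(st.integers(2, 6)))]
        D = 1000
        n, GF, N = {}, {}, {"A": 30, "B": 20}
        for g in genes:
            n[(g, "A")] = data.draw(st.integers(0, 30))
            n[(g, "B")] = data.draw(st.integers(0, 20))
            GF[g] = data.draw(st.integers(1, D))
        index = index_of(n, GF, D, N)
        base = data.draw(st.sampled_from([2.0, math.e, 10.0, 1.5]))
        natural = [s.gene for s in tfidf_scores(index)]
        rebased = [s.gene for s in tfidf_scores(index, base=base)]
        assert natural == rebased

    def test_raising_one_count_never_lowers_rank(self):
        n = {("G", "A"): 2, ("H", "A"): 5, ("K", "A"): 1}
        GF = {"G": 10, "H": 10, "K": 10}
        index = index_of(dict(n), GF, 1000, {"A": 20})
        before = {s.gene: s.rank for s in tfidf_scores(index)}
        n[("G", "A")] = 3
        after = {s.gene: s.rank for s in tfidf_scores(index_of(n, GF, 1000, {"A": 20}))}
        assert after["G"] <= before["G"]

    def test_planted_high_frequency_low_background_gene_ranks_first(self):
        n = {("RARE", "A"): 18, ("COMMON", "A"): 18, ("MID", "A"): 5}
        GF = {"RARE": 2, "COMMON": 900, "MID": 100}
        scores = tfidf_scores(index_of(n, GF, 1000, {"A": 20}))
        assert scores[0].gene == "RARE" and scores[0].rank == 1


def make_subcorpora(layout):
    """layout: per-subcorpus lists of abstracts driving the dictionaries."""
    subs = []
    pairs = [("bovine", "tro"), ("human", "tro"), ("mouse", "tro"),
             ("rat", "tro"), ("human", "cho"), ("mouse", "cho")]
    for (species, tissue), abstracts in zip(pairs, layout):
        sub = Subcorpus(species, tissue)
        for i, ab in enumerate(abstracts):
            sub.add(DocumentRecord(doc_id=f"{species}{tissue}{i}",
                                   source="pubmed", abstract=ab))
        subs.append(sub)
    return subs


class TestPresence:
    def test_row_sums(self):
        subs = make_subcorpora([["gata3 a"], ["gata3 b"], ["gata3 c"], ["x"], ["y"], ["z"]])
        genes = [GeneLexicon.build("GATA3", ["GATA3"]),
                 GeneLexicon.build("NONE", ["NONE"])]
        matrix = presence_matrix(genes, subs)
        assert matrix.s_i0["GATA3"] == 3
        assert matrix.s_i0["NONE"] == 0

    def test_rows_sorted_by_score_then_symbol(self):
        subs = make_subcorpora([["aaa bbb"], ["aaa"], [], [], [], []])
        genes = [GeneLexicon.build(s, [s]) for s in ("BBB", "AAA")]
        matrix = presence_matrix(genes, subs)
        assert matrix.genes == ["AAA", "BBB"]  # 2 hits before 1 hit

    def test_selection_cutoff(self):
        subs = make_subcorpora([["g"], ["g"], ["g"], ["g"], ["g"], ["x"]])
        matrix = presence_matrix([GeneLexicon.build("G", ["G"])], subs)
        assert matrix.select(min_score=5) == ["G"]
        assert matrix.select(min_score=6) == []

    def test_conservation_sum_of_row_sums_equals_ones(self):
        subs = make_subcorpora([["g h"], ["g"], ["h"], [], [], []])
        genes = [GeneLexicon.build(s, [s]) for s in ("G", "H")]
        matrix = presence_matrix(genes, subs)
        assert sum(matrix.s_i0.values()) == int(matrix.s.sum())

    def test_no_subcorpora_is_error(self):
        with pytest.raises(ValueError):
            presence_matrix([GeneLexicon.build("G", ["G"])], [])


class TestRankAndSelect:
    def scores(self, pairs):
        index = index_of(
            n={(g, "A"): c for g, c in pairs}, GF={g: 10 for g, _ in pairs},
            D=1000, N={"A": 50},
        )
        return tfidf_scores(index)

    def test_k_zero_empty(self):
        assert rank_and_select(self.scores([("G", 5)]), 0) == []

    def test_negative_k_error(self):
        with pytest.raises(ValueError):
            rank_and_select([], -1)

    def test_equal_scores_alphabetical(self):
        scores = self.scores([("ZZZ", 5), ("AAA", 5)])
        assert [s.gene for s in rank_and_select(scores, 2)] == ["AAA", "ZZZ"]

    def test_topk_overlap_matches_set_intersection_oracle(self):
        subs = make_subcorpora(
            [["aa bb"], ["aa cc"], ["bb"], ["cc"], ["dd"], ["aa"]]
        )
        genes = [GeneLexicon.build(s, [s]) for s in ("AA", "BB", "CC", "DD")]
        matrix = presence_matrix(genes, subs)
        presence_top = matrix.genes[:2]
        tfidf_top = [
            s.gene
            for s in rank_and_select(
                self.scores([("AA", 9), ("BB", 2), ("CC", 7), ("DD", 1)]), 2
            )
        ]
        overlap = set(presence_top) & set(tfidf_top)
        # brute-force oracle over explicit memberships
        oracle = {
            g for g in ("AA", "BB", "CC", "DD")
            if g in presence_top and g in tfidf_top
        }
        assert overlap == oracle
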