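"""BLEU, ontology distances, annotation cosine, Jaccard retrieval, binned ANOVA."""

import io
import math
from collections import Counter

import networkx as nx
import numpy as np
import pytest

import biotext as bt
from biotext.similarity import read_gmt
from biotext.text import tokenize


def reference_bleu(candidate, reference, max_n=4):
    """Independent BLEU: explicit clipped n-gram counts, log-domain mean, BP.

    Orders beyond the candidate length carry no n-grams and are excluded;
    the geometric mean runs over the populated orders.
    """
    cand, ref = tokenize(candidate), tokenize(reference)
    logs = []
    for n in range(1, max_n + 1):
        cand_ngrams = [tuple(cand[i:i + n]) for i in range(len(cand) - n + 1)]
        ref_counts = Counter(tuple(ref[i:i + n]) for i in range(len(ref) - n + 1))
        if not cand_ngrams:
            break
        clipped = Counter()
        for g in cand_ngrams:
            clipped[g] += 1
        matched = sum(min(v, ref_counts.get(g, 0)) for g, v in clipped.items())
        if matched == 0:
            return 0.0
        logs.append(math.log(matched / len(cand_ngrams)))
    bp = 1.0 if len(cand) >= len(ref) else math.exp(1 - len(ref) / len(cand))
    return bp * math.exp(sum(logs) / len(logs))


WORDS = ["protein", "binding", "cell", "membrane", "kinase", "signal",
         "transport", "nuclear", "response", "regulation"]


class TestBleu:
    def test_identical_texts_score_exactly_one(self):
        text = "regulation of T cell mediated immune response to tumor cell"
        assert bt.bleu_similarity(text, text) == 1.0

    def test_token_disjoint_texts_score_zero(self):
        assert bt.bleu_similarity("alpha beta gamma delta", "one two three four") == 0.0

    def test_matches_reference_implementation_on_random_pairs(self, rng):
        for _ in range(20):
            a = " ".join(rng.choice(WORDS, size=int(rng.integers(5, 15))))
            b = " ".join(rng.choice(WORDS, size=int(rng.integers(5, 15))))
            assert bt.bleu_similarity(a, b) == pytest.approx(
                reference_bleu(a, b), abs=1e-9
            )

    def test_empty_text_errors(self):
        with pytest.raises(ValueError):
            bt.bleu_similarity("", "something")

    def test_smoothing_gives_nonzero_for_partial_overlap(self):
        a = "protein binding activity"
        b = "protein transport activity"
        assert bt.bleu_similarity(a, b) == 0.0  # no 3-gram match, unsmoothed
        assert bt.bleu_similarity(a, b, smoothing=True) > 0.0

    def test_symmetrized_mean_of_both_directions(self):
        a = "protein binding"
        b = "protein binding activity and more words"
        sym = bt.bleu_similarity(a, b, symmetric=True, smoothing=True)
        fwd = bt.bleu_similarity(a, b, smoothing=True)
        bwd = bt.bleu_similarity(b, a, smoothing=True)
        assert sym == pytest.approx((fwd + bwd) / 2)


class TestGraphDistance:
    def test_self_distance_zero(self, toy_graph):
        assert bt.graph_distance("T:0004", "T:0004", toy_graph) == 0

    def test_parent_child_distance_one(self, toy_graph):
        assert bt.graph_distance("T:0002", "T:0001", toy_graph) == 1

    def test_diamond_corners_via_bfs_oracle(self, toy_graph):
        digraph = toy_graph.graph().to_undirected()
        expected = nx.shortest_path_length(digraph, "T:0004", "T:0001")
        assert bt.graph_distance("T:0004", "T:0001", toy_graph) == expected == 2

    def test_unknown_term_errors(self, toy_graph):
        with pytest.raises(KeyError):
            bt.graph_distance("T:0004", "NOPE:1", toy_graph)

    def test_unreachable_terms_return_none(self):
        terms = {
            "I:1": bt.OntologyTerm(id="I:1", name="a"),
            "I:2": bt.OntologyTerm(id="I:2", name="b"),
        }
        g = bt.OntologyGraph(terms)
        assert bt.graph_distance("I:1", "I:2", g) is None

    def test_triangle_inequality_on_sampled_triples(self, rng):
        g = bt.generate_ontology(bt.FixtureSpec(n_terms=30, seed=4))
        ids = sorted(g.active_ids)
        for _ in range(50):
            a, b, c = rng.choice(ids, size=3, replace=False)
            dab = bt.graph_distance(a, b, g)
            dbc = bt.graph_distance(b, c, g)
            dac = bt.graph_distance(a, c, g)
            if None not in (dab, dbc, dac):
                assert dac <= dab + dbc


class TestAnnotationCosine:
    def make_ann(self, cols):
        terms = sorted(cols)
        n = len(next(iter(cols.values())))
        A = np.array([[cols[t][i] for t in terms] for i in range(n)])
        return bt.AnnotationMatrix([f"i{k}" for k in range(n)], terms, A,
                                   propagated=True)

    def test_identical_vectors_give_one(self):
        ann = self.make_ann({"a": [1, 0, 1], "b": [1, 0, 1]})
        assert bt.annotation_cosine("a", "b", ann) == pytest.approx(1.0)

    def test_disjoint_vectors_give_zero(self):
        ann = self.make_ann({"a": [1, 0, 0], "b": [0, 1, 1]})
        assert bt.annotation_cosine("a", "b", ann) == 0.0

    def test_single_overlap_of_two_by_two_supports_gives_half(self):
        ann = self.make_ann({"a": [1, 1, 0], "b": [0, 1, 1]})
        assert bt.annotation_cosine("a", "b", ann) == pytest.approx(0.5)

    def test_unannotated_term_errors(self):
        ann = self.make_ann({"a": [1, 0], "b": [0, 0]})
        with pytest.raises(ValueError):
            bt.annotation_cosine("a", "b", ann)


class TestJaccardRetrieval:
    @pytest.mark.parametrize(
        "s1,s2,expected",
        [({"a", "b"}, {"a", "b"}, 1.0), ({"a"}, {"b"}, 0.0),
         ({"a", "b"}, {"b", "c"}, 1 / 3)],
    )
    def test_jaccard_values(self, s1, s2, expected):
        assert bt.jaccard_gene_sets(s1, s2) == pytest.approx(expected)

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            bt.jaccard_gene_sets(set(), {"a"})

    def test_query_equal_to_corpus_set_is_first(self):
        corpus = {"s1": {"a", "b"}, "s2": {"a", "b", "c"}, "s3": {"z"}}
        assert bt.nearest_gene_sets({"a", "b"}, corpus, k=2)[0] == "s1"

    def test_k_one_agrees_with_argmax_oracle(self, rng):
        genes = [f"g{i}" for i in range(30)]
        corpus = {
            f"s{i}": set(rng.choice(genes, size=8, replace=False))
            for i in range(15)
        }
        query = set(rng.choice(genes, size=8, replace=False))
        best = bt.nearest_gene_sets(query, corpus, k=1)[0]
        oracle = min(
            corpus, key=lambda s: (-bt.jaccard_gene_sets(query, corpus[s]), s)
        )
        assert best == oracle

    def test_all_disjoint_corpus_ordered_by_id(self):
        corpus = {"s3": {"x"}, "s1": {"y"}, "s2": {"z"}}
        assert bt.nearest_gene_sets({"q"}, corpus, k=3) == ["s1", "s2", "s3"]

    def test_k_beyond_corpus_warns_and_returns_all(self):
        corpus = {"s1": {"a"}, "s2": {"b"}}
        with pytest.warns(UserWarning):
            assert len(bt.nearest_gene_sets({"a"}, corpus, k=5)) == 2

    def test_read_gmt(self):
        gmt = io.StringIO("p1\tfirst pathway\tg1\tg2\np2\tsecond\tg3\n")
        sets = read_gmt(gmt)
        assert sets["p1"]["genes"] == {"g1", "g2"}
        assert sets["p2"]["description"] == "second"


class TestBinnedAssociation:
    def test_identical_group_distributions_give_f_zero_p_one(self):
        x = np.array([0.1, 0.1, 0.1, 0.5, 0.5, 0.5])
        y = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        f_stat, p = bt.binned_association_test(x, y)
        assert f_stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_f_ratio(self):
        x = np.array([0.1] * 4 + [0.9] * 4)
        y = np.array([1.0, 1.1, 0.9, 1.0, 3.0, 3.1, 2.9, 3.0])
        f_stat, p = bt.binned_association_test(x, y)
        groups = [y[:4], y[4:]]
        grand = y.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        expected = (ss_between / 1) / (ss_within / 6)
        assert f_stat == pytest.approx(expected, rel=1e-10)
        assert p < 1e-6

    def test_bins_excluding_all_data_error(self):
        with pytest.raises(ValueError):
            bt.binned_association_test(
                np.array([0.1, 0.2]), np.array([1.0, 2.0]), bin_edges=(10, 20)
            )

    def test_single_occupied_bin_errors(self):
        with pytest.raises(ValueError):
            bt.binned_association_test(
                np.array([0.05, 0.1, 0.15]), np.array([1.0, 2.0, 3.0])
            )

    def test_rejects_on_correlated_fixture_and_calibrated_under_null(self):
        from biotext.benchmarks import association_calibration

        p_corr, type1 = association_calibration(seed=0)
        assert p_corr < 0.01
        assert 0.02 <= type1 <= 0.08


def test_pairwise_records_schema(toy_graph):
    records = bt.pairwise_similarity_records(
        ["T:0001", "T:0002", "T:0003"], toy_graph
    )
    assert len(records) == 3
    assert {"id_a", "id_b", "text_sim", "graph_dist", "annotation_sim"} == set(
        records[0]
    )
    assert all(0 <= r["text_sim"] <= 1 for r in records)
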