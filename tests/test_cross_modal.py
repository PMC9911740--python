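"""Modality translators, Eq.-style pairing score, pooling, diffusion features."""

import io

import networkx as nx
import numpy as np
import pytest

import biotext as bt
from biotext.cross_modal import cross_modal_score_matrix, write_predictions
from biotext.encoders import DenseBlock


def identity_translator(dim, d_bio, W=None, seed=0):
    """Translator whose encoder is a fixed identity-ish dense block."""
    block = DenseBlock(dim, dim, seed=seed)
    block.W = np.eye(dim)
    block.b = np.full(dim, 5.0)  # keep ReLU in its linear regime
    if W is None:
        # small projection so scores stay away from logistic saturation
        W = 0.02 * np.random.default_rng(seed).normal(size=(dim, d_bio))
    return bt.ModalityTranslator(
        modality="test", encoder_block=block, W=W, d_bio=d_bio
    )


class TestCrossModalScore:
    def test_zero_projection_gives_half(self):
        t_a = identity_translator(3, 4, W=np.zeros((3, 4)))
        t_b = identity_translator(3, 4, seed=1)
        assert bt.cross_modal_score(t_a, np.ones(3), t_b, np.ones(3)) == 0.5

    def test_symmetric_under_argument_swap(self, rng):
        t_a = identity_translator(3, 4, seed=2)
        t_b = identity_translator(5, 4, seed=3)
        F_a, F_b = rng.normal(size=3), rng.normal(size=5)
        assert bt.cross_modal_score(t_a, F_a, t_b, F_b) == pytest.approx(
            bt.cross_modal_score(t_b, F_b, t_a, F_a), abs=1e-12
        )

    def test_matches_explicit_loop_computation(self, rng):
        t_a = identity_translator(3, 4, seed=4)
        t_b = identity_translator(2, 4, seed=5)
        F_a, F_b = rng.normal(size=3), rng.normal(size=2)
        enc_a = t_a.encoder_block.forward(F_a)[0]
        enc_b = t_b.encoder_block.forward(F_b)[0]
        logit = sum(
            enc_a[i] * t_a.W[i, k] * t_b.W[j, k] * enc_b[j]
            for i in range(3) for j in range(2) for k in range(4)
        )
        assert bt.cross_modal_score(t_a, F_a, t_b, F_b) == pytest.approx(
            1 / (1 + np.exp(-logit)), abs=1e-10
        )

    def test_dimension_mismatch_errors(self, rng):
        t_a = identity_translator(3, 4)
        t_b = identity_translator(3, 5, seed=1)
        with pytest.raises(ValueError):
            bt.cross_modal_score(t_a, np.ones(3), t_b, np.ones(3))


class TestPathwayEmbedding:
    def test_single_gene_identity(self):
        v = np.arange(4.0)
        assert np.array_equal(bt.pathway_embedding([v]), v)

    def test_two_genes_elementwise_sum(self):
        out = bt.pathway_embedding([np.ones(3), 2 * np.ones(3)])
        assert out.tolist() == [3.0, 3.0, 3.0]

    def test_matches_loop_accumulation_and_permutation_invariant(self, rng):
        genes = [rng.normal(size=6) for _ in range(10)]
        acc = np.zeros(6)
        for gvec in genes:
            acc = acc + gvec
        np.testing.assert_allclose(bt.pathway_embedding(genes), acc, atol=1e-12)
        perm = [genes[i] for i in rng.permutation(10)]
        np.testing.assert_allclose(
            bt.pathway_embedding(perm), bt.pathway_embedding(genes), atol=1e-12
        )

    def test_empty_pathway_errors(self):
        with pytest.raises(ValueError):
            bt.pathway_embedding([])


class TestGraphNodeFeatures:
    def test_two_disconnected_cliques_separate(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        nodes, Z = bt.graph_node_features(g, dim=3, seed=0)
        def cos(a, b):
            return Z[a] @ Z[b] / (np.linalg.norm(Z[a]) * np.linalg.norm(Z[b]))
        within = [cos(i, j) for i in range(5) for j in range(i + 1, 5)]
        across = [cos(i, j) for i in range(5) for j in range(5, 10)]
        assert min(within) > max(across)

    def test_isomorphic_relabeling_permutes_embeddings(self):
        g = nx.path_graph(7)
        mapping = {i: 10 + (6 - i) for i in range(7)}
        h = nx.relabel_nodes(g, mapping)
        nodes_g, Z_g = bt.graph_node_features(g, dim=3, seed=0)
        nodes_h, Z_h = bt.graph_node_features(h, dim=3, seed=0)
        pos_h = {n: k for k, n in enumerate(nodes_h)}
        perm = [pos_h[mapping[n]] for n in nodes_g]
        np.testing.assert_allclose(np.abs(Z_g), np.abs(Z_h[perm]), atol=1e-8)

    def test_star_center_distinct_at_dim_one(self):
        g = nx.star_graph(5)
        nodes, Z = bt.graph_node_features(g, dim=1, seed=0)
        center = Z[nodes.index(0), 0]
        leaves = [Z[nodes.index(k), 0] for k in range(1, 6)]
        assert all(abs(center - leaf) > 1e-6 for leaf in leaves)
        np.testing.assert_allclose(leaves, leaves[0], atol=1e-8)

    def test_dim_must_be_below_node_count(self):
        with pytest.raises(ValueError):
            bt.graph_node_features(nx.path_graph(4), dim=4)


class TestRankCandidates:
    def test_exact_match_ranked_first(self, rng):
        q = rng.normal(size=4)
        cands = {"far": -q, "near": 10 * q, "mid": q * 0.1}
        assert bt.rank_candidates(q, cands)[0] == "near"

    def test_reversed_scores_reverse_order(self, rng):
        q = np.ones(3)
        cands = {"a": np.array([3.0, 0, 0]), "b": np.array([2.0, 0, 0]),
                 "c": np.array([1.0, 0, 0])}
        assert bt.rank_candidates(q, cands) == ["a", "b", "c"]
        neg = {k: -v for k, v in cands.items()}
        assert bt.rank_candidates(q, neg) == ["c", "b", "a"]

    def test_agrees_with_full_sort_oracle_and_breaks_ties_by_id(self, rng):
        q = rng.normal(size=5)
        cands = {f"g{i}": rng.normal(size=5) for i in range(20)}
        cands["dup2"] = cands["g0"].copy()
        cands["dup1"] = cands["g0"].copy()
        order = bt.rank_candidates(q, cands)
        scores = {k: float(q @ v) for k, v in cands.items()}
        expected = sorted(cands, key=lambda k: (-scores[k], k))
        assert order == expected

    def test_prediction_tsv_format(self, rng):
        q = np.ones(2)
        buf = io.StringIO()
        write_predictions(buf, "drugX", q, {"g1": np.ones(2), "g2": -np.ones(2)})
        lines = buf.getvalue().strip().splitlines()
        assert lines[0].startswith("drugX\tg1\t")
        assert lines[1].endswith("\t2")


class TestTranslatorModel:
    def test_duplicate_corpus_ids_rejected(self, rng):
        with pytest.raises(ValueError):
            bt.PairedCorpus(["a", "a"], rng.normal(size=(2, 3)), ["x", "y"])

    def test_zero_epochs_identity_on_initial_weights(self, rng):
        corpus = bt.PairedCorpus(
            [f"i{k}" for k in range(8)], rng.normal(size=(8, 4)),
            [f"desc {k}" for k in range(8)],
        )
        enc = bt.HashingEncoder(dim=16, seed=0)
        m = bt.TranslatorModel(corpus, enc)
        t1 = m.fit(bt.TrainConfig(epochs=0, seed=2))
        t2 = m.fit(bt.TrainConfig(epochs=0, seed=2))
        assert np.array_equal(t1.W, t2.W)
        assert not t1.loss_history

    def test_loss_decreases_on_synthetic_corpus(self):
        ca, _, _ = bt.generate_paired_modalities(bt.FixtureSpec(seed=3),
                                                 n_items=60)
        enc = bt.HashingEncoder(dim=128, seed=3)
        t = bt.TranslatorModel(ca, enc).fit(
            bt.TrainConfig(epochs=20, learning_rate=1e-3, seed=3)
        )
        assert t.loss_history[-1] < t.loss_history[0]

    def test_translator_output_dimension_is_d_bio(self, rng):
        corpus = bt.PairedCorpus(
            [f"i{k}" for k in range(8)], rng.normal(size=(8, 4)),
            [f"desc {k}" for k in range(8)],
        )
        enc = bt.HashingEncoder(dim=24, seed=0)
        t = bt.TranslatorModel(corpus, enc).fit(bt.TrainConfig(epochs=1, seed=0))
        assert t.project(rng.normal(size=(5, 4))).shape == (5, 24)
        assert t.d_bio == 24


def test_score_matrix_shape(rng):
    t_a = identity_translator(3, 6, seed=0)
    t_b = identity_translator(4, 6, seed=1)
    S = cross_modal_score_matrix(t_a, rng.normal(size=(7, 3)),
                                 t_b, rng.normal(size=(9, 4)))
    assert S.shape == (7, 9)
    assert ((S > 0) & (S < 1)).all()
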