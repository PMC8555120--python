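import numpy as np
import pytest

from pocketgnn.chem_graph import parse_smiles, MolecularGraph
from pocketgnn.subgraph_vocab import build_vocabulary, index_graph, IndexedGraph
from pocketgnn.gnn_core import (
    BranchParameters, GNNParameters, init_parameters, embed,
    transition_step, readout_average, encode_graph, classify, softmax,
    zero_gradients, loss_and_gradients, forward_pair,
)

from _oracles import random_labeled_graph, permute_graph


def _indexed(smiles: str, r: int = 1):
    g = parse_smiles(smiles)
    vocab = build_vocabulary([g], r)
    return g, vocab, index_graph(g, vocab)


def _params_for(vc, vp, d=4, lc=2, lp=2, seed=0):
    rng = np.random.default_rng(seed)
    return init_parameters(vc.n_vertex, vc.n_edge, vp.n_vertex, vp.n_edge,
                           d, lc, lp, rng)


class TestEmbed:
    def test_lookup_returns_table_rows(self):
        _, vocab, ig = _indexed("CCO")
        params = _params_for(vocab, vocab)
        V, E = embed(ig, params.compound)
        assert V.shape == (3, 4) and E.shape == (2, 4)
        np.testing.assert_array_equal(
            V[0], params.compound.vertex_embeddings[ig.vertex_indices[0]])

    def test_equal_indices_give_equal_vectors(self):
        _, vocab, ig = _indexed("CCCC", r=0)
        params = _params_for(vocab, vocab)
        V, _ = embed(ig, params.compound)
        np.testing.assert_array_equal(V[1], V[2])  # interior carbons share a row

    def test_single_vertex_graph_has_empty_edge_block(self):
        _, vocab, ig = _indexed("C")
        params = _params_for(vocab, vocab)
        V, E = embed(ig, params.compound)
        assert V.shape == (1, 4) and E.shape == (0, 4)

    def test_out_of_bounds_index_is_an_error(self):
        _, vocab, ig = _indexed("CCO")
        params = _params_for(vocab, vocab)
        params.compound.vertex_embeddings = params.compound.vertex_embeddings[:1]
        with pytest.raises(IndexError):
            embed(ig, params.compound)


class TestTransitionStep:
    def test_hand_computed_two_vertex_update(self):
        # d=1, h=(1,2), e=0.5, W=1: both vertices map to relu(h_i + h_j + e)
        h = np.array([[1.0], [2.0]])
        e = np.array([[0.5]])
        adjacency = [[(1, 0)], [(0, 0)]]
        out = transition_step(h, e, adjacency, np.array([[1.0]]))
        np.testing.assert_allclose(out, [[3.5], [3.5]])

    def test_isolated_vertex_with_nonnegative_embedding_is_fixed(self):
        h = np.array([[0.3, 0.0, 1.2]])
        out = transition_step(h, np.empty((0, 3)), [[]], np.eye(3))
        np.testing.assert_array_equal(out, h)

    def test_zero_weights_reduce_to_relu_of_self(self):
        h = np.array([[1.0, -1.0], [2.0, 0.5]])
        e = np.array([[0.1, 0.1]])
        adjacency = [[(1, 0)], [(0, 0)]]
        out = transition_step(h, e, adjacency, np.zeros((2, 2)))
        np.testing.assert_array_equal(out, np.maximum(h, 0))

    def test_shape_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            transition_step(np.ones((2, 3)), np.empty((0, 3)), [[], []],
                            np.eye(2))


class TestReadout:
    def test_mean_of_two_vertices_is_the_midpoint(self):
        out = readout_average(np.array([[0.0, 0.0], [2.0, 2.0]]))
        np.testing.assert_array_equal(out, [1.0, 1.0])

    def test_empty_graph_is_an_error(self):
        with pytest.raises(ValueError):
            readout_average(np.empty((0, 3)))


class TestEncodeGraph:
    def test_zero_layers_is_the_mean_raw_embedding(self):
        _, vocab, ig = _indexed("CCO")
        params = _params_for(vocab, vocab)
        y = encode_graph(ig, params.compound, n_layers=0)
        V, _ = embed(ig, params.compound)
        np.testing.assert_allclose(y, V.mean(axis=0))

    def test_all_zero_embeddings_give_the_zero_vector(self):
        _, vocab, ig = _indexed("CCO")
        params = _params_for(vocab, vocab)
        params.compound.vertex_embeddings[:] = 0
        params.compound.edge_embeddings[:] = 0
        y = encode_graph(ig, params.compound)
        np.testing.assert_array_equal(y, np.zeros(4))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        g = random_labeled_graph(rng, max_vertices=7)
        vocab = build_vocabulary([g], 1)
        params = _params_for(vocab, vocab)
        y0 = encode_graph(index_graph(g, vocab), params.compound)
        for _ in range(20):
            h = permute_graph(g, list(rng.permutation(g.n_vertices)))
            y = encode_graph(index_graph(h, vocab), params.compound)
            assert np.abs(y - y0).max() < 1e-6


class TestClassify:
    def test_zero_head_gives_an_even_split(self):
        _, vc, _ = _indexed("CC")
        params = _params_for(vc, vc)
        params.W_output[:] = 0
        params.b_output[:] = 0
        z, p_active = classify(np.ones(4), np.ones(4), params)
        np.testing.assert_array_equal(z, [0.0, 0.0])
        assert p_active == pytest.approx(0.5)

    def test_softmax_closed_form(self):
        p = softmax(np.array([0.0, np.log(3.0)]))
        np.testing.assert_allclose(p, [0.25, 0.75])

    def test_concatenation_order_matters(self):
        _, vc, _ = _indexed("CC")
        params = _params_for(vc, vc, seed=5)
        y1, y2 = np.ones(4), -np.ones(4)
        z12, _ = classify(y1, y2, params)
        z21, _ = classify(y2, y1, params)
        assert not np.allclose(z12, z21)

    def test_dimension_mismatch_is_an_error(self):
        _, vc, _ = _indexed("CC")
        params = _params_for(vc, vc)
        with pytest.raises(ValueError):
            classify(np.ones(3), np.ones(4), params)

    def test_softmax_is_a_distribution_for_random_logits(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = softmax(rng.normal(scale=5, size=2))
            assert p.sum() == pytest.approx(1.0)
            assert (p > 0).all() and (p < 1).all()


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        """Central finite differences on every parameter entry, d=2, L=1."""
        g1 = parse_smiles("CCO")
        g2 = parse_smiles("CCN")
        vc = build_vocabulary([g1], 1)
        vp = build_vocabulary([g2], 1)
        rng = np.random.default_rng(0)
        params = init_parameters(vc.n_vertex, vc.n_edge, vp.n_vertex,
                                 vp.n_edge, 2, 1, 1, rng)
        ig1, ig2 = index_graph(g1, vc), index_graph(g2, vp)
        _, grads, _ = loss_and_gradients(ig1, ig2, 1, params)
        eps = 1e-6
        worst = 0.0
        for name, arr in params.named_arrays():
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + eps
                lp, _, _ = loss_and_gradients(ig1, ig2, 1, params,
                                              zero_gradients(params))
                arr[idx] = orig - eps
                lm, _, _ = loss_and_gradients(ig1, ig2, 1, params,
                                              zero_gradients(params))
                arr[idx] = orig
                fd = (lp - lm) / (2 * eps)
                an = grads[name][idx]
                denom = max(abs(fd), abs(an), 1e-8)
                worst = max(worst, abs(fd - an) / denom)
        assert worst < 1e-4

    def test_full_forward_pass_is_permutation_invariant(self):
        rng = np.random.default_rng(4)
        g1 = random_labeled_graph(rng, max_vertices=7)
        g2 = random_labeled_graph(rng, max_vertices=7)
        vc, vp = build_vocabulary([g1], 1), build_vocabulary([g2], 1)
        params = _params_for(vc, vp, seed=1)
        p0 = forward_pair(index_graph(g1, vc), index_graph(g2, vp), params)
        for _ in range(20):
            h1 = permute_graph(g1, list(rng.permutation(g1.n_vertices)))
            h2 = permute_graph(g2, list(rng.permutation(g2.n_vertices)))
            p = forward_pair(index_graph(h1, vc), index_graph(h2, vp), params)
            assert abs(p - p0) < 1e-6
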