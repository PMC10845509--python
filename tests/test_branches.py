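"""Branch encoders: manual-forward oracles, invariances, parameter counts."""

import numpy as np
import pytest

from dtiagg import autograd as ag
from dtiagg.aggregation import DotHead, TensorHead
from dtiagg.branches import (CNNBranch, EmbeddingBranch, MLPBranch,
                             MPNNBranch, MPNNFCBranch, batch_graphs,
                             count_parameters)
from dtiagg.featurization import MolecularGraph, smiles_to_graph

RNG = np.random.default_rng(7)


class TestMLPBranch:
    def test_zero_weights_give_zero_embedding(self):
        b = MLPBranch(4, 3, hidden=[5], seed=0)
        for W, bias in b.layers:
            W.data[:] = 0
            bias.data[:] = 0
        out = b.forward(RNG.standard_normal((6, 4)))
        assert np.allclose(out.data, 0)

    def test_identity_configuration(self):
        b = MLPBranch(3, 3, hidden=[], activation="linear", seed=0)
        b.layers[0][0].data = np.eye(3)
        b.layers[0][1].data[:] = 0
        x = RNG.standard_normal((4, 3))
        assert np.allclose(b.forward(x).data, x)

    def test_matches_manual_forward(self):
        b = MLPBranch(5, 2, hidden=[7, 4], activation="relu", seed=3)
        x = RNG.standard_normal((8, 5))
        h = x
        for i, (W, bias) in enumerate(b.layers):
            h = h @ W.data + bias.data
            if i < len(b.layers) - 1:
                h = np.maximum(h, 0)
        assert np.allclose(b.forward(x).data, h)

    def test_shape_mismatch_raises(self):
        b = MLPBranch(5, 2, seed=0)
        with pytest.raises(ValueError, match="width"):
            b.forward(np.zeros((3, 4)))


class TestEmbeddingBranch:
    def test_row_selection_plus_bias(self):
        b = EmbeddingBranch(4, 2, seed=0)
        b.table.data = np.arange(8.0).reshape(4, 2)
        b.bias.data = np.array([0.5, -0.5])
        out = b.forward([2, 0])
        assert np.allclose(out.data, [[4.5, 4.5], [0.5, 0.5]])

    def test_zero_weights_return_bias(self):
        b = EmbeddingBranch(3, 2, seed=0)
        b.table.data[:] = 0
        b.bias.data = np.array([1.0, 2.0])
        assert np.allclose(b.forward([1]).data, [[1.0, 2.0]])

    def test_distinct_rows_give_distinct_embeddings(self):
        b = EmbeddingBranch(5, 3, seed=1)
        out = b.forward([0, 3]).data
        assert not np.allclose(out[0], out[1])

    def test_out_of_range_index(self):
        b = EmbeddingBranch(3, 2, seed=0)
        with pytest.raises(ValueError, match="out of range"):
            b.forward([3])


class TestCNNBranch:
    def test_zero_weights_give_zero(self):
        b = CNNBranch(vocab_size=5, max_len=10, embedding_dim=4, seed=0)
        b.proj_W.data[:] = 0
        b.proj_b.data[:] = 0
        out = b.forward(RNG.integers(0, 6, size=(3, 10)))
        assert np.allclose(out.data, 0)

    def test_output_width_is_embedding_dim(self):
        b = CNNBranch(vocab_size=9, max_len=12, embedding_dim=6, seed=2)
        out = b.forward(RNG.integers(0, 10, size=(4, 12)))
        assert out.shape == (4, 6)

    def test_width1_sum_pool_equals_token_embedding_sum(self):
        # single width-1 filter with weight 1, linear activation, sum pooling
        b = CNNBranch(vocab_size=4, max_len=6, embedding_dim=1, token_dim=1,
                      channels=[1], kernel_size=1, pooling="sum",
                      activation="linear", seed=0)
        b.convs[0][0].data[:] = 1.0
        b.convs[0][1].data[:] = 0.0
        b.proj_W.data[:] = 1.0
        b.proj_b.data[:] = 0.0
        tokens = np.array([[1, 2, 3, 0, 0, 0]])
        expected = b.table.data[tokens[0]].sum()
        assert b.forward(tokens).data[0, 0] == pytest.approx(expected)

    def test_receptive_field_configuration_error(self):
        with pytest.raises(ValueError, match="receptive"):
            CNNBranch(vocab_size=5, max_len=3, embedding_dim=4,
                      channels=[8, 8, 8], kernel_size=3)


def _random_graph(rng, n_atoms=6, feat_dim=18, bond_dim=5):
    feats = rng.standard_normal((n_atoms, feat_dim))
    bonds = []
    for i in range(1, n_atoms):
        bonds.append((rng.integers(0, i), i))  # random tree: connected
    bonds = np.array(bonds, dtype=np.intp)
    bfeats = rng.standard_normal((len(bonds), bond_dim))
    return MolecularGraph(atom_features=feats, bonds=bonds, bond_features=bfeats)


def _permute_graph(g, perm):
    inv = np.argsort(perm)
    return MolecularGraph(atom_features=g.atom_features[perm],
                          bonds=inv[g.bonds], bond_features=g.bond_features)


class TestMPNNBranch:
    def test_single_atom_graph_messages_vacuous(self):
        g = MolecularGraph(atom_features=np.ones((1, 18)),
                           bonds=np.zeros((0, 2), dtype=np.intp),
                           bond_features=np.zeros((0, 5)))
        b = MPNNBranch(18, 5, embedding_dim=3, hidden_dim=4, n_rounds=2, seed=0)
        out = b.forward(batch_graphs([g]))
        # manual: h0 = relu(x W_in + b); rounds update without messages
        h = np.maximum(np.ones((1, 18)) @ b.W_in.data + b.b_in.data, 0)
        for W_msg, W_self, bias in b.rounds:
            h = np.maximum(h @ W_self.data + bias.data, 0)
        expected = h @ b.out_W.data + b.out_b.data
        assert np.allclose(out.data, expected)

    def test_two_atom_path_matches_hand_computation(self):
        g = MolecularGraph(atom_features=np.array([[1.0, 0.0], [0.0, 1.0]]),
                           bonds=np.array([[0, 1]], dtype=np.intp),
                           bond_features=np.array([[2.0]]))
        b = MPNNBranch(2, 1, embedding_dim=1, hidden_dim=2, n_rounds=1,
                       activation="linear", seed=0)
        b.W_in.data = np.array([[1.0, 0.0], [0.0, 1.0]])
        b.b_in.data[:] = 0
        W_msg, W_self, bias = b.rounds[0]
        W_msg.data = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
        W_self.data = np.eye(2)
        bias.data[:] = 0
        b.out_W.data = np.array([[1.0], [1.0]])
        b.out_b.data[:] = 0
        # h0 = I; messages: atom0 -> atom1 carries [1,0,2]Wm = [2,1];
        # atom1 -> atom0 carries [0,1,2]Wm = [1,2]; update h = h + msg
        h1 = np.array([[1.0 + 1.0, 0.0 + 2.0], [0.0 + 2.0, 1.0 + 1.0]])
        expected = h1.sum()  # sum readout then all-ones projection
        assert b.forward(batch_graphs([g])).data[0, 0] == pytest.approx(expected)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        g = _random_graph(rng)
        perm = rng.permutation(g.n_atoms)
        b = MPNNBranch(18, 5, embedding_dim=4, hidden_dim=8, n_rounds=3,
                       seed=seed)
        out1 = b.forward(batch_graphs([g])).data
        out2 = b.forward(batch_graphs([_permute_graph(g, perm)])).data
        assert np.allclose(out1, out2, atol=1e-10)

    def test_batched_equals_single(self):
        graphs = [smiles_to_graph(s) for s in ("CCO", "C1CCCC1", "NCCN")]
        b = MPNNBranch(18, 5, embedding_dim=4, seed=5)
        batched = b.forward(batch_graphs(graphs)).data
        singles = np.vstack([b.forward(batch_graphs([g])).data for g in graphs])
        assert np.allclose(batched, singles)


class TestMPNNFCBranch:
    def test_empty_fc_stack_equals_bare_mpnn(self):
        fc = MPNNFCBranch(18, 5, embedding_dim=4, n_rounds=2, fc_hidden=[], seed=9)
        bare = MPNNBranch(18, 5, embedding_dim=4, n_rounds=2, seed=9)
        batch = batch_graphs([smiles_to_graph("CCOC")])
        assert np.allclose(fc.forward(batch).data, bare.forward(batch).data)

    def test_fc_layers_add_capacity(self):
        bare = MPNNBranch(18, 5, embedding_dim=4, n_rounds=2, seed=0)
        fc = MPNNFCBranch(18, 5, embedding_dim=4, n_rounds=2,
                          fc_hidden=[16], seed=0)
        assert count_parameters(fc) > count_parameters(bare)

    def test_zero_fc_weights_give_zero_embedding(self):
        fc = MPNNFCBranch(18, 5, embedding_dim=3, n_rounds=1, fc_hidden=[8], seed=0)
        fc.fc[-1][0].data[:] = 0
        fc.fc[-1][1].data[:] = 0
        out = fc.forward(batch_graphs([smiles_to_graph("CCN")]))
        assert np.allclose(out.data, 0)


class TestEmbeddingDimContract:
    @pytest.mark.parametrize("make", [
        lambda d: (MLPBranch(6, d, hidden=[4], seed=0),
                   RNG.standard_normal((3, 6))),
        lambda d: (EmbeddingBranch(5, d, seed=0), np.array([0, 2, 4])),
        lambda d: (CNNBranch(5, 10, d, seed=0),
                   RNG.integers(0, 6, size=(3, 10))),
        lambda d: (MPNNBranch(18, 5, d, seed=0),
                   batch_graphs([smiles_to_graph(s) for s in ("CCO", "CN", "C")])),
        lambda d: (MPNNFCBranch(18, 5, d, seed=0),
                   batch_graphs([smiles_to_graph(s) for s in ("CCO", "CN", "C")])),
    ])
    @pytest.mark.parametrize("d", [1, 7])
    def test_output_width_always_d(self, make, d):
        branch, inputs = make(d)
        assert branch.forward(inputs).shape == (3, d)


class TestCountParameters:
    def test_mlp_4_3_1_is_19(self):
        assert count_parameters(MLPBranch(4, 1, hidden=[3], seed=0)) == 19

    def test_embedding_10_entities_dim8_with_bias_is_88(self):
        assert count_parameters(EmbeddingBranch(10, 8, seed=0)) == 88

    def test_dot_head_has_zero_tensor_head_d1d2(self):
        assert count_parameters(DotHead(4, 4)) == 0
        assert count_parameters(TensorHead(3, 5)) == 15
        assert count_parameters(TensorHead(3, 5, use_bias=True)) == 16

    def test_determinism_of_forwards(self):
        b = CNNBranch(5, 10, 4, seed=3)
        tokens = RNG.integers(0, 6, size=(2, 10))
        assert np.array_equal(b.forward(tokens).data, b.forward(tokens).data)
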