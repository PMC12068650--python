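import numpy as np
import pytest
from oracles import oracle_encode

from hmgcl import (attach_drug_view, attach_element_view, build_molecule_view,
                   featurize)
from hmgcl.autodiff import Tensor
from hmgcl.encoder import (EncoderConfig, EncoderParams, EncoderSchemaError,
                           GraphIndex, attention_messages, encode, init_state,
                           readout, update_state)
from hmgcl.fixtures import MOLECULE_TEMPLATES
from conftest import random_typed_graph


def mol_view(smiles):
    return featurize(build_molecule_view(smiles))


class TestInitState:
    def test_zero_inputs_give_bias_free_projection(self, enc_cfg):
        """With zero features, positions and biases, h_v = 0 and
        h_e = beta @ B (linearity of the init map)."""
        g = random_typed_graph(seed=0)
        params = EncoderParams.init(enc_cfg, seed=0)
        for n in g.nodes:
            n.alpha = np.zeros_like(n.alpha)
            n.lam = np.zeros_like(n.lam)
        for name in ("init.node_bias", "init.pos_bias", "init.edge_bias"):
            params.params[name].data[:] = 0.0
        st = init_state(g, params)
        np.testing.assert_allclose(st.h_v.data, 0.0, atol=1e-12)
        for j, e in enumerate(g.edges):
            expect = e.beta @ params.params[f"init.edge.{e.etype}"].data
            np.testing.assert_allclose(st.h_e.data[j], expect, atol=1e-12)

    def test_directed_pair_difference_is_node_difference(self, enc_params):
        """h_eij - h_eji = h_vi - h_vj at initialization (shared beta)."""
        g = mol_view("CCO")
        st = init_state(g, enc_params)
        nid = {n.id: i for i, n in enumerate(g.nodes)}
        eid = {(e.src, e.dst, e.etype): j for j, e in enumerate(g.edges)}
        for e in g.edges:
            fwd = st.h_e.data[eid[(e.src, e.dst, e.etype)]]
            rev = st.h_e.data[eid[(e.dst, e.src, e.etype)]]
            np.testing.assert_allclose(
                fwd - rev,
                st.h_v.data[nid[e.src]] - st.h_v.data[nid[e.dst]],
                atol=1e-10)

    def test_directed_edge_states_differ(self, enc_params):
        """A heteroatom bond separates the two edge directions."""
        g = mol_view("CO")
        st = init_state(g, enc_params)
        gaps = []
        eid = {(e.src, e.dst, e.etype): j for j, e in enumerate(g.edges)}
        for e in g.edges:
            rev = eid[(e.dst, e.src, e.etype)]
            gaps.append(np.abs(st.h_e.data[eid[(e.src, e.dst, e.etype)]]
                               - st.h_e.data[rev]).max())
        assert max(gaps) > 1e-3

    def test_missing_type_raises_schema_error(self, enc_cfg):
        g = mol_view("CCO")
        params = EncoderParams.init(enc_cfg, seed=0)
        del params.params["init.node.atom"]
        with pytest.raises(EncoderSchemaError):
            init_state(g, params)


class TestAttention:
    def test_rows_sum_to_one(self, enc_params):
        g = mol_view("CC(=O)OC")
        gi = GraphIndex.build(g)
        st = init_state(gi, enc_params)
        collected = []
        attention_messages(st, gi, enc_params, layer=1,
                           collect_attention=collected)
        for p in collected:
            sums = p.sum(axis=1)
            has = sums > 1e-9
            np.testing.assert_allclose(sums[has], 1.0, atol=1e-6)

    def test_isolated_node_gets_zero_message(self, enc_cfg):
        from hmgcl.graph import HMGraph, Node
        from hmgcl.molview import NODE_FEATURE_DIMS, POS_DIM
        g = HMGraph("M")
        rng = np.random.default_rng(0)
        for i in range(3):
            g.add_node(Node(f"n{i}", "atom",
                            alpha=rng.standard_normal(NODE_FEATURE_DIMS["atom"]),
                            lam=np.zeros(POS_DIM)))
        g.add_edge_pair("n0", "n1", "bond",
                        beta=rng.standard_normal(6))
        params = EncoderParams.init(enc_cfg, seed=1)
        gi = GraphIndex.build(g)
        st = init_state(gi, params)
        m_v, _ = attention_messages(st, gi, params, layer=1)
        np.testing.assert_allclose(m_v.data[2], 0.0, atol=1e-12)

    def test_single_source_receives_mixed_value(self, enc_cfg):
        """A singleton source set means softmax weight 1: the node message
        equals that edge's value vector passed through the output mix."""
        from hmgcl.graph import HMGraph, Node
        from hmgcl.molview import NODE_FEATURE_DIMS, POS_DIM
        params = EncoderParams.init(EncoderConfig(d=8, heads=1, layers=1,
                                                  d_kg=16), seed=2)
        g = HMGraph("M")
        rng = np.random.default_rng(3)
        for i in range(2):
            g.add_node(Node(f"n{i}", "atom",
                            alpha=rng.standard_normal(NODE_FEATURE_DIMS["atom"]),
                            lam=np.zeros(POS_DIM)))
        g.add_edge_pair("n0", "n1", "bond", beta=rng.standard_normal(6))
        gi = GraphIndex.build(g)
        st = init_state(gi, params)
        m_v, _ = attention_messages(st, gi, params, layer=1)
        P = {k: t.data for k, t in params.params.items()}
        for i, incoming in ((0, 1), (1, 0)):  # edge j->i is the only source
            v = (st.h_e.data[incoming] @ P["attn.v.1.0"]
                 @ P["unify.edge.bond"]) @ P["mix.node"]
            np.testing.assert_allclose(m_v.data[i], v, atol=1e-10)


class TestUpdate:
    def test_identity_passthrough_construction(self, enc_cfg):
        """W = [I; 0] on nonnegative states reproduces h^{l-1}."""
        g = mol_view("CCO")
        params = EncoderParams.init(enc_cfg, seed=0)
        d = enc_cfg.d
        eye = np.vstack([np.eye(d), np.zeros((d, d))])
        for t in ("atom", "fragment"):
            params.params[f"update.1.node.{t}"].data[:] = eye
        for t in ("bond", "join", "reaction"):
            params.params[f"update.1.edge.{t}"].data[:] = eye
        gi = GraphIndex.build(g)
        st = init_state(gi, params)
        st.h_v = Tensor(np.abs(st.h_v.data))
        st.h_e = Tensor(np.abs(st.h_e.data))
        msgs = attention_messages(st, gi, params, layer=1)
        new = update_state(st, msgs, gi, params, layer=1)
        np.testing.assert_allclose(new.h_v.data, st.h_v.data, atol=1e-10)
        np.testing.assert_allclose(new.h_e.data, st.h_e.data, atol=1e-10)

    def test_leak_slope_on_negative_preactivations(self, enc_cfg):
        g = mol_view("CCO")
        params = EncoderParams.init(enc_cfg, seed=0)
        d = enc_cfg.d
        neg_eye = np.vstack([-np.eye(d), np.zeros((d, d))])
        for t in ("atom", "fragment"):
            params.params[f"update.1.node.{t}"].data[:] = neg_eye
        for t in ("bond", "join", "reaction"):
            params.params[f"update.1.edge.{t}"].data[:] = neg_eye
        gi = GraphIndex.build(g)
        st = init_state(gi, params)
        st.h_v = Tensor(np.abs(st.h_v.data) + 0.1)
        st.h_e = Tensor(np.abs(st.h_e.data) + 0.1)
        msgs = attention_messages(st, gi, params, layer=1)
        new = update_state(st, msgs, gi, params, layer=1)
        np.testing.assert_allclose(new.h_v.data, -0.01 * st.h_v.data,
                                   atol=1e-10)


class TestEncodeOracle:
    def test_random_graphs_match_dense_oracle(self, enc_cfg):
        """>=20 random small graphs: full pipeline vs independent loops."""
        worst = 0.0
        for seed in range(20):
            g = random_typed_graph(seed=seed,
                                   n_nodes=int(3 + seed % 6))
            params = EncoderParams.init(enc_cfg, seed=100 + seed)
            got = encode(g, params).vector
            want = oracle_encode(g, params)
            worst = max(worst, float(np.abs(got - want).max()))
        assert worst < 1e-5

    def test_molecule_views_match_oracle(self, ekg, dkg, enc_params):
        g = mol_view("CC(=O)OC")
        for graph in (g, attach_element_view(g, ekg),
                      attach_drug_view(g, "drug_0", dkg)):
            got = encode(graph, enc_params).vector
            want = oracle_encode(graph, enc_params)
            np.testing.assert_allclose(got, want, atol=1e-6)

    def test_zero_layers_reads_out_initial_state(self, ekg):
        cfg = EncoderConfig(d=16, heads=2, layers=0, d_kg=16)
        params = EncoderParams.init(cfg, seed=5)
        g = mol_view("CCO")
        emb = encode(g, params)
        want = oracle_encode(g, params)
        np.testing.assert_allclose(emb.vector, want, atol=1e-8)


class TestEncodeProperties:
    def test_permutation_invariance(self, enc_params):
        g = mol_view("CC(=O)Oc1ccccc1")
        h1 = encode(g, enc_params).vector
        rng = np.random.default_rng(0)
        g2 = g.copy()
        order = rng.permutation(len(g2.nodes))
        g2.nodes = [g2.nodes[i] for i in order]
        eorder = rng.permutation(len(g2.edges))
        g2.edges = [g2.edges[i] for i in eorder]
        h2 = encode(g2, enc_params).vector
        np.testing.assert_allclose(h1, h2, atol=1e-6)

    def test_single_type_reduces_to_plain_attention(self):
        """Identity unifying transforms collapse the typed projection to
        standard Q/K/V."""
        cfg = EncoderConfig(d=8, heads=2, layers=1, d_kg=16)
        params = EncoderParams.init(cfg, seed=3)
        for name, t in list(params.params.items()):
            if name.startswith("unify."):
                t.data[:] = np.eye(cfg.d_head)
        g = random_typed_graph(seed=1, node_types=("atom",),
                               edge_types=("bond",))
        gi = GraphIndex.build(g)
        st = init_state(gi, params)
        m_v, _ = attention_messages(st, gi, params, layer=1)
        # plain computation without any type machinery
        P = {k: t.data for k, t in params.params.items()}
        heads = []
        for k in range(cfg.heads):
            q = st.h_v.data @ P[f"attn.q.1.{k}"]
            kk = st.h_e.data @ P[f"attn.k.1.{k}"]
            vv = st.h_e.data @ P[f"attn.v.1.{k}"]
            scores = q @ kk.T / np.sqrt(cfg.d / cfg.heads)
            mask = gi.node_mask
            e = np.exp(scores - scores.max(axis=1, keepdims=True)) * mask
            p = e / np.maximum(e.sum(axis=1, keepdims=True), 1e-300)
            heads.append(p @ vv)
        want = np.concatenate(heads, axis=1) @ P["mix.node"]
        np.testing.assert_allclose(m_v.data, want, atol=1e-8)

    @pytest.mark.parametrize("smiles", MOLECULE_TEMPLATES)
    def test_all_outputs_finite_on_fixture_molecules(self, smiles, ekg,
                                                     enc_params):
        g = attach_element_view(mol_view(smiles), ekg)
        emb = encode(g, enc_params)
        assert np.all(np.isfinite(emb.vector))

    def test_finite_over_many_parameter_draws(self, ekg):
        cfg = EncoderConfig(d=8, heads=2, layers=2, d_kg=16)
        g = attach_element_view(mol_view("CC(=O)OC"), ekg)
        for seed in range(100):
            params = EncoderParams.init(cfg, seed=seed)
            assert np.all(np.isfinite(encode(g, params).vector))

    def test_pooled_weights_sum_to_one(self, enc_params):
        emb = encode(mol_view("c1ccccc1"), enc_params)
        assert np.isclose(emb.pool_weights.sum(), 1.0, atol=1e-6)
        kept = emb.pool_weights > 0
        assert kept.sum() == int(np.ceil(0.5 * len(emb.pool_weights)))

    def test_empty_graph_rejected(self, enc_params):
        from hmgcl.graph import HMGraph
        with pytest.raises(ValueError):
            encode(HMGraph("M"), enc_params)


class TestCheckpoint:
    def test_round_trip(self, enc_params, tmp_path):
        from hmgcl.encoder import load_checkpoint, save_checkpoint
        path = tmp_path / "ckpt.json"
        save_checkpoint(enc_params, path)
        loaded, extra = load_checkpoint(path)
        assert loaded.cfg == enc_params.cfg
        assert extra == {}
        g = mol_view("CCO")
        np.testing.assert_allclose(encode(g, enc_params).vector,
                                   encode(g, loaded).vector, atol=1e-12)
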