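import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from hmgcl import (ContrastiveConfig, PredictorHead, build_view_batch, encode,
                   export_attention, finetune, gen_molecule_pool, make_batches,
                   predict_ddi, predict_property, pretrain, pretrain_step,
                   project, total_loss)
from hmgcl.autodiff import Tensor
from hmgcl.contrastive import ProjectedBatch, init_projector
from hmgcl.encoder import EncoderConfig, EncoderParams
from hmgcl.fixtures import MOLECULE_TEMPLATES, MoleculeRecord
from hmgcl.tasks import build_graph_views


@pytest.fixture(scope="module")
def view_batch(ekg, dkg):
    records = [MoleculeRecord(s, rid=f"m{i}")
               for i, s in enumerate(MOLECULE_TEMPLATES[:7])]
    for j, rec in enumerate(records[-3:]):
        rec.drug_id = f"drug_{j}"
    return build_view_batch(records, ekg, dkg)


class TestBuildViewBatch:
    def test_counts_and_alignment(self, view_batch):
        assert (view_batch.n, view_batch.m) == (7, 3)
        assert len(view_batch.elem_views) == 7

    def test_element_view_contains_molecule_view(self, view_batch):
        for gm, gem in zip(view_batch.mol_views, view_batch.elem_views):
            assert len(gem.nodes) >= len(gm.nodes)
            assert len(gem.edges) >= len(gm.edges)

    def test_non_trailing_drug_positions_rejected(self, ekg, dkg):
        records = [MoleculeRecord("CCO", drug_id="drug_0", rid="a"),
                   MoleculeRecord("CCN", rid="b")]
        with pytest.raises(ValueError):
            build_view_batch(records, ekg, dkg)

    def test_all_non_drug_batch_warns(self, ekg, dkg, caplog):
        import logging
        records = [MoleculeRecord("CCO"), MoleculeRecord("CCN")]
        with caplog.at_level(logging.WARNING):
            vb = build_view_batch(records, ekg, dkg)
        assert vb.m == 0 and "no drug records" in caplog.text


class TestPretrainStep:
    def test_loss_matches_compositional_route(self, view_batch, enc_cfg):
        """pretrain_step equals encode -> project -> total_loss done by hand."""
        params = EncoderParams.init(enc_cfg, seed=0)
        cfg = ContrastiveConfig(temperature=0.1)
        proj = init_projector(enc_cfg.d, cfg, seed=1)
        value, log = pretrain_step(view_batch, params, proj, cfg)

        def rows(graphs):
            return Tensor(np.stack([encode(g, params).vector for g in graphs]))
        pb = ProjectedBatch(project(rows(view_batch.mol_views), proj, cfg),
                            project(rows(view_batch.elem_views), proj, cfg),
                            project(rows(view_batch.drug_views), proj, cfg))
        want, _ = total_loss(pb, cfg)
        np.testing.assert_allclose(value, float(want.data), atol=1e-9)
        assert set(log) >= {"loss_m_em", "loss_m_dm", "loss_em_dm"}

    def test_deterministic_under_seed(self, pool, ekg, dkg, enc_cfg):
        vals = []
        for _ in range(2):
            res = pretrain(pool, ekg, dkg, enc_cfg,
                           ContrastiveConfig(temperature=0.1),
                           batch_size=10, complement_size=1, steps=2,
                           lr=1e-3, seed=7)
            vals.append([h["loss_total"] for h in res.history])
        np.testing.assert_allclose(vals[0], vals[1], atol=1e-7)

    def test_loss_decreases_over_training(self, pool, ekg, dkg, enc_cfg):
        res = pretrain(pool, ekg, dkg, enc_cfg,
                       ContrastiveConfig(temperature=0.1),
                       batch_size=10, complement_size=1, steps=12,
                       lr=3e-3, seed=0)
        assert res.history[-1]["loss_total"] < res.history[0]["loss_total"]


class TestPredictors:
    def test_property_matches_manual_composition(self, enc_params):
        g = build_graph_views("CC(=O)OC")["M"]
        head = PredictorHead.init(enc_params.cfg.d, seed=3)
        got = predict_property(g, enc_params, head)
        want = head.forward(Tensor(encode(g, enc_params).vector
                                   .reshape(1, -1))).data[0]
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_zero_weight_head_outputs_bias(self, enc_params):
        g = build_graph_views("CCO")["M"]
        head = PredictorHead.init(enc_params.cfg.d, seed=0)
        head.params["head.w1"].data[:] = 0.0
        head.params["head.b1"].data[:] = 0.75
        np.testing.assert_allclose(predict_property(g, enc_params, head),
                                   [0.75], atol=1e-12)

    def test_permuted_atoms_same_prediction(self, enc_params):
        head = PredictorHead.init(enc_params.cfg.d, seed=1)
        g = build_graph_views("Cc1ccccc1")["M"]
        g2 = g.copy()
        order = np.random.default_rng(0).permutation(len(g2.nodes))
        g2.nodes = [g2.nodes[i] for i in order]
        np.testing.assert_allclose(predict_property(g, enc_params, head),
                                   predict_property(g2, enc_params, head),
                                   atol=1e-6)

    def test_ddi_is_order_sensitive(self, enc_params):
        d = enc_params.cfg.d
        head = PredictorHead.init(2 * d, seed=2)
        # a head reading only the difference of the two halves
        head.params["head.w0"].data[:d] = np.eye(d, head.params["head.w0"]
                                                 .data.shape[1])
        head.params["head.w0"].data[d:] = -np.eye(d, head.params["head.w0"]
                                                  .data.shape[1])
        head.params["head.b0"].data[:] = 0.0
        g1 = build_graph_views("CCO")["M"]
        g2 = build_graph_views("c1ccccc1")["M"]
        ab = predict_ddi(g1, g2, enc_params, head)
        ba = predict_ddi(g2, g1, enc_params, head)
        assert np.abs(ab - ba).max() > 1e-8
        aa = predict_ddi(g1, g1, enc_params, head)
        # difference head on identical graphs sees zero input -> tanh(0)=0
        want = head.params["head.b1"].data
        np.testing.assert_allclose(aa, want, atol=1e-10)

    def test_ddi_matches_manual_composition(self, enc_params):
        head = PredictorHead.init(2 * enc_params.cfg.d, seed=4)
        g1 = build_graph_views("CC#N")["M"]
        g2 = build_graph_views("CCN")["M"]
        got = predict_ddi(g1, g2, enc_params, head)
        pair = np.concatenate([encode(g1, enc_params).vector,
                               encode(g2, enc_params).vector]).reshape(1, -1)
        want = head.forward(Tensor(pair)).data[0]
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_width_mismatch_rejected(self, enc_params):
        g = build_graph_views("CCO")["M"]
        bad = PredictorHead.init(enc_params.cfg.d + 1, seed=0)
        with pytest.raises(ValueError):
            predict_property(g, enc_params, bad)
        with pytest.raises(ValueError):
            predict_ddi(g, g, enc_params, bad)


class TestExportAttention:
    def test_per_type_normalization(self, ekg, enc_params):
        g = build_graph_views("CC(=O)OC", ekg)["EM"]
        weights = export_attention(g, enc_params)
        for ntype, w in weights.items():
            total = sum(w.values())
            assert total == pytest.approx(1.0, abs=1e-6) or total == 0.0

    def test_deterministic(self, enc_params):
        g = build_graph_views("c1ccccc1")["M"]
        a = export_attention(g, enc_params)
        b = export_attention(g, enc_params)
        assert a == b

    def test_dropped_units_zero_weight(self, enc_params):
        g = build_graph_views("CC(=O)Oc1ccccc1")["M"]
        emb = encode(g, enc_params)
        dropped = set(np.nonzero(emb.pool_weights == 0)[0])
        assert dropped  # pooling with r=0.5 drops about half the units
        weights = export_attention(g, enc_params)
        flat = {k: v for w in weights.values() for k, v in w.items()}
        for i, (uid, kind) in enumerate(zip(emb.unit_ids, emb.unit_kinds)):
            if kind == "node" and i in dropped:
                assert flat[uid] == 0.0


class TestFinetune:
    def _nitrogen_dataset(self):
        smiles = list(MOLECULE_TEMPLATES)
        labels = [sum(1 for a in Chem.MolFromSmiles(s).GetAtoms()
                      if a.GetSymbol() == "N") for s in smiles]
        return pd.DataFrame({"smiles": smiles, "label": labels})

    def test_nitrogen_count_regression_learns(self, enc_cfg):
        """Label = #N atoms (oracle-computable); frozen-encoder fit reaches
        train RMSE < 0.5 within 200 epochs."""
        params = EncoderParams.init(enc_cfg, seed=0)
        res = finetune(self._nitrogen_dataset(), params, epochs=200, lr=1e-2,
                       seed=0)
        assert res.train_metric < 0.5

    def test_frozen_mode_keeps_encoder_fixed(self, enc_cfg):
        params = EncoderParams.init(enc_cfg, seed=0)
        before = {k: v.data.copy() for k, v in params.params.items()
                  if not k.startswith("readout.")}
        finetune(self._nitrogen_dataset().head(5), params, epochs=3, seed=0)
        for k, v in before.items():
            np.testing.assert_array_equal(v, params.params[k].data)

    def test_unfrozen_mode_moves_encoder(self, enc_cfg):
        params = EncoderParams.init(enc_cfg, seed=0)
        before = params.params["mix.node"].data.copy()
        finetune(self._nitrogen_dataset().head(4), params, epochs=2,
                 freeze_encoder=False, seed=0)
        assert np.abs(before - params.params["mix.node"].data).max() > 0

    def test_seeded_reproducibility(self, enc_cfg):
        metrics = []
        for _ in range(2):
            params = EncoderParams.init(enc_cfg, seed=0)
            res = finetune(self._nitrogen_dataset().head(6), params,
                           epochs=20, seed=5)
            metrics.append(res.train_metric)
        assert metrics[0] == pytest.approx(metrics[1], abs=1e-6)

    def test_ddi_task_binary_labels(self, enc_cfg):
        params = EncoderParams.init(enc_cfg, seed=0)
        df = pd.DataFrame({
            "smiles": ["CCO", "c1ccccc1", "CC#N", "CCN"],
            "smiles2": ["CCN", "CC#N", "c1ccccc1", "CCO"],
            "label": [1, 0, 1, 0]})
        res = finetune(df, params, task="ddi", kind="binary", epochs=30,
                       seed=0)
        assert np.isfinite(res.train_metric)

    def test_schema_errors(self, enc_cfg):
        params = EncoderParams.init(enc_cfg, seed=0)
        with pytest.raises(ValueError):
            finetune(pd.DataFrame({"smiles": ["CCO"]}), params)
        with pytest.raises(ValueError):
            finetune(pd.DataFrame({"smiles": ["(("], "label": [1.0]}), params)


class TestAlignmentLearning:
    def test_cross_view_alignment_improves(self, ekg, dkg, enc_cfg):
        """Pre-training pulls a molecule's own element view closer than
        other molecules' element views (the objective's alignment)."""
        pool = gen_molecule_pool(28, 0.4, dkg, seed=9)
        res = pretrain(pool, ekg, dkg, enc_cfg,
                       ContrastiveConfig(temperature=0.1),
                       batch_size=10, complement_size=1, steps=40,
                       lr=3e-3, seed=1)
        batch = res.plan.batches[0]
        vb = build_view_batch(batch, ekg, dkg)
        z_m = np.stack([encode(g, res.enc_params).vector
                        for g in vb.mol_views])
        z_em = np.stack([encode(g, res.enc_params).vector
                         for g in vb.elem_views])
        z_m /= np.linalg.norm(z_m, axis=1, keepdims=True)
        z_em /= np.linalg.norm(z_em, axis=1, keepdims=True)
        sims = z_m @ z_em.T
        own = np.diag(sims)
        other = (sims.sum(axis=1) - own) / (sims.shape[1] - 1)
        assert (own > other).mean() >= 0.5
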