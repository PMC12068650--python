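"""Training orchestration: contrastive pre-training and fine-tuning heads.

Pre-training encodes each batch molecule in up to three views with one
shared encoder parameter set, projects the pooled embeddings, and descends
the cross-view contrastive loss.  Fine-tuning discards the projector and
puts a fresh task head (and a freshly initialized pooling scorer) on top of
the molecule-view encoder: a property predictor reads one graph embedding,
the drug–drug-interaction predictor reads the order-sensitive concatenation
of two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .autodiff import Adam, Tensor, concat, parameter, stack_rows
from .batcher import BatchPlan, make_batches
from .contrastive import (ContrastiveConfig, ProjectedBatch, init_projector,
                          project, total_loss)
from .encoder import EncoderConfig, EncoderParams, encode
from .fixtures import DrugKG, ElementKG, MoleculeRecord
from .graph import HMGraph
from .kgviews import attach_drug_view, attach_element_view
from .molview import build_molecule_view, featurize

logger = logging.getLogger(__name__)


@dataclass
class ViewBatch:
    mol_views: list[HMGraph]      # length N
    elem_views: list[HMGraph]     # length N
    drug_views: list[HMGraph]     # length M = #drug records, last M positions
    record_ids: list[str | None]

    @property
    def n(self) -> int:
        return len(self.mol_views)

    @property
    def m(self) -> int:
        return len(self.drug_views)


def build_graph_views(smiles: str, ekg: ElementKG | None = None,
                      drug_id: str | None = None, dkg: DrugKG | None = None
                      ) -> dict[str, HMGraph]:
    """Featurized views of one molecule; EM/DM only where inputs allow."""
    gm = featurize(build_molecule_view(smiles))
    out = {"M": gm}
    if ekg is not None:
        out["EM"] = attach_element_view(gm, ekg)
    if drug_id is not None:
        if dkg is None:
            raise ValueError("drug view requested without a drug KG")
        out["DM"] = attach_drug_view(gm, drug_id, dkg)
    return out


def build_view_batch(records: list[MoleculeRecord], ekg: ElementKG,
                     dkg: DrugKG) -> ViewBatch:
    """Assemble the aligned three-view sets for one batch.

    Drug records must occupy the trailing positions (the batcher guarantees
    this); a batch without any drug record is assembled with a warning and
    an empty drug-view list.
    """
    n_drug = sum(r.drug_id is not None for r in records)
    if n_drug and any(r.drug_id is None for r in records[-n_drug:]):
        raise ValueError("drug records must occupy the trailing batch positions")
    if n_drug == 0:
        logger.warning("batch has no drug records; drug view will be empty")
    mol_views, elem_views, drug_views = [], [], []
    for rec in records:
        try:
            views = build_graph_views(rec.smiles, ekg, rec.drug_id, dkg)
        except Exception as exc:
            raise RuntimeError(
                f"view construction failed for record {rec.rid!r} "
                f"({rec.smiles!r}): {exc}") from exc
        mol_views.append(views["M"])
        elem_views.append(views["EM"])
        if rec.drug_id is not None:
            drug_views.append(views["DM"])
    return ViewBatch(mol_views, elem_views, drug_views,
                     [r.rid for r in records])


def _encode_rows(graphs: list[HMGraph], params: EncoderParams) -> Tensor:
    return stack_rows([encode(g, params).h for g in graphs])


def pretrain_step(batch: ViewBatch, enc_params: EncoderParams,
                  proj_params: dict[str, Tensor], cfg: ContrastiveConfig,
                  optimizer: Adam | None = None
                  ) -> tuple[float, dict[str, float]]:
    """One contrastive step; updates parameters in place when an optimizer
    is supplied, otherwise only evaluates the loss."""
    h_m = _encode_rows(batch.mol_views, enc_params)
    h_em = _encode_rows(batch.elem_views, enc_params)
    if batch.m:
        h_dm = _encode_rows(batch.drug_views, enc_params)
    else:
        h_dm = Tensor(np.zeros((0, enc_params.cfg.d)))
    pb = ProjectedBatch(project(h_m, proj_params, cfg),
                        project(h_em, proj_params, cfg),
                        project(h_dm, proj_params, cfg) if batch.m
                        else Tensor(np.zeros((0, enc_params.cfg.d))))
    loss, log = total_loss(pb, cfg)
    if optimizer is not None:
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
    return float(loss.data), log


@dataclass
class PretrainResult:
    enc_params: EncoderParams
    proj_params: dict[str, Tensor]
    plan: BatchPlan
    history: list[dict[str, float]] = field(default_factory=list)


def pretrain(records: list[MoleculeRecord], ekg: ElementKG, dkg: DrugKG,
             enc_cfg: EncoderConfig, con_cfg: ContrastiveConfig,
             batch_size: int, complement_size: int, steps: int,
             lr: float = 1e-3, seed: int = 0) -> PretrainResult:
    """Full pre-training loop on a molecule pool (cycling over batches)."""
    s_m = [r for r in records if r.drug_id is None]
    s_d = [r for r in records if r.drug_id is not None]
    plan = make_batches(s_m, s_d, batch_size, complement_size, seed)
    view_batches = [build_view_batch(b, ekg, dkg) for b in plan.batches]

    enc_params = EncoderParams.init(enc_cfg, seed=seed)
    proj_params = init_projector(enc_cfg.d, con_cfg, seed=seed + 1)
    opt = Adam({**enc_params.params, **proj_params}, lr=lr)
    history = []
    for step in range(steps):
        vb = view_batches[step % len(view_batches)]
        value, log = pretrain_step(vb, enc_params, proj_params, con_cfg, opt)
        log["step"] = step
        history.append(log)
    return PretrainResult(enc_params, proj_params, plan, history)


# ---------------------------------------------------------------------------
# predictor heads

@dataclass
class PredictorHead:
    """2-layer MLP head mapping d (property) or 2d (DDI) to task outputs."""
    params: dict[str, Tensor]
    d_in: int
    d_out: int
    kind: str = "regression"        # regression | binary | multilabel

    @classmethod
    def init(cls, d_in: int, d_out: int = 1, hidden: int = 32,
             kind: str = "regression", seed: int = 0) -> "PredictorHead":
        rng = np.random.default_rng(seed)
        p = {
            "head.w0": parameter(rng, (d_in, hidden)),
            "head.b0": parameter(rng, (hidden,), fan_in=d_in),
            "head.w1": parameter(rng, (hidden, d_out)),
            "head.b1": parameter(rng, (d_out,), fan_in=hidden),
        }
        return cls(p, d_in, d_out, kind)

    def forward(self, x: Tensor) -> Tensor:
        h = (x @ self.params["head.w0"] + self.params["head.b0"]).tanh()
        return h @ self.params["head.w1"] + self.params["head.b1"]


def predict_property(g: HMGraph, enc_params: EncoderParams,
                     head: PredictorHead) -> np.ndarray:
    """Molecule-view property prediction (logits for classification heads)."""
    if head.d_in != enc_params.cfg.d:
        raise ValueError(f"head expects width {head.d_in}, "
                         f"encoder emits {enc_params.cfg.d}")
    h = encode(g, enc_params).h
    return head.forward(h.reshape(1, -1)).data[0]


def predict_ddi(g1: HMGraph, g2: HMGraph, enc_params: EncoderParams,
                head: PredictorHead) -> np.ndarray:
    """Drug–drug interaction from the ordered concatenation [h(g1), h(g2)]."""
    if head.d_in != 2 * enc_params.cfg.d:
        raise ValueError(f"head expects width {head.d_in}, "
                         f"pair embedding has {2 * enc_params.cfg.d}")
    h1 = encode(g1, enc_params).h
    h2 = encode(g2, enc_params).h
    pair = concat([h1.reshape(1, -1), h2.reshape(1, -1)], axis=1)
    return head.forward(pair).data[0]


def export_attention(g: HMGraph, enc_params: EncoderParams
                     ) -> dict[str, dict[str, float]]:
    """Final-pooling attention weights per node, normalized within node type.

    Units dropped by the pooling step receive weight 0; within each node
    type with any retained unit the weights sum to 1.
    """
    emb = encode(g, enc_params)
    out: dict[str, dict[str, float]] = {}
    for uid, kind, utype, w in zip(emb.unit_ids, emb.unit_kinds,
                                   emb.unit_types, emb.pool_weights):
        if kind != "node":
            continue
        out.setdefault(utype, {})[uid] = float(w)
    for utype, weights in out.items():
        total = sum(weights.values())
        if total > 0:
            out[utype] = {k: v / total for k, v in weights.items()}
    return out


# ---------------------------------------------------------------------------
# fine-tuning

@dataclass
class FinetuneResult:
    head: PredictorHead
    enc_params: EncoderParams
    history: list[dict[str, float]]
    train_metric: float       # RMSE (regression) or mean CE (classification)


def _task_loss(pred: Tensor, y: np.ndarray, kind: str) -> Tensor:
    t = Tensor(y)
    if kind == "regression":
        diff = pred - t
        return (diff * diff).sum() * (1.0 / y.size)
    # binary / multilabel: sigmoid cross-entropy on logits, stable form:
    # max(x,0) - x*y + log(1+exp(-|x|))
    x = pred
    relu_x = x.relu()
    absx = (x * x) ** 0.5
    return ((relu_x - x * t + (1.0 + (-absx).exp()).log()).sum()
            * (1.0 / y.size))


def finetune(dataset: pd.DataFrame, enc_params: EncoderParams,
             task: str = "property", kind: str = "regression",
             epochs: int = 200, lr: float = 1e-2, hidden: int = 32,
             freeze_encoder: bool = True, seed: int = 0,
             reset_pooling: bool = True) -> FinetuneResult:
    """Fit a task head (optionally the encoder too) on a labelled CSV table.

    ``dataset`` needs a ``smiles`` column (plus ``smiles2`` for DDI) and a
    ``label`` column.  The pre-training projector plays no role here; by
    default the pooling scorer is re-initialized for the task and only the
    head is trained (the encoder stays frozen).
    """
    for col in (["smiles", "label"] + (["smiles2"] if task == "ddi" else [])):
        if col not in dataset.columns:
            raise ValueError(f"dataset lacks required column {col!r}")
    for s in list(dataset["smiles"]) + (
            list(dataset["smiles2"]) if task == "ddi" else []):
        if Chem.MolFromSmiles(s) is None:
            raise ValueError(f"invalid SMILES in dataset: {s!r}")

    if reset_pooling:
        enc_params.reset_readout(seed)
    d = enc_params.cfg.d
    d_in = 2 * d if task == "ddi" else d
    y = np.asarray(dataset["label"], dtype=float).reshape(len(dataset), -1)
    head = PredictorHead.init(d_in, d_out=y.shape[1], hidden=hidden,
                              kind=kind, seed=seed)

    graphs = [featurize(build_molecule_view(s)) for s in dataset["smiles"]]
    graphs2 = ([featurize(build_molecule_view(s)) for s in dataset["smiles2"]]
               if task == "ddi" else None)

    trainable = dict(head.params)
    if not freeze_encoder:
        trainable.update(enc_params.params)
    opt = Adam(trainable, lr=lr)

    def embed() -> Tensor:
        rows = [encode(g, enc_params).h for g in graphs]
        if graphs2 is not None:
            rows2 = [encode(g, enc_params).h for g in graphs2]
            return concat([stack_rows(rows), stack_rows(rows2)], axis=1)
        return stack_rows(rows)

    # standardize embedding features (pooled embeddings are small in scale);
    # moments are fixed from the initial pass so they act as constants
    x0 = embed().data
    mu = x0.mean(axis=0, keepdims=True)
    sd = x0.std(axis=0, keepdims=True) + 1e-8

    def standardize(x: Tensor) -> Tensor:
        return (x - Tensor(mu)) * Tensor(1.0 / sd)

    x_frozen = standardize(Tensor(x0)) if freeze_encoder else None
    history = []
    for epoch in range(epochs):
        x = x_frozen if freeze_encoder else standardize(embed())
        loss = _task_loss(head.forward(x), y, kind)
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append({"epoch": epoch, "loss": float(loss.data)})

    x = x_frozen if freeze_encoder else standardize(Tensor(embed().data))
    pred = head.forward(x).data
    if kind == "regression":
        metric = float(np.sqrt(np.mean((pred - y) ** 2)))
    else:
        p = 1.0 / (1.0 + np.exp(-pred))
        eps = 1e-12
        metric = float(-np.mean(y * np.log(p + eps)
                                + (1 - y) * np.log(1 - p + eps)))
    return FinetuneResult(head, enc_params, history, metric)
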