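"""Dual node–edge message-passing graph-transformer encoder.

Per layer, every node aggregates messages from its incoming directed edges
and every directed edge aggregates from its source node and that node's
incoming edges (the reverse edge included), all through multi-head
attention in which queries come from the receiver and keys/values from the
senders.  Heterogeneity is handled by type-specific input projections and
by per-type "unifying" transforms applied after the shared per-head Q/K/V
maps, so all node and edge types meet in one feature space.  Updates are
synchronous: all messages of layer ``l`` are computed from layer ``l-1``
state before any embedding changes.  The readout is self-attention graph
pooling over the union of final node and directed-edge embeddings.

Initial embeddings are type-specific affine maps of the raw features, plus
a learned projection of the positional vector for nodes; each directed
edge additionally absorbs its *source* node's initial embedding, which is
what makes the two directions of a chemical bond distinct.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, parameter
from .graph import HMGraph
from .molview import EDGE_FEATURE_DIMS, NODE_FEATURE_DIMS, POS_DIM

LEAK_SLOPE = 0.01


class EncoderSchemaError(KeyError):
    """A node/edge type in the graph has no parameters."""


@dataclass
class EncoderConfig:
    d: int = 16            # hidden width
    heads: int = 2         # attention heads K
    layers: int = 2        # message-passing rounds L
    pool_ratio: float = 0.5
    pos_dim: int = POS_DIM
    d_kg: int = 16         # drug-KG embedding width (dnode raw feature)

    def __post_init__(self) -> None:
        if self.d % self.heads != 0:
            raise ValueError(f"d={self.d} not divisible by heads={self.heads}")

    @property
    def d_head(self) -> int:
        return self.d // self.heads


def default_feature_dims(cfg: EncoderConfig) -> tuple[dict, dict]:
    node_dims = dict(NODE_FEATURE_DIMS)
    node_dims["dnode"] = cfg.d_kg
    return node_dims, dict(EDGE_FEATURE_DIMS)


class EncoderParams:
    """All learnable tensors of the encoder, addressable by name.

    Naming scheme: ``init.node.<type>``, ``init.edge.<type>``,
    ``attn.{q,k,v}.<layer>.<head>``, ``unify.{node,edge}.<type>``,
    ``mix.{node,edge}``, ``update.<layer>.{node,edge}.<type>``,
    ``readout.{w,b}``.
    """

    def __init__(self, cfg: EncoderConfig, node_dims: dict[str, int],
                 edge_dims: dict[str, int], params: dict[str, Tensor]):
        self.cfg = cfg
        self.node_dims = dict(node_dims)
        self.edge_dims = dict(edge_dims)
        self.params = params

    @classmethod
    def init(cls, cfg: EncoderConfig, seed: int,
             node_dims: dict[str, int] | None = None,
             edge_dims: dict[str, int] | None = None) -> "EncoderParams":
        if node_dims is None or edge_dims is None:
            nd, ed = default_feature_dims(cfg)
            node_dims = node_dims or nd
            edge_dims = edge_dims or ed
        rng = np.random.default_rng(seed)
        d, dh = cfg.d, cfg.d_head
        p: dict[str, Tensor] = {}
        for t, dv in node_dims.items():
            p[f"init.node.{t}"] = parameter(rng, (dv, d))
        p["init.node_bias"] = parameter(rng, (d,), fan_in=d)
        p["init.pos"] = parameter(rng, (cfg.pos_dim, d))
        p["init.pos_bias"] = parameter(rng, (d,), fan_in=d)
        for t, de in edge_dims.items():
            p[f"init.edge.{t}"] = parameter(rng, (de, d))
        p["init.edge_bias"] = parameter(rng, (d,), fan_in=d)
        for l in range(1, cfg.layers + 1):
            for k in range(cfg.heads):
                for role in ("q", "k", "v"):
                    p[f"attn.{role}.{l}.{k}"] = parameter(rng, (d, dh))
            for t in node_dims:
                p[f"update.{l}.node.{t}"] = parameter(rng, (2 * d, d))
            for t in edge_dims:
                p[f"update.{l}.edge.{t}"] = parameter(rng, (2 * d, d))
        for t in node_dims:
            p[f"unify.node.{t}"] = parameter(rng, (dh, dh))
        for t in edge_dims:
            p[f"unify.edge.{t}"] = parameter(rng, (dh, dh))
        p["mix.node"] = parameter(rng, (d, d))
        p["mix.edge"] = parameter(rng, (d, d))
        cls._init_readout(p, rng, d)
        return cls(cfg, node_dims, edge_dims, p)

    @staticmethod
    def _init_readout(p: dict[str, Tensor], rng: np.random.Generator,
                      d: int) -> None:
        p["readout.w"] = parameter(rng, (d, 1))
        p["readout.b"] = parameter(rng, (1,), fan_in=d)

    def reset_readout(self, seed: int) -> None:
        """Fresh pooling scorer (used when fine-tuning rebuilds the readout)."""
        self._init_readout(self.params, np.random.default_rng(seed), self.cfg.d)

    def __getitem__(self, name: str) -> Tensor:
        try:
            return self.params[name]
        except KeyError:
            raise EncoderSchemaError(
                f"no parameter {name!r}; type missing from encoder schema")

    def schema_hash(self) -> str:
        payload = json.dumps({"node": self.node_dims, "edge": self.edge_dims,
                              "d": self.cfg.d, "pos": self.cfg.pos_dim},
                             sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# graph indexing

@dataclass
class GraphIndex:
    """Precomputed constant index structures for one graph."""
    n: int
    m: int
    node_groups: list[tuple[str, np.ndarray]]
    edge_groups: list[tuple[str, np.ndarray]]
    node_perm: np.ndarray
    node_inv: np.ndarray
    edge_perm: np.ndarray
    edge_inv: np.ndarray
    alpha: dict[str, np.ndarray]     # per-type stacked raw node features
    beta: dict[str, np.ndarray]
    lam: np.ndarray                  # n × pos_dim
    src: np.ndarray                  # per-edge source node index
    node_mask: np.ndarray            # n × m   (incoming edges per node)
    edge_mask: np.ndarray            # m × (n+m)  (source node + its in-edges)

    @classmethod
    def build(cls, g: HMGraph) -> "GraphIndex":
        if not g.nodes:
            raise ValueError("cannot index an empty graph")
        nidx = {node.id: i for i, node in enumerate(g.nodes)}
        n, m = len(g.nodes), len(g.edges)

        def _groups(items, typeof):
            by: dict[str, list[int]] = {}
            for i, it in enumerate(items):
                by.setdefault(typeof(it), []).append(i)
            return [(t, np.asarray(by[t])) for t in sorted(by)]

        node_groups = _groups(g.nodes, lambda x: x.ntype)
        edge_groups = _groups(g.edges, lambda x: x.etype)
        node_perm = (np.concatenate([ix for _, ix in node_groups])
                     if node_groups else np.zeros(0, dtype=int))
        edge_perm = (np.concatenate([ix for _, ix in edge_groups])
                     if m else np.zeros(0, dtype=int))
        node_inv = np.empty(n, dtype=int)
        node_inv[node_perm] = np.arange(n)
        edge_inv = np.empty(m, dtype=int)
        edge_inv[edge_perm] = np.arange(m)

        alpha = {t: np.stack([g.nodes[i].alpha for i in ix])
                 for t, ix in node_groups}
        beta = {t: np.stack([g.edges[i].beta for i in ix])
                for t, ix in edge_groups}
        lam = np.stack([node.lam for node in g.nodes])

        src = np.asarray([nidx[e.src] for e in g.edges], dtype=int)
        dst = np.asarray([nidx[e.dst] for e in g.edges], dtype=int)
        node_mask = np.zeros((n, m))
        node_mask[dst, np.arange(m)] = 1.0
        edge_mask = np.zeros((m, n + m))
        edge_mask[np.arange(m), src] = 1.0
        if m:
            # sender edges e_p with dst(e_p) == src(e)
            edge_mask[:, n:] = (dst[None, :] == src[:, None]).astype(float)
        return cls(n, m, node_groups, edge_groups, node_perm, node_inv,
                   edge_perm, edge_inv, alpha, beta, lam, src,
                   node_mask, edge_mask)


def _typed(x: Tensor, groups, perm, inv, weights: dict[str, Tensor]) -> Tensor:
    """Apply a per-type matrix to row blocks of ``x`` grouped by type."""
    grouped = x.gather_rows(perm)
    # slice via gather on the grouped tensor to keep the autodiff tape intact
    out_chunks, lo = [], 0
    for t, ix in groups:
        hi = lo + len(ix)
        out_chunks.append(grouped.gather_rows(np.arange(lo, hi)) @ weights[t])
        lo = hi
    return concat(out_chunks, axis=0).gather_rows(inv)


@dataclass
class EncoderState:
    h_v: Tensor     # n × d
    h_e: Tensor     # m × d
    layer: int = 0


def init_state(g: HMGraph | GraphIndex, params: EncoderParams) -> EncoderState:
    """Initial embeddings: typed feature projection + positional term; each
    directed edge absorbs its source node's initial embedding."""
    gi = g if isinstance(g, GraphIndex) else GraphIndex.build(g)
    d = params.cfg.d
    node_chunks = []
    for t, ix in gi.node_groups:
        node_chunks.append(Tensor(gi.alpha[t]) @ params[f"init.node.{t}"])
    h_v = (concat(node_chunks, axis=0).gather_rows(gi.node_inv)
           + params["init.node_bias"]
           + Tensor(gi.lam) @ params["init.pos"] + params["init.pos_bias"])
    if gi.m:
        edge_chunks = []
        for t, ix in gi.edge_groups:
            edge_chunks.append(Tensor(gi.beta[t]) @ params[f"init.edge.{t}"])
        h_e = (concat(edge_chunks, axis=0).gather_rows(gi.edge_inv)
               + params["init.edge_bias"] + h_v.gather_rows(gi.src))
    else:
        h_e = Tensor(np.zeros((0, d)))
    return EncoderState(h_v, h_e, layer=0)


def _masked_attention(q: Tensor, kk: Tensor, vv: Tensor, mask: np.ndarray,
                      scale: float,
                      collect: list | None = None) -> Tensor:
    """Per-receiver softmax attention restricted to ``mask``; empty source
    sets yield zero messages."""
    scores = (q @ kk.T) * (1.0 / scale)
    neg = np.where(mask > 0, scores.data, -np.inf)
    rowmax = np.max(neg, axis=1, keepdims=True, initial=-np.inf)
    has = (mask.sum(axis=1, keepdims=True) > 0)
    rowmax = np.where(has, rowmax, 0.0)
    a = (scores - Tensor(rowmax)).exp() * Tensor(mask)
    denom = a.sum(axis=1, keepdims=True) + Tensor((~has).astype(float))
    p = a / denom
    if collect is not None:
        collect.append(p.data.copy())
    return p @ vv


def attention_messages(state: EncoderState, g: HMGraph | GraphIndex,
                       params: EncoderParams, layer: int,
                       collect_attention: list | None = None
                       ) -> tuple[Tensor, Tensor]:
    """Multi-head messages for all nodes and directed edges at ``layer``."""
    gi = g if isinstance(g, GraphIndex) else GraphIndex.build(g)
    cfg = params.cfg
    scale = np.sqrt(cfg.d / cfg.heads)
    unify_n = {t: params[f"unify.node.{t}"] for t, _ in gi.node_groups}
    unify_e = {t: params[f"unify.edge.{t}"] for t, _ in gi.edge_groups}

    def node_typed(x):
        return _typed(x, gi.node_groups, gi.node_perm, gi.node_inv, unify_n)

    def edge_typed(x):
        return _typed(x, gi.edge_groups, gi.edge_perm, gi.edge_inv, unify_e)

    node_heads, edge_heads = [], []
    for k in range(cfg.heads):
        wq = params[f"attn.q.{layer}.{k}"]
        wk = params[f"attn.k.{layer}.{k}"]
        wv = params[f"attn.v.{layer}.{k}"]
        qn = node_typed(state.h_v @ wq)
        kn = node_typed(state.h_v @ wk)
        vn = node_typed(state.h_v @ wv)
        if gi.m:
            qe = edge_typed(state.h_e @ wq)
            ke = edge_typed(state.h_e @ wk)
            ve = edge_typed(state.h_e @ wv)
        else:
            qe = ke = ve = Tensor(np.zeros((0, cfg.d_head)))
        node_heads.append(_masked_attention(qn, ke, ve, gi.node_mask, scale,
                                            collect_attention))
        ks = concat([kn, ke], axis=0)
        vs = concat([vn, ve], axis=0)
        edge_heads.append(_masked_attention(qe, ks, vs, gi.edge_mask, scale,
                                            collect_attention))
    m_v = concat(node_heads, axis=1) @ params["mix.node"]
    m_e = concat(edge_heads, axis=1) @ params["mix.edge"]
    return m_v, m_e


def update_state(state: EncoderState, messages: tuple[Tensor, Tensor],
                 g: HMGraph | GraphIndex, params: EncoderParams,
                 layer: int) -> EncoderState:
    """h^l = LeakyReLU([h^{l-1} ‖ m^l] W) with the receiver's type-specific W."""
    gi = g if isinstance(g, GraphIndex) else GraphIndex.build(g)
    m_v, m_e = messages
    up_n = {t: params[f"update.{layer}.node.{t}"] for t, _ in gi.node_groups}
    h_v = _typed(concat([state.h_v, m_v], axis=1),
                 gi.node_groups, gi.node_perm, gi.node_inv,
                 up_n).leaky_relu(LEAK_SLOPE)
    if gi.m:
        up_e = {t: params[f"update.{layer}.edge.{t}"]
                for t, _ in gi.edge_groups}
        h_e = _typed(concat([state.h_e, m_e], axis=1),
                     gi.edge_groups, gi.edge_perm, gi.edge_inv,
                     up_e).leaky_relu(LEAK_SLOPE)
    else:
        h_e = state.h_e
    return EncoderState(h_v, h_e, layer=layer)


@dataclass
class GraphEmbedding:
    h: Tensor                        # pooled graph embedding, shape (d,)
    unit_ids: list[str]              # node ids then directed-edge ids
    unit_kinds: list[str]            # "node" | "edge" per unit
    unit_types: list[str]
    pool_weights: np.ndarray         # attention weight per unit (0 if dropped)
    scores: np.ndarray               # raw scorer output per unit
    kept: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    @property
    def vector(self) -> np.ndarray:
        return self.h.data


def _pool_order(scores: np.ndarray, units: np.ndarray,
                kinds: list[str], types: list[str]) -> list[int]:
    """Descending score; ties broken by score then a relabeling-invariant
    canonical key (kind, type, rounded embedding) so pooling is stable
    under node reordering."""
    keys = []
    for i in range(len(scores)):
        emb_key = tuple(np.round(units[i], 9))
        keys.append((-scores[i], kinds[i], types[i], emb_key))
    return sorted(range(len(scores)), key=lambda i: keys[i])


def readout(state: EncoderState, g: HMGraph, params: EncoderParams,
            pool_ratio: float | None = None) -> GraphEmbedding:
    """Self-attention graph pooling over final node ∪ edge embeddings."""
    r = params.cfg.pool_ratio if pool_ratio is None else pool_ratio
    units = concat([state.h_v, state.h_e], axis=0)
    s = (units @ params["readout.w"] + params["readout.b"]).tanh()
    total = units.shape[0]
    keep = int(np.ceil(r * total))
    kinds = (["node"] * state.h_v.shape[0]) + (["edge"] * state.h_e.shape[0])
    types = [n.ntype for n in g.nodes] + [e.etype for e in g.edges]
    order = _pool_order(s.data[:, 0], units.data, kinds, types)
    kept = np.asarray(sorted(order[:keep]), dtype=int)

    s_kept = s.gather_rows(kept)
    mx = float(np.max(s_kept.data))
    ex = (s_kept - Tensor(mx)).exp()
    a = ex / ex.sum()
    h = (a * s_kept * units.gather_rows(kept)).sum(axis=0)

    weights = np.zeros(total)
    weights[kept] = a.data[:, 0]
    ids = [n.id for n in g.nodes] + [e.id for e in g.edges]
    return GraphEmbedding(h, ids, kinds, types, weights, s.data[:, 0], kept)


def encode(g: HMGraph, params: EncoderParams,
           pool_ratio: float | None = None) -> GraphEmbedding:
    """Full pipeline: init, L synchronous dual message-passing rounds, pooling."""
    gi = GraphIndex.build(g)
    state = init_state(gi, params)
    for layer in range(1, params.cfg.layers + 1):
        messages = attention_messages(state, gi, params, layer)
        state = update_state(state, messages, gi, params, layer)
    return readout(state, g, params, pool_ratio)


# ---------------------------------------------------------------------------
# checkpointing (JSON archive: header + named arrays)

CHECKPOINT_VERSION = "1"


def save_checkpoint(params: EncoderParams, path,
                    extra: dict[str, Tensor] | None = None) -> None:
    payload = {
        "header": {
            "version": CHECKPOINT_VERSION,
            "d": params.cfg.d, "heads": params.cfg.heads,
            "layers": params.cfg.layers, "pool_ratio": params.cfg.pool_ratio,
            "pos_dim": params.cfg.pos_dim, "d_kg": params.cfg.d_kg,
            "node_dims": params.node_dims, "edge_dims": params.edge_dims,
            "schema_hash": params.schema_hash(),
        },
        "params": {k: v.data.tolist() for k, v in params.params.items()},
        "extra": {k: v.data.tolist() for k, v in (extra or {}).items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path) -> tuple[EncoderParams, dict[str, Tensor]]:
    with open(path) as fh:
        payload = json.load(fh)
    hdr = payload["header"]
    if hdr.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {hdr.get('version')!r}")
    cfg = EncoderConfig(d=hdr["d"], heads=hdr["heads"], layers=hdr["layers"],
                        pool_ratio=hdr["pool_ratio"], pos_dim=hdr["pos_dim"],
                        d_kg=hdr["d_kg"])
    params = {k: Tensor(np.asarray(v), requires_grad=True)
              for k, v in payload["params"].items()}
    extra = {k: Tensor(np.asarray(v), requires_grad=True)
             for k, v in payload.get("extra", {}).items()}
    return EncoderParams(cfg, hdr["node_dims"], hdr["edge_dims"], params), extra
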