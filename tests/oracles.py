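"""Independent brute-force oracles used to cross-check the implementation.

These re-derive the encoder forward pass and the contrastive loss with
explicit per-receiver / per-term loops and plain NumPy — no shared code
with the package's vectorized, autodiff-based implementations.
"""

from __future__ import annotations

import math

import numpy as np


def _softmax(xs: list[float]) -> list[float]:
    mx = max(xs)
    es = [math.exp(x - mx) for x in xs]
    s = sum(es)
    return [e / s for e in es]


def oracle_encode(g, params, return_state: bool = False):
    """Loop-based dense re-implementation of the full encoder pipeline."""
    P = {k: np.asarray(t.data, dtype=float) for k, t in params.params.items()}
    cfg = params.cfg
    d, K, L = cfg.d, cfg.heads, cfg.layers
    scale = math.sqrt(d / K)
    nodes, edges = g.nodes, g.edges
    nid = {n.id: i for i, n in enumerate(nodes)}

    hv = [np.asarray(n.alpha) @ P[f"init.node.{n.ntype}"]
          + P["init.node_bias"]
          + np.asarray(n.lam) @ P["init.pos"] + P["init.pos_bias"]
          for n in nodes]
    he = [np.asarray(e.beta) @ P[f"init.edge.{e.etype}"]
          + P["init.edge_bias"] + hv[nid[e.src]] for e in edges]

    for l in range(1, L + 1):
        mv, me = [], []
        for i, n in enumerate(nodes):
            heads = []
            for k in range(K):
                q = hv[i] @ P[f"attn.q.{l}.{k}"] @ P[f"unify.node.{n.ntype}"]
                senders = [j for j, e in enumerate(edges) if nid[e.dst] == i]
                if not senders:
                    heads.append(np.zeros(d // K))
                    continue
                ks = [he[j] @ P[f"attn.k.{l}.{k}"]
                      @ P[f"unify.edge.{edges[j].etype}"] for j in senders]
                vs = [he[j] @ P[f"attn.v.{l}.{k}"]
                      @ P[f"unify.edge.{edges[j].etype}"] for j in senders]
                w = _softmax([float(q @ kk) / scale for kk in ks])
                heads.append(sum(wi * vi for wi, vi in zip(w, vs)))
            mv.append(np.concatenate(heads) @ P["mix.node"])
        for j, e in enumerate(edges):
            s = nid[e.src]
            heads = []
            for k in range(K):
                q = he[j] @ P[f"attn.q.{l}.{k}"] @ P[f"unify.edge.{e.etype}"]
                ks = [hv[s] @ P[f"attn.k.{l}.{k}"]
                      @ P[f"unify.node.{nodes[s].ntype}"]]
                vs = [hv[s] @ P[f"attn.v.{l}.{k}"]
                      @ P[f"unify.node.{nodes[s].ntype}"]]
                for f, ef in enumerate(edges):
                    if nid[ef.dst] == s:
                        ks.append(he[f] @ P[f"attn.k.{l}.{k}"]
                                  @ P[f"unify.edge.{ef.etype}"])
                        vs.append(he[f] @ P[f"attn.v.{l}.{k}"]
                                  @ P[f"unify.edge.{ef.etype}"])
                w = _softmax([float(q @ kk) / scale for kk in ks])
                heads.append(sum(wi * vi for wi, vi in zip(w, vs)))
            me.append(np.concatenate(heads) @ P["mix.edge"])

        def leaky(x):
            return np.where(x >= 0, x, 0.01 * x)

        hv = [leaky(np.concatenate([hv[i], mv[i]])
                    @ P[f"update.{l}.node.{n.ntype}"])
              for i, n in enumerate(nodes)]
        he = [leaky(np.concatenate([he[j], me[j]])
                    @ P[f"update.{l}.edge.{e.etype}"])
              for j, e in enumerate(edges)]

    units = hv + he
    scores = [float(np.tanh(u @ P["readout.w"] + P["readout.b"])[0])
              for u in units]
    keep = math.ceil(cfg.pool_ratio * len(units))
    order = sorted(range(len(units)), key=lambda i: -scores[i])[:keep]
    w = _softmax([scores[i] for i in order])
    h_g = sum(wi * scores[i] * units[i] for wi, i in zip(w, order))
    if return_state:
        return h_g, hv, he
    return h_g


def oracle_pair_loss(z1: np.ndarray, z2: np.ndarray, i: int,
                     tau: float) -> float:
    """Literal term-by-term InfoNCE denominator enumeration."""
    m1, m2 = len(z1), len(z2)
    mmin = min(m1, m2)
    ai, pi = m1 - mmin + i, m2 - mmin + i
    pos = math.exp(float(z1[ai] @ z2[pi]) / tau)
    denom = 0.0
    for j in range(m1):
        if j != ai:
            denom += math.exp(float(z1[ai] @ z1[j]) / tau)
    for j in range(m2):
        if j != pi:
            denom += math.exp(float(z1[ai] @ z2[j]) / tau)
    return -math.log(pos / denom)


def oracle_total_loss(z_m, z_em, z_dm, tau: float) -> float:
    total = 0.0
    for a, b in ((z_m, z_em), (z_m, z_dm), (z_em, z_dm)):
        mmin = min(len(a), len(b))
        if mmin == 0:
            continue
        s = sum(oracle_pair_loss(a, b, i, tau) for i in range(mmin))
        s += sum(oracle_pair_loss(b, a, i, tau) for i in range(mmin))
        total += s / mmin
    return total


def oracle_pair_term_count(m1: int, m2: int) -> int:
    """Number of exponential terms in the directed denominator."""
    return (m1 - 1) + (m2 - 1)
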