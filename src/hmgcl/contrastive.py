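"""Projector head and cross-view InfoNCE loss with imbalanced view sizes.

A batch of N molecules yields N molecule views, N element views, and only
M = ceil(0.3·N) drug views (the trailing M batch positions — only those
molecules carry drug ids).  For an anchor in one view, the positive is the
same molecule's row in the partner view; the denominator collects the
anchor view's other rows as intra-view negatives and the partner view's
non-positive rows as inter-view negatives.  With view sizes M ≤ N that is
(M−1) + (N−1) = N+M−2 negative terms per anchor, and the directed loss is
asymmetric in its two views.  The positive term is not part of the
denominator.

Similarity is cosine (projected rows are unit-normalized), scaled by a
temperature τ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, parameter

logger = logging.getLogger(__name__)


@dataclass
class ContrastiveConfig:
    temperature: float = 0.1
    projector_depth: int = 2    # 0 = identity-then-normalize
    projector_width: int | None = None   # defaults to input width

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


def init_projector(d: int, cfg: ContrastiveConfig, seed: int) -> dict[str, Tensor]:
    rng = np.random.default_rng(seed)
    w = cfg.projector_width or d
    params: dict[str, Tensor] = {}
    dims = [d] + [w] * max(cfg.projector_depth - 1, 0) + [d]
    for i in range(cfg.projector_depth):
        params[f"proj.w{i}"] = parameter(rng, (dims[i], dims[i + 1]))
        params[f"proj.b{i}"] = parameter(rng, (dims[i + 1],), fan_in=dims[i])
    return params


def project(h: Tensor | np.ndarray, params: dict[str, Tensor],
            cfg: ContrastiveConfig) -> Tensor:
    """Row-wise projector MLP followed by unit normalization."""
    z = h if isinstance(h, Tensor) else Tensor(h)
    depth = cfg.projector_depth
    for i in range(depth):
        z = z @ params[f"proj.w{i}"] + params[f"proj.b{i}"]
        if i < depth - 1:
            z = z.tanh()
    norm = (z * z).sum(axis=1, keepdims=True) ** 0.5
    return z / norm


@dataclass
class ProjectedBatch:
    z_m: Tensor      # N × d molecule-view rows
    z_em: Tensor     # N × d element-view rows
    z_dm: Tensor     # M × d drug-view rows, aligned to the LAST M positions
    log: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.z_m.shape[0]

    @property
    def m(self) -> int:
        return self.z_dm.shape[0]


def pair_counts(m: int, n: int) -> tuple[int, int, int]:
    """Pair accounting for view sizes M ≤ N.

    Returns (positives, inter-view negatives per anchor, intra-view
    negatives per anchor) = (M, M−1, N−1); each anchor therefore faces
    N+M−2 negative terms.
    """
    if m > n:
        raise ValueError(f"M={m} must not exceed N={n}")
    if m < 1:
        raise ValueError("M must be >= 1")
    return m, m - 1, n - 1


def _rows(z: Tensor | np.ndarray) -> Tensor:
    return z if isinstance(z, Tensor) else Tensor(z)


def pair_loss(z1: Tensor | np.ndarray, z2: Tensor | np.ndarray, i: int,
              cfg: ContrastiveConfig) -> Tensor:
    """Directed InfoNCE term for anchor ``i``, anchored in view ``z1``.

    Rows are aligned on the trailing overlap: with sizes M1 and M2 and
    Mmin = min(M1, M2), anchor ``i`` ∈ [0, Mmin) refers to row
    ``M1−Mmin+i`` of ``z1`` and its positive is row ``M2−Mmin+i`` of
    ``z2``.  Negatives: every other row of ``z1`` (M1−1 intra terms) and
    every non-positive row of ``z2`` (M2−1 inter terms).
    """
    z1, z2 = _rows(z1), _rows(z2)
    m1, m2 = z1.shape[0], z2.shape[0]
    mmin = min(m1, m2)
    if not 0 <= i < mmin:
        raise IndexError(f"anchor {i} out of range for aligned size {mmin}")
    ai, pi = m1 - mmin + i, m2 - mmin + i
    tau = cfg.temperature

    anchor = z1.gather_rows([ai]).reshape(-1)            # (d,)
    pos = (z2.gather_rows([pi]).reshape(-1) * anchor).sum()
    neg_rows = []
    if m1 > 1:
        neg_rows.append(z1.gather_rows([j for j in range(m1) if j != ai]))
    if m2 > 1:
        neg_rows.append(z2.gather_rows([j for j in range(m2) if j != pi]))
    if not neg_rows:
        raise ValueError("loss undefined: no negative terms (M=N=1)")
    negs = concat(neg_rows, axis=0) @ anchor.reshape(-1, 1)   # (#neg, 1)
    mx = float(np.max(negs.data)) / tau                        # stability shift
    lse = Tensor(mx) + (((negs * (1.0 / tau)) - Tensor(mx)).exp().sum()).log()
    return lse - pos * (1.0 / tau)


def view_pair_loss(z1: Tensor | np.ndarray, z2: Tensor | np.ndarray,
                   cfg: ContrastiveConfig) -> Tensor:
    """Symmetric sum of the two directed averages over the aligned anchors."""
    z1, z2 = _rows(z1), _rows(z2)
    mmin = min(z1.shape[0], z2.shape[0])
    if mmin == 0:
        logger.warning("degenerate view pair (no aligned rows); loss = 0")
        return Tensor(0.0)
    terms = [pair_loss(z1, z2, i, cfg) for i in range(mmin)]
    terms += [pair_loss(z2, z1, i, cfg) for i in range(mmin)]
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / mmin)


def total_loss(batch: ProjectedBatch, cfg: ContrastiveConfig
               ) -> tuple[Tensor, dict[str, float]]:
    """Sum of the three pairwise view losses (Molecule/Element/Drug)."""
    l_m_em = view_pair_loss(batch.z_m, batch.z_em, cfg)
    l_m_dm = view_pair_loss(batch.z_m, batch.z_dm, cfg)
    l_em_dm = view_pair_loss(batch.z_em, batch.z_dm, cfg)
    total = l_m_em + l_m_dm + l_em_dm
    log = {"loss_m_em": float(l_m_em.data), "loss_m_dm": float(l_m_dm.data),
           "loss_em_dm": float(l_em_dm.data), "loss_total": float(total.data),
           "tau": cfg.temperature, "n": batch.n, "m": batch.m}
    return total, log
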