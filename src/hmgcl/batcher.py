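"""Drug-aware mini-batch generation by constrained clustering.

Non-drug molecules are clustered into equal-size groups of ceil(0.7·N) by
size-constrained K-means on circular substructure fingerprints; each
cluster is completed with the (0.3·N − n) drug molecules nearest to its
centroid — consumed globally, so nearest-neighbor complements never repeat
across batches — and topped up with n drug molecules sampled at random from
the remaining pool (reusable across batches, never within one).  Every
batch ends up with exactly N members whose drug records occupy the trailing
0.3·N positions, the alignment the contrastive loss relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .fixtures import MoleculeRecord
from .molview import SmilesParseError

logger = logging.getLogger(__name__)

FP_BITS = 1024
FP_RADIUS = 2


class BatchResourceError(RuntimeError):
    """Not enough drug records to satisfy the batch composition."""


@dataclass
class BatchPlan:
    batches: list[list[MoleculeRecord]]
    centers: np.ndarray
    used_drugs: set[str]         # record ids consumed as NN complements
    n_non_drug: int              # ceil(0.7 N) per batch
    n_drug: int                  # N - ceil(0.7 N) per batch
    dropped: int = 0             # leftover non-drug records not batched
    meta: dict = field(default_factory=dict)


def molecule_features(records: list[MoleculeRecord]) -> np.ndarray:
    """Morgan (circular, radius 2, 1024-bit) fingerprints, one row per record."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS,
                                                    fpSize=FP_BITS)
    rows = np.zeros((len(records), FP_BITS))
    for i, rec in enumerate(records):
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            raise SmilesParseError(f"record {i}: {rec.smiles}")
        fp = gen.GetFingerprint(mol)
        rows[i, list(fp.GetOnBits())] = 1.0
    return rows


def constrained_kmeans(features: np.ndarray, cluster_size: int, seed: int
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Equal-size K-means: floor(rows/size) clusters of exactly ``size``.

    Seeded K-means provides initial centroids; assignments are then solved
    exactly per iteration as a minimum-cost matching of points to cluster
    slots (``linear_sum_assignment``), alternating with centroid updates
    until stable.  Leftover rows that do not fill a cluster are dropped
    (assignment −1) with a logged count.
    """
    rows = features.shape[0]
    if cluster_size < 1:
        raise ValueError("cluster_size must be >= 1")
    if rows < cluster_size:
        raise ValueError(f"{rows} rows cannot fill a cluster of {cluster_size}")
    n_clusters = rows // cluster_size
    leftover = rows - n_clusters * cluster_size
    if leftover:
        logger.info("dropping %d leftover rows (< one cluster)", leftover)

    if n_clusters == 1:
        centers = features.mean(axis=0, keepdims=True)
        assign = np.zeros(rows, dtype=int)
        if leftover:
            d = ((features - centers[0]) ** 2).sum(axis=1)
            assign[np.argsort(d, kind="stable")[cluster_size:]] = -1
        return assign, centers

    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=4)
    centers = km.fit(features).cluster_centers_

    assign = np.full(rows, -1, dtype=int)
    for _ in range(20):
        d2 = ((features[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        cost = np.repeat(d2, cluster_size, axis=1)   # rows × slots
        ri, ci = linear_sum_assignment(cost)
        new_assign = np.full(rows, -1, dtype=int)
        new_assign[ri] = ci // cluster_size
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for c in range(n_clusters):
            members = features[assign == c]
            if len(members):
                centers[c] = members.mean(axis=0)
    return assign, centers


def make_batches(s_m: list[MoleculeRecord], s_d: list[MoleculeRecord],
                 batch_size: int, complement_size: int, seed: int) -> BatchPlan:
    """Build drug-balanced batches of ``batch_size`` records.

    ``complement_size`` (n) of each batch's drug slots are filled by random
    sampling; the remaining drug slots by globally-disjoint nearest
    neighbors to the cluster centroid.
    """
    if batch_size < 2:
        raise ValueError("batch_size must be >= 2")
    k_non = int(np.ceil(0.7 * batch_size))
    k_drug = batch_size - k_non
    if not 0 <= complement_size <= k_drug:
        raise ValueError(
            f"complement size {complement_size} outside [0, {k_drug}]")
    if len(s_m) < k_non:
        raise ValueError(f"need >= {k_non} non-drug records, got {len(s_m)}")
    if not s_d:
        raise BatchResourceError("no drug records available")

    rng = np.random.default_rng(seed)
    feats_m = molecule_features(s_m)
    feats_d = molecule_features(s_d)
    assign, centers = constrained_kmeans(feats_m, k_non, seed)
    n_clusters = centers.shape[0]

    n_nn = k_drug - complement_size
    need = n_clusters * n_nn + (complement_size if n_clusters else 0)
    if len(s_d) < need:
        raise BatchResourceError(
            f"need >= {need} drug records for {n_clusters} batches "
            f"({n_nn} disjoint NN complements each + {complement_size} "
            f"random), got {len(s_d)}")

    def rid(rec: MoleculeRecord, idx: int) -> str:
        return rec.rid if rec.rid is not None else f"drug-rec-{idx}"

    used: set[str] = set()
    used_idx: set[int] = set()
    batches: list[list[MoleculeRecord]] = []
    for c in range(n_clusters):
        members = [s_m[i] for i in np.nonzero(assign == c)[0]]
        avail = [i for i in range(len(s_d)) if i not in used_idx]
        d = ((feats_d[avail] - centers[c]) ** 2).sum(axis=1)
        order = np.argsort(d, kind="stable")[:n_nn]
        nn_idx = [avail[int(o)] for o in order]
        used_idx.update(nn_idx)
        used.update(rid(s_d[i], i) for i in nn_idx)
        batches.append(members + [s_d[i] for i in nn_idx])

    for c in range(n_clusters):
        pool = [i for i in range(len(s_d)) if i not in used_idx]
        if len(pool) < complement_size:
            raise BatchResourceError(
                f"random fill needs {complement_size} drug records outside "
                f"the used set, only {len(pool)} remain")
        picks = rng.choice(len(pool), size=complement_size, replace=False)
        batches[c].extend(s_d[pool[int(p)]] for p in sorted(picks))

    dropped = int(np.sum(assign == -1))
    return BatchPlan(batches, centers, used, k_non, k_drug, dropped,
                     meta={"batch_size": batch_size,
                           "complement_size": complement_size, "seed": seed})
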