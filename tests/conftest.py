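import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from hmgcl import (ContrastiveConfig, gen_drug_kg, gen_element_kg,
                   gen_molecule_pool)
from hmgcl.encoder import EncoderConfig, EncoderParams
from hmgcl.graph import HMGraph, Node
from hmgcl.molview import POS_DIM


@pytest.fixture(scope="session")
def ekg():
    return gen_element_kg(seed=1)


@pytest.fixture(scope="session")
def dkg():
    return gen_drug_kg(n_drugs=20, n_other_entities=12, d_kg=16, seed=1)


@pytest.fixture(scope="session")
def pool(dkg):
    return gen_molecule_pool(40, 0.35, dkg, seed=3)


@pytest.fixture(scope="session")
def enc_cfg():
    return EncoderConfig(d=16, heads=2, layers=2, d_kg=16)


@pytest.fixture()
def enc_params(enc_cfg):
    return EncoderParams.init(enc_cfg, seed=0)


@pytest.fixture()
def con_cfg():
    return ContrastiveConfig(temperature=0.1)


def random_typed_graph(seed: int, n_nodes: int = 6,
                       node_types=("atom", "fragment"),
                       edge_types=("bond", "join")) -> HMGraph:
    """Small random featurized multi-type graph for encoder oracle tests."""
    from hmgcl.molview import EDGE_FEATURE_DIMS, NODE_FEATURE_DIMS

    rng = np.random.default_rng(seed)
    g = HMGraph("M")
    for i in range(n_nodes):
        t = node_types[int(rng.integers(len(node_types)))]
        g.add_node(Node(f"n{i}", t,
                        alpha=rng.standard_normal(NODE_FEATURE_DIMS[t]),
                        lam=rng.standard_normal(POS_DIM)))
    n_edges = int(rng.integers(n_nodes - 1, 2 * n_nodes))
    for _ in range(n_edges):
        i, j = rng.choice(n_nodes, size=2, replace=False)
        t = edge_types[int(rng.integers(len(edge_types)))]
        g.add_edge_pair(f"n{i}", f"n{j}", t,
                        beta=rng.standard_normal(EDGE_FEATURE_DIMS[t]),
                        key=str(rng.integers(10**9)))
    return g
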