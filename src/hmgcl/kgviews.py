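"""Knowledge-graph augmentation: element view (EM) and drug view (DM).

The element view grafts element and functional-group nodes from the
elemental KG onto the molecule view and wires them with five edge types:
AE (atom–element, shared chemical symbol), FrFu (fragment–functional group,
SMARTS match inside the fragment), and EE / FuFu / EFu knowledge edges
carried over from the KG, restricted to 2 hops — each 2-hop edge stores the
intermediate entity it was traversed through and takes that entity's
attribute vector as its feature.

The drug view adds a single DNode whose raw feature is the drug-KG
embedding, linked to every atom (AD) and every fragment (FrD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .fixtures import ATTR_DIM, DrugKG, ElementKG
from .graph import HMGraph, Node
from .molview import (KGEDGE_DIM, POS_DIM, attach_relation_feature)

logger = logging.getLogger(__name__)

_KG_RELATION_OFFSET = ATTR_DIM


class DrugLookupError(KeyError):
    def __init__(self, drug_id: str):
        super().__init__(f"no embedding for drug id {drug_id!r}")
        self.drug_id = drug_id


@dataclass(frozen=True)
class TwoHopEdge:
    a: str                      # endpoint entity id (chemical level)
    b: str
    intermediate: str | None    # None for direct 1-hop EFu relations
    relation: str | None        # set for 1-hop relations
    etype: str                  # EE | FuFu | EFu
    feature: np.ndarray


def _pair_type(ekg: ElementKG, a: str, b: str) -> str:
    ka, kb = ekg.entities[a].kind, ekg.entities[b].kind
    if ka == kb == "element":
        return "EE"
    if ka == kb == "functional_group":
        return "FuFu"
    return "EFu"


def _relation_feature(ekg: ElementKG, relation: str) -> np.ndarray:
    v = np.zeros(KGEDGE_DIM)
    v[_KG_RELATION_OFFSET + ekg.relations.index(relation)] = 1.0
    return v


def _intermediate_feature(ekg: ElementKG, intermediate: str) -> np.ndarray:
    v = np.zeros(KGEDGE_DIM)
    v[:ATTR_DIM] = ekg.entities[intermediate].attributes
    return v


def two_hop_edges(ekg: ElementKG, active_entities: set[str]) -> list[TwoHopEdge]:
    """Knowledge edges among active chemical-level entities, ≤ 2 KG hops.

    For each unordered pair of active entities, one edge is emitted per
    shared KG neighbor (the intermediate of a length-2 path) — multiple
    shared intermediates yield multiple parallel edges.  Direct
    element–functional-group triples are additionally emitted as 1-hop EFu
    edges with relation one-hot features.
    """
    for ent in active_entities:
        if ekg.entities[ent].level != "chemical":
            raise ValueError(f"{ent!r} is not a chemical-level entity")
    active = sorted(active_entities)
    nbrs = {ent: ekg.undirected_neighbors(ent) for ent in active}
    out: list[TwoHopEdge] = []
    for ia, a in enumerate(active):
        for b in active[ia + 1:]:
            # direct 1-hop relations (element <-> functional group)
            for rel in nbrs[a].get(b, []):
                out.append(TwoHopEdge(a, b, None, rel, "EFu",
                                      _relation_feature(ekg, rel)))
            # length-2 paths through a shared neighbor
            shared = sorted(set(nbrs[a]) & set(nbrs[b]) - {a, b})
            for mid in shared:
                out.append(TwoHopEdge(a, b, mid, None, _pair_type(ekg, a, b),
                                      _intermediate_feature(ekg, mid)))
    out.sort(key=lambda e: (e.etype, e.a, e.b, e.intermediate or "",
                            e.relation or ""))
    return out


def _fragment_matches(mol: Chem.Mol, pattern: Chem.Mol,
                      atom_to_frag: list[int]) -> set[int]:
    """Fragments overlapping a SMARTS match on the whole molecule.

    Matching runs on the intact molecule and each match is attributed to
    every BRICS fragment it touches: fragmentation frequently cuts straight
    through a functional group (BRICS cleaves ester and amide bonds), so a
    group confined to one fragment links only that fragment, while a
    straddling group links each fragment contributing atoms to it.
    """
    hit: set[int] = set()
    for match in mol.GetSubstructMatches(pattern):
        hit.update(atom_to_frag[i] for i in match)
    return hit


def attach_element_view(gm: HMGraph, ekg: ElementKG) -> HMGraph:
    """Augment a molecule view into the element view 𝒢EM.

    Adds one element node per distinct chemical symbol present in both the
    molecule and the KG, one functional-group node per KG group matching
    within some fragment, and the ≤2-hop knowledge edges among them.  The
    molecule-view content is unchanged.  Elements absent from the KG are
    skipped with a warning.
    """
    if gm.view != "M":
        raise ValueError(f"expected a molecule view, got {gm.view!r}")
    g = gm.copy()
    g.view = "EM"

    symbols = sorted({n.meta["symbol"] for n in g.nodes_of_type("atom")})
    active: list[str] = []
    for sym in symbols:
        ent = ekg.element_by_symbol(sym)
        if ent is None:
            logger.warning("element %s not in the elemental KG; skipped", sym)
            continue
        g.add_node(Node(f"elem:{ent.id}", "element",
                        alpha=np.asarray(ent.attributes, dtype=float),
                        lam=np.zeros(POS_DIM), meta={"entity": ent.id}))
        active.append(ent.id)
        for atom in g.nodes_of_type("atom"):
            if atom.meta["symbol"] == sym:
                g.add_edge_pair(atom.id, f"elem:{ent.id}", "AE",
                                beta=attach_relation_feature("AE"))

    mol = Chem.MolFromSmiles(g.meta["smiles"])
    atom_to_frag = g.meta["atom_to_frag"]
    for fg in sorted(ekg.functional_groups(), key=lambda e: e.id):
        pattern = Chem.MolFromSmarts(fg.smarts)
        frags = _fragment_matches(mol, pattern, atom_to_frag)
        if not frags:
            continue
        g.add_node(Node(f"fg:{fg.id}", "functional_group",
                        alpha=np.asarray(fg.attributes, dtype=float),
                        lam=np.zeros(POS_DIM), meta={"entity": fg.id}))
        active.append(fg.id)
        for f in sorted(frags):
            g.add_edge_pair(f"frag:{f}", f"fg:{fg.id}", "FrFu",
                            beta=attach_relation_feature("FrFu"))

    node_of = {ent: (f"elem:{ent}" if ekg.entities[ent].kind == "element"
                     else f"fg:{ent}") for ent in active}
    for k, edge in enumerate(two_hop_edges(ekg, set(active))):
        g.add_edge_pair(node_of[edge.a], node_of[edge.b], edge.etype,
                        beta=edge.feature,
                        meta={"intermediate": edge.intermediate,
                              "relation": edge.relation},
                        key=edge.intermediate or f"rel:{edge.relation}")
    return g


def attach_drug_view(gm: HMGraph, drug_id: str, dkg: DrugKG) -> HMGraph:
    """Augment a molecule view into the drug view 𝒢DM for ``drug_id``."""
    if gm.view != "M":
        raise ValueError(f"expected a molecule view, got {gm.view!r}")
    if drug_id not in dkg.embeddings:
        raise DrugLookupError(drug_id)
    g = gm.copy()
    g.view = "DM"
    g.add_node(Node(f"dnode:{drug_id}", "dnode",
                    alpha=np.asarray(dkg.embeddings[drug_id], dtype=float),
                    lam=np.zeros(POS_DIM), meta={"entity": drug_id}))
    for atom in g.nodes_of_type("atom"):
        g.add_edge_pair(atom.id, f"dnode:{drug_id}", "AD",
                        beta=attach_relation_feature("AD"))
    for frag in g.nodes_of_type("fragment"):
        g.add_edge_pair(frag.id, f"dnode:{drug_id}", "FrD",
                        beta=attach_relation_feature("FrD"))
    return g
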