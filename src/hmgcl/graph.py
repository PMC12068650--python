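"""Typed heterogeneous molecular graph container.

A molecule is represented at three granularities ("views"):

* ``M``  — the plain molecule view: atom and BRICS-fragment nodes with
  bond / reaction / join edges.
* ``EM`` — the element view: ``M`` plus element and functional-group nodes
  imported from an elemental knowledge graph, connected by AE / FrFu edges
  and by knowledge-derived EE / FuFu / EFu edges.
* ``DM`` — the drug view: ``M`` plus a single drug hub node (DNode) carrying
  a drug-KG embedding, connected to every atom (AD) and fragment (FrD).

Every chemistry- or knowledge-derived relation is stored as a *pair* of
directed edges (i->j and j->i); the encoder keeps separate embeddings per
direction.  Parallel edges between the same endpoints are permitted (and
occur in the EM view, one per shared knowledge-graph intermediate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NODE_TYPES = ("atom", "fragment", "element", "functional_group", "dnode")
EDGE_TYPES = (
    "bond", "reaction", "join",          # molecule view
    "AE", "FrFu", "EE", "FuFu", "EFu",   # element view
    "AD", "FrD",                         # drug view
)
VIEW_TAGS = ("M", "EM", "DM")

#: edge types added by each view on top of the molecule view
MOL_VIEW_EDGE_TYPES = ("bond", "reaction", "join")
ELEMENT_VIEW_EDGE_TYPES = ("AE", "FrFu", "EE", "FuFu", "EFu")
DRUG_VIEW_EDGE_TYPES = ("AD", "FrD")


class GraphSchemaError(ValueError):
    """Raised when a node/edge type or view tag violates the graph schema."""


@dataclass
class Node:
    id: str
    ntype: str
    alpha: np.ndarray | None = None   # raw feature vector, dim d_v(type)
    lam: np.ndarray | None = None     # positional vector, dim k
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ntype not in NODE_TYPES:
            raise GraphSchemaError(f"unknown node type {self.ntype!r}")


@dataclass
class Edge:
    id: str
    src: str
    dst: str
    etype: str
    beta: np.ndarray | None = None    # raw feature vector, dim d_e(type)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.etype not in EDGE_TYPES:
            raise GraphSchemaError(f"unknown edge type {self.etype!r}")


@dataclass
class HMGraph:
    view: str
    nodes: list[Node] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.view not in VIEW_TAGS:
            raise GraphSchemaError(f"unknown view tag {self.view!r}")

    # -- construction ------------------------------------------------------

    def add_node(self, node: Node) -> Node:
        if node.id in self._node_index():
            raise GraphSchemaError(f"duplicate node id {node.id!r}")
        self.nodes.append(node)
        self.__dict__.pop("_idx_cache", None)
        return node

    def add_edge_pair(self, src: str, dst: str, etype: str,
                      beta: np.ndarray | None = None,
                      meta: dict | None = None,
                      key: str | None = None) -> tuple[Edge, Edge]:
        """Add both directions of an undirected relation.

        ``key`` disambiguates parallel edges between the same endpoints
        (e.g. one per knowledge-graph intermediate).
        """
        idx = self._node_index()
        for n in (src, dst):
            if n not in idx:
                raise GraphSchemaError(f"edge endpoint {n!r} not in graph")
        suffix = f"#{key}" if key is not None else ""
        meta = dict(meta or {})
        fwd = Edge(f"{etype}:{src}->{dst}{suffix}", src, dst, etype,
                   None if beta is None else np.asarray(beta, dtype=float),
                   dict(meta))
        rev = Edge(f"{etype}:{dst}->{src}{suffix}", dst, src, etype,
                   None if beta is None else np.asarray(beta, dtype=float),
                   dict(meta))
        self.edges.extend((fwd, rev))
        return fwd, rev

    # -- queries -----------------------------------------------------------

    def _node_index(self) -> dict[str, int]:
        cache = self.__dict__.get("_idx_cache")
        if cache is None or len(cache) != len(self.nodes):
            cache = {n.id: i for i, n in enumerate(self.nodes)}
            self.__dict__["_idx_cache"] = cache
        return cache

    def node(self, node_id: str) -> Node:
        return self.nodes[self._node_index()[node_id]]

    def node_types(self) -> set[str]:
        return {n.ntype for n in self.nodes}

    def edge_types(self) -> set[str]:
        return {e.etype for e in self.edges}

    def nodes_of_type(self, ntype: str) -> list[Node]:
        return [n for n in self.nodes if n.ntype == ntype]

    def edges_of_type(self, etype: str) -> list[Edge]:
        return [e for e in self.edges if e.etype == etype]

    def copy(self) -> "HMGraph":
        g = HMGraph(self.view, meta=dict(self.meta))
        g.nodes = [Node(n.id, n.ntype,
                        None if n.alpha is None else n.alpha.copy(),
                        None if n.lam is None else n.lam.copy(),
                        dict(n.meta)) for n in self.nodes]
        g.edges = [Edge(e.id, e.src, e.dst, e.etype,
                        None if e.beta is None else e.beta.copy(),
                        dict(e.meta)) for e in self.edges]
        return g

    def validate(self) -> None:
        """Check referential integrity and directed-pair completeness."""
        idx = self._node_index()
        directed = set()
        for e in self.edges:
            if e.src not in idx or e.dst not in idx:
                raise GraphSchemaError(f"edge {e.id!r} references missing node")
            directed.add((e.src, e.dst, e.etype))
        for e in self.edges:
            if (e.dst, e.src, e.etype) not in directed:
                raise GraphSchemaError(
                    f"edge {e.id!r} has no reverse companion")
        if self.view == "DM":
            dn = self.nodes_of_type("dnode")
            if len(dn) != 1:
                raise GraphSchemaError(
                    f"DM view must hold exactly one dnode, found {len(dn)}")
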