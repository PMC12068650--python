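"""Synthetic knowledge graphs and molecule pools for desk-scale experiments.

The elemental knowledge graph is a small curated chemistry KG structured in
three levels — class nodes (broad chemical categories), chemical-level nodes
(elements and SMARTS-defined functional groups), and property nodes (atomic
weight buckets, periodic-table periods).  The drug knowledge graph is a
seeded stand-in for a pharmacological network (drugs linked to genes,
diseases, side effects, ...) whose drug entities carry unit-norm embedding
vectors; a real, externally trained embedding table can be supplied instead.

Molecule pools emulate a pre-training corpus in which only a minority of
molecules are approved drugs with a drug-KG identifier — the sparsity that
the drug-aware batch generator is designed around.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

ATTR_DIM = 8  #: width of entity attribute vectors (used as 2-hop edge features)

ELEMENT_RELATIONS = ("isSubClassOf", "isPartOf", "hasWeight", "isInPeriod")

# symbol -> (period, atomic weight, class)
_ELEMENT_TABLE: dict[str, tuple[int, float, str]] = {
    "H": (1, 1.008, "ReactiveNonmetal"),
    "C": (2, 12.011, "ReactiveNonmetal"),
    "N": (2, 14.007, "ReactiveNonmetal"),
    "O": (2, 15.999, "ReactiveNonmetal"),
    "F": (2, 18.998, "Halogens"),
    "S": (3, 32.06, "ReactiveNonmetal"),
    "Cl": (3, 35.45, "Halogens"),
    "Br": (4, 79.904, "Halogens"),
    "P": (3, 30.974, "ReactiveNonmetal"),
}

_CLASS_TABLE: dict[str, str | None] = {
    "Nonmetals": None,
    "ReactiveNonmetal": "Nonmetals",
    "Halogens": "Nonmetals",
}

# name -> (SMARTS, member element symbols)
_FUNCTIONAL_GROUPS: dict[str, tuple[str, tuple[str, ...]]] = {
    "Acetal": ("O[CH1][OX2H0]", ("C", "O")),
    "Nitrile": ("[NX1]#[CX2]", ("C", "N")),
    "Nitro": ("[$([NX3](=O)=O),$([NX3+](=O)[O-])]", ("N", "O")),
    "Ester": ("[CX3](=O)[OX2H0][#6]", ("C", "O")),
    "Amide": ("[CX3](=O)[NX3]", ("C", "N", "O")),
    "Ketone": ("[#6][CX3](=O)[#6]", ("C", "O")),
    "Ether": ("[OD2]([#6])[#6]", ("C", "O")),
    "Hydroxyl": ("[OX2H]", ("O",)),
    "PrimaryAmine": ("[NX3;H2][#6]", ("C", "N")),
    "CarboxylicAcid": ("[CX3](=O)[OX2H1]", ("C", "O")),
    "Halide": ("[#6][F,Cl,Br,I]", ("C", "F", "Cl", "Br")),
}


def _weight_bucket(weight: float) -> str:
    for i, hi in enumerate((10.0, 20.0, 40.0), start=1):
        if weight < hi:
            return f"Weight{i}"
    return "Weight4"


@dataclass(frozen=True)
class KGTriple:
    head: str
    relation: str
    tail: str

    def __post_init__(self) -> None:
        if self.head == self.tail:
            raise ValueError(f"self-loop triple on {self.head!r}")


@dataclass
class KGEntity:
    id: str
    level: str            # class | chemical | property
    kind: str             # element | functional_group | class | property
    symbol: str | None = None
    smarts: str | None = None
    attributes: np.ndarray | None = None


@dataclass
class ElementKG:
    entities: dict[str, KGEntity]
    relations: tuple[str, ...]
    triples: list[KGTriple]

    def __post_init__(self) -> None:
        for t in self.triples:
            if t.head not in self.entities or t.tail not in self.entities:
                raise ValueError(f"dangling triple {t}")
            if t.relation not in self.relations:
                raise ValueError(f"unknown relation {t.relation!r}")

    def chemical_entities(self) -> list[KGEntity]:
        return [e for e in self.entities.values() if e.level == "chemical"]

    def element_by_symbol(self, symbol: str) -> KGEntity | None:
        e = self.entities.get(symbol)
        if e is not None and e.kind == "element":
            return e
        return None

    def functional_groups(self) -> list[KGEntity]:
        return [e for e in self.entities.values()
                if e.kind == "functional_group"]

    def undirected_neighbors(self, entity_id: str) -> dict[str, list[str]]:
        """Neighbor id -> relations connecting it to ``entity_id``."""
        out: dict[str, list[str]] = {}
        for t in self.triples:
            if t.head == entity_id:
                out.setdefault(t.tail, []).append(t.relation)
            elif t.tail == entity_id:
                out.setdefault(t.head, []).append(t.relation)
        return out


DRUG_CATEGORIES = ("gene", "compound", "disease", "process",
                   "side-effect", "symptom")
DRUG_RELATIONS = ("targets", "interacts_with", "treats", "participates_in",
                  "causes", "associated_with")
_CATEGORY_RELATION = dict(zip(DRUG_CATEGORIES, DRUG_RELATIONS))


@dataclass
class DrugKG:
    entities: dict[str, KGEntity]   # kind ∈ {drug} ∪ DRUG_CATEGORIES
    relations: tuple[str, ...]
    triples: list[KGTriple]
    embeddings: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        dims = {v.shape[0] for v in self.embeddings.values()}
        if len(dims) > 1:
            raise ValueError(f"ragged embedding dims {sorted(dims)}")
        for e in self.entities.values():
            if e.kind == "drug" and e.id not in self.embeddings:
                raise ValueError(f"drug {e.id!r} lacks an embedding")
        for t in self.triples:
            if t.head not in self.entities or t.tail not in self.entities:
                raise ValueError(f"dangling triple {t}")

    @property
    def d_kg(self) -> int:
        return next(iter(self.embeddings.values())).shape[0]

    def drug_ids(self) -> list[str]:
        return sorted(e.id for e in self.entities.values() if e.kind == "drug")


@dataclass
class MoleculeRecord:
    smiles: str
    drug_id: str | None = None
    rid: str | None = None


def _entity_rng(seed: int, entity_id: str) -> np.random.Generator:
    mix = (int(seed) * 1_000_003 + zlib.crc32(entity_id.encode())) % (2**31)
    return np.random.default_rng(mix)


def _attr(seed: int, entity_id: str) -> np.ndarray:
    v = _entity_rng(seed, entity_id).standard_normal(ATTR_DIM)
    return v / np.linalg.norm(v)


def gen_element_kg(n_elements: int = len(_ELEMENT_TABLE),
                   n_fgroups: int = len(_FUNCTIONAL_GROUPS),
                   seed: int = 0) -> ElementKG:
    """Build the three-level elemental knowledge graph.

    The first ``n_elements`` elements of the curated mini periodic table and
    the first ``n_fgroups`` functional groups are instantiated together with
    their class and property nodes.  The seed only controls entity attribute
    vectors; the triple inventory is curated chemistry and identical across
    seeds.
    """
    if n_elements < 2:
        raise ValueError("n_elements must be >= 2")
    if not 1 <= n_fgroups <= len(_FUNCTIONAL_GROUPS):
        raise ValueError(f"n_fgroups must be in [1, {len(_FUNCTIONAL_GROUPS)}]")
    if n_elements > len(_ELEMENT_TABLE):
        raise ValueError(f"at most {len(_ELEMENT_TABLE)} elements available")

    symbols = list(_ELEMENT_TABLE)[:n_elements]
    fgroups = list(_FUNCTIONAL_GROUPS)[:n_fgroups]

    entities: dict[str, KGEntity] = {}
    triples: list[KGTriple] = []

    for cname, parent in _CLASS_TABLE.items():
        entities[cname] = KGEntity(cname, "class", "class",
                                   attributes=_attr(seed, cname))
        if parent is not None:
            triples.append(KGTriple(cname, "isSubClassOf", parent))

    for sym in symbols:
        period, weight, cls = _ELEMENT_TABLE[sym]
        entities[sym] = KGEntity(sym, "chemical", "element", symbol=sym,
                                 attributes=_attr(seed, sym))
        for pid in (f"Period{period}", _weight_bucket(weight)):
            if pid not in entities:
                entities[pid] = KGEntity(pid, "property", "property",
                                         attributes=_attr(seed, pid))
        triples.append(KGTriple(sym, "isInPeriod", f"Period{period}"))
        triples.append(KGTriple(sym, "hasWeight", _weight_bucket(weight)))
        triples.append(KGTriple(sym, "isSubClassOf", cls))

    for name in fgroups:
        smarts, members = _FUNCTIONAL_GROUPS[name]
        if Chem.MolFromSmarts(smarts) is None:  # pragma: no cover
            raise ValueError(f"invalid SMARTS for {name!r}: {smarts}")
        entities[name] = KGEntity(name, "chemical", "functional_group",
                                  smarts=smarts, attributes=_attr(seed, name))
        for sym in members:
            if sym in entities:
                triples.append(KGTriple(sym, "isPartOf", name))

    return ElementKG(entities, ELEMENT_RELATIONS, triples)


def gen_drug_kg(n_drugs: int = 10, n_other_entities: int = 12,
                d_kg: int = 16, seed: int = 0,
                embeddings: dict[str, np.ndarray] | None = None) -> DrugKG:
    """Generate a drug KG with unit-norm drug embeddings.

    ``embeddings`` may supply an externally trained table (keyed by drug id)
    to replace the seeded random stand-in.
    """
    if n_drugs < 1:
        raise ValueError("n_drugs must be >= 1")
    if n_other_entities < 1:
        raise ValueError("n_other_entities must be >= 1 "
                         "(a drug must connect to something)")
    if d_kg < 2:
        raise ValueError("d_kg must be >= 2")

    rng = np.random.default_rng(seed)
    entities: dict[str, KGEntity] = {}
    for i in range(n_drugs):
        did = f"drug_{i}"
        entities[did] = KGEntity(did, "chemical", "drug")
    others: list[str] = []
    for i in range(n_other_entities):
        cat = DRUG_CATEGORIES[i % len(DRUG_CATEGORIES)]
        oid = f"{cat}_{i}"
        entities[oid] = KGEntity(oid, "chemical", cat)
        others.append(oid)

    triples: list[KGTriple] = []
    for i in range(n_drugs):
        k = 1 + int(rng.integers(0, min(3, len(others))))
        picks = rng.choice(len(others), size=k, replace=False)
        for j in sorted(int(p) for p in picks):
            oid = others[j]
            rel = _CATEGORY_RELATION[entities[oid].kind]
            triples.append(KGTriple(f"drug_{i}", rel, oid))

    if embeddings is None:
        embeddings = {}
        for i in range(n_drugs):
            v = rng.standard_normal(d_kg)
            embeddings[f"drug_{i}"] = v / np.linalg.norm(v)
    else:
        embeddings = {k: np.asarray(v, dtype=float) for k, v in embeddings.items()}

    return DrugKG(entities, DRUG_RELATIONS, triples, embeddings)


#: in-code SMILES templates: aromatic rings, halogens, esters, amides,
#: nitriles, ethers, acids — some BRICS-cleavable, some single-fragment.
MOLECULE_TEMPLATES: tuple[str, ...] = (
    "c1ccccc1",            # benzene: single fragment
    "Cc1ccccc1",           # toluene
    "CC(=O)OC",            # methyl acetate: BRICS-cleavable ester
    "CC(=O)NC",            # N-methylacetamide
    "CC#N",                # acetonitrile
    "N#Cc1ccccc1",         # benzonitrile
    "Clc1ccccc1",          # chlorobenzene
    "Fc1ccc(F)cc1",        # 1,4-difluorobenzene
    "CC(=O)Oc1ccccc1",     # phenyl acetate
    "CCOC(=O)c1ccccc1",    # ethyl benzoate
    "O=C(O)c1ccccc1",      # benzoic acid
    "CN(C)C(=O)c1ccccc1",  # N,N-dimethylbenzamide
    "CCOCC",               # diethyl ether
    "CC(C)O",              # isopropanol
    "CCN",                 # ethylamine
    "OCC(O)CO",            # glycerol
    "CCCCCC",              # hexane
    "c1ccncc1",            # pyridine
    "CSc1ccccc1",          # thioanisole
    "CC(=O)NCc1ccccc1",    # N-benzylacetamide
)


def gen_molecule_pool(n_total: int, drug_fraction: float, dkg: DrugKG,
                      seed: int = 0,
                      allow_repeat_drugs: bool = False) -> list[MoleculeRecord]:
    """Draw a seeded molecule pool; a ``drug_fraction`` minority get drug ids.

    Exactly ``ceil(n_total * drug_fraction)`` records carry a drug id drawn
    from ``dkg``; without ``allow_repeat_drugs`` the ids are distinct, which
    requires the KG to hold at least that many drug entities.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0.0 <= drug_fraction <= 1.0:
        raise ValueError("drug_fraction must be in [0, 1]")
    n_drug = int(np.ceil(n_total * drug_fraction))
    drug_ids = dkg.drug_ids()
    if n_drug > len(drug_ids) and not allow_repeat_drugs:
        raise ValueError(
            f"need {n_drug} distinct drug ids but KG has {len(drug_ids)}; "
            "pass allow_repeat_drugs=True to reuse ids")

    rng = np.random.default_rng(seed)
    smiles = [MOLECULE_TEMPLATES[int(i)]
              for i in rng.integers(0, len(MOLECULE_TEMPLATES), size=n_total)]
    records = [MoleculeRecord(s, rid=f"mol{i}") for i, s in enumerate(smiles)]
    if n_drug:
        where = sorted(int(i) for i in
                       rng.choice(n_total, size=n_drug, replace=False))
        if allow_repeat_drugs:
            ids = [drug_ids[int(i)] for i in
                   rng.integers(0, len(drug_ids), size=n_drug)]
        else:
            perm = rng.permutation(len(drug_ids))[:n_drug]
            ids = [drug_ids[int(i)] for i in perm]
        for pos, did in zip(where, ids):
            records[pos].drug_id = did
    return records
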