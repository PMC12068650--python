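"""File formats: molecule CSV, KG TSVs, graph JSON, with schema versioning.

All writers stamp a schema-version field (a ``#schema=`` header comment for
TSV/CSV, a ``"schema_version"`` key for JSON) and all readers verify it.
Graph JSON is a diffable, lossless round-trip of an ``HMGraph`` including
feature vectors, parallel edges and the view tag.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .fixtures import (DRUG_RELATIONS, DrugKG, ElementKG, KGEntity, KGTriple,
                       MoleculeRecord)
from .graph import Edge, HMGraph, Node

SCHEMA_VERSION = "1"
_HEADER = f"#schema={SCHEMA_VERSION}\n"


class FormatError(ValueError):
    pass


class IntegrityError(ValueError):
    pass


def _check_header(path: Path) -> None:
    with open(path) as fh:
        first = fh.readline()
    if first.strip() != _HEADER.strip():
        raise FormatError(f"{path}: missing or mismatched schema header "
                          f"(expected {_HEADER.strip()!r})")


# -- molecules --------------------------------------------------------------

def write_molecules(records: list[MoleculeRecord], path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_HEADER)
        pd.DataFrame(
            {"rid": [r.rid for r in records],
             "smiles": [r.smiles for r in records],
             "drug_id": [r.drug_id or "" for r in records]}
        ).to_csv(fh, index=False)


def read_molecules(path, strict: bool = False
                   ) -> tuple[list[MoleculeRecord], list[dict]]:
    """Load molecule records; invalid SMILES are skipped (lenient, default)
    or abort with the offending row number (strict)."""
    path = Path(path)
    _check_header(path)
    # skiprows (not comment=...) — '#' is the SMILES triple-bond character
    df = pd.read_csv(path, skiprows=1, keep_default_na=False)
    if "smiles" not in df.columns:
        raise FormatError(f"{path}: no 'smiles' column")
    records, skipped = [], []
    for pos, row in enumerate(df.itertuples(index=False)):
        if Chem.MolFromSmiles(row.smiles) is None:
            report = {"row": pos + 1, "smiles": row.smiles}
            if strict:
                raise FormatError(
                    f"{path}: invalid SMILES at data row {pos + 1}: "
                    f"{row.smiles!r}")
            skipped.append(report)
            continue
        records.append(MoleculeRecord(
            row.smiles,
            drug_id=(getattr(row, "drug_id", "") or None),
            rid=(getattr(row, "rid", "") or None)))
    return records, skipped


# -- knowledge graphs --------------------------------------------------------

def write_kg(kg: ElementKG | DrugKG, triples_path, attributes_path,
             embeddings_path=None) -> None:
    with open(triples_path, "w") as fh:
        fh.write(_HEADER)
        for t in kg.triples:
            fh.write(f"{t.head}\t{t.relation}\t{t.tail}\n")
    with open(attributes_path, "w") as fh:
        fh.write(_HEADER)
        for e in sorted(kg.entities.values(), key=lambda e: e.id):
            attrs = ("" if e.attributes is None
                     else ",".join(f"{v:.17g}" for v in e.attributes))
            level = getattr(e, "level", "chemical")
            fh.write(f"{e.id}\t{level}\t{e.kind}\t{e.symbol or ''}\t"
                     f"{e.smarts or ''}\t{attrs}\n")
    if embeddings_path is not None:
        emb = getattr(kg, "embeddings", None)
        if emb is None:
            raise ValueError("this KG carries no embeddings")
        with open(embeddings_path, "w") as fh:
            fh.write(_HEADER)
            for k in sorted(emb):
                fh.write(k + "\t" + "\t".join(f"{v:.17g}" for v in emb[k])
                         + "\n")


def _read_entities(attributes_path) -> dict[str, KGEntity]:
    _check_header(Path(attributes_path))
    entities: dict[str, KGEntity] = {}
    with open(attributes_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            eid, level, kind, symbol, smarts, attrs = line.rstrip("\n").split("\t")
            vec = (np.array([float(x) for x in attrs.split(",")])
                   if attrs else None)
            entities[eid] = KGEntity(eid, level, kind, symbol or None,
                                     smarts or None, vec)
    return entities


def _read_triples(triples_path, entities) -> list[KGTriple]:
    _check_header(Path(triples_path))
    triples = []
    with open(triples_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            h, r, t = line.rstrip("\n").split("\t")
            for end in (h, t):
                if end not in entities:
                    raise IntegrityError(
                        f"triple ({h}, {r}, {t}) references unknown "
                        f"entity {end!r}")
            triples.append(KGTriple(h, r, t))
    return triples


def read_element_kg(triples_path, attributes_path) -> ElementKG:
    entities = _read_entities(attributes_path)
    triples = _read_triples(triples_path, entities)
    relations = tuple(sorted({t.relation for t in triples}))
    return ElementKG(entities, relations, triples)


def read_drug_kg(triples_path, attributes_path, embeddings_path) -> DrugKG:
    entities = _read_entities(attributes_path)
    triples = _read_triples(triples_path, entities)
    _check_header(Path(embeddings_path))
    embeddings: dict[str, np.ndarray] = {}
    width = None
    with open(embeddings_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            vec = np.array([float(x) for x in parts[1:]])
            if width is None:
                width = vec.shape[0]
            elif vec.shape[0] != width:
                raise FormatError(
                    f"ragged embedding width for {parts[0]!r}: "
                    f"{vec.shape[0]} != {width}")
            embeddings[parts[0]] = vec
    return DrugKG(entities, DRUG_RELATIONS, triples, embeddings)


# -- graphs ------------------------------------------------------------------

def serialize_graph(g: HMGraph, path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "view": g.view,
        "meta": {k: v for k, v in g.meta.items()},
        "nodes": [{"id": n.id, "type": n.ntype,
                   "alpha": None if n.alpha is None else n.alpha.tolist(),
                   "lam": None if n.lam is None else n.lam.tolist(),
                   "meta": _jsonable(n.meta)} for n in g.nodes],
        "edges": [{"id": e.id, "src": e.src, "dst": e.dst, "type": e.etype,
                   "beta": None if e.beta is None else e.beta.tolist(),
                   "meta": _jsonable(e.meta)} for e in g.edges],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def _jsonable(meta: dict) -> dict:
    out = {}
    for k, v in meta.items():
        out[k] = v.tolist() if isinstance(v, np.ndarray) else v
    return out


def deserialize_graph(path) -> HMGraph:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise FormatError(f"{path}: schema version "
                          f"{payload.get('schema_version')!r} unsupported")
    g = HMGraph(payload["view"], meta=payload.get("meta", {}))
    for n in payload["nodes"]:
        meta = dict(n["meta"])
        if "feature" in meta:
            meta["feature"] = np.asarray(meta["feature"])
        g.nodes.append(Node(n["id"], n["type"],
                            None if n["alpha"] is None else np.asarray(n["alpha"]),
                            None if n["lam"] is None else np.asarray(n["lam"]),
                            meta))
    for e in payload["edges"]:
        g.edges.append(Edge(e["id"], e["src"], e["dst"], e["type"],
                            None if e["beta"] is None else np.asarray(e["beta"]),
                            dict(e["meta"])))
    g.validate()
    return g
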