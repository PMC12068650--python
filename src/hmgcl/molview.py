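"""Molecule view construction: atoms, BRICS fragments, and raw features.

The molecule view holds two node types (atom, fragment) and three edge
types: atom-bond-atom chemical bonds, fragment-reaction-fragment edges at
BRICS breakpoints, and atom-join-fragment membership edges.  Hydrogens are
implicit (heavy-atom graph).

Feature schema (the field-standard one-hot featurization):

* atom:  element one-hot over the fixture periodic table (+ "other") ‖
  degree 0–5 one-hot ‖ formal charge −2..+2 one-hot ‖ aromatic bit ‖
  hybridization one-hot (SP/SP2/SP3/other) ‖ ring bit
* fragment:  mean of member-atom features ‖ heavy-atom count
* bond:  bond-order one-hot (single/double/triple/aromatic) ‖ conjugation
  bit ‖ ring bit
* reaction:  one-hot pair of the BRICS rule labels at the breakpoint
* join:  constant 1

Positional vectors λ are the ``k`` lowest Laplacian eigenvectors of the
atom-bond subgraph (zero-padded, sign fixed so the first nonzero component
is positive); fragment and knowledge-derived nodes get λ = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import BRICS

from .fixtures import ATTR_DIM, ELEMENT_RELATIONS
from .graph import Edge, HMGraph, Node

ELEMENTS = ("H", "C", "N", "O", "F", "S", "Cl", "Br", "P")
_HYBRIDIZATIONS = ("SP", "SP2", "SP3")
_BOND_ORDERS = (Chem.BondType.SINGLE, Chem.BondType.DOUBLE,
                Chem.BondType.TRIPLE, Chem.BondType.AROMATIC)
#: BRICS link labels used by the RDKit rule set
BRICS_LABELS = tuple(str(i) for i in range(1, 17)) + ("7a", "7b")

POS_DIM = 8  #: width k of the Laplacian positional encoding

ATOM_DIM = (len(ELEMENTS) + 1) + 6 + 5 + 1 + (len(_HYBRIDIZATIONS) + 1) + 1
FRAGMENT_DIM = ATOM_DIM + 1
BOND_DIM = len(_BOND_ORDERS) + 2
REACTION_DIM = 2 * len(BRICS_LABELS)
JOIN_DIM = 1
#: AE / FrFu / AD / FrD features are a one-hot over this shared relation vocab
ATTACH_RELATIONS = ("AE", "FrFu", "AD", "FrD")
ATTACH_DIM = len(ATTACH_RELATIONS)
#: EE / FuFu / EFu features: intermediate attribute vector ‖ KG relation one-hot
KGEDGE_DIM = ATTR_DIM + len(ELEMENT_RELATIONS)

NODE_FEATURE_DIMS = {
    "atom": ATOM_DIM,
    "fragment": FRAGMENT_DIM,
    "element": ATTR_DIM,
    "functional_group": ATTR_DIM,
    # dnode width is the drug-KG embedding dimension, set at attach time
}
EDGE_FEATURE_DIMS = {
    "bond": BOND_DIM,
    "reaction": REACTION_DIM,
    "join": JOIN_DIM,
    "AE": ATTACH_DIM,
    "FrFu": ATTACH_DIM,
    "AD": ATTACH_DIM,
    "FrD": ATTACH_DIM,
    "EE": KGEDGE_DIM,
    "FuFu": KGEDGE_DIM,
    "EFu": KGEDGE_DIM,
}


class SmilesParseError(ValueError):
    def __init__(self, smiles: str):
        super().__init__(f"unparsable SMILES: {smiles!r}")
        self.smiles = smiles


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:  # "" parses to an empty mol
        raise SmilesParseError(smiles)
    return mol


@dataclass
class FragmentMap:
    atom_to_frag: list[int]
    breakpoints: list[tuple[int, int]]
    bond_labels: list[tuple[str, str]]

    @property
    def n_fragments(self) -> int:
        return max(self.atom_to_frag) + 1 if self.atom_to_frag else 0


def brics_fragments(smiles: str) -> FragmentMap:
    """Partition atoms into BRICS fragments.

    Fragments are the connected components left after deleting the bonds the
    BRICS rule set would cleave; a molecule with no cleavable bond is a
    single fragment with no breakpoints.
    """
    mol = _mol(smiles)
    cuts = sorted(((min(i, j), max(i, j)), (str(a), str(b)))
                  for (i, j), (a, b) in BRICS.FindBRICSBonds(mol))
    cut_set = {ij for ij, _ in cuts}

    n = mol.GetNumAtoms()
    adj: list[list[int]] = [[] for _ in range(n)]
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if (min(i, j), max(i, j)) in cut_set:
            continue
        adj[i].append(j)
        adj[j].append(i)

    frag = [-1] * n
    fid = 0
    for start in range(n):
        if frag[start] >= 0:
            continue
        stack = [start]
        frag[start] = fid
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if frag[v] < 0:
                    frag[v] = fid
                    stack.append(v)
        fid += 1
    return FragmentMap(frag, [ij for ij, _ in cuts], [lab for _, lab in cuts])


def _atom_feature(atom: Chem.Atom) -> np.ndarray:
    sym = atom.GetSymbol()
    elem = [0.0] * (len(ELEMENTS) + 1)
    elem[ELEMENTS.index(sym) if sym in ELEMENTS else len(ELEMENTS)] = 1.0
    deg = [0.0] * 6
    deg[min(atom.GetDegree(), 5)] = 1.0
    chg = [0.0] * 5
    chg[int(np.clip(atom.GetFormalCharge(), -2, 2)) + 2] = 1.0
    hyb = [0.0] * (len(_HYBRIDIZATIONS) + 1)
    hname = str(atom.GetHybridization())
    hyb[_HYBRIDIZATIONS.index(hname) if hname in _HYBRIDIZATIONS
        else len(_HYBRIDIZATIONS)] = 1.0
    return np.array(elem + deg + chg + [float(atom.GetIsAromatic())]
                    + hyb + [float(atom.IsInRing())])


def _bond_feature(bond: Chem.Bond) -> np.ndarray:
    order = [0.0] * len(_BOND_ORDERS)
    bt = bond.GetBondType()
    if bt in _BOND_ORDERS:
        order[_BOND_ORDERS.index(bt)] = 1.0
    return np.array(order + [float(bond.GetIsConjugated()),
                             float(bond.IsInRing())])


def _reaction_feature(labels: tuple[str, str]) -> np.ndarray:
    v = np.zeros(REACTION_DIM)
    lo, hi = sorted(labels)
    v[BRICS_LABELS.index(lo)] = 1.0
    v[len(BRICS_LABELS) + BRICS_LABELS.index(hi)] = 1.0
    return v


def attach_relation_feature(relation: str) -> np.ndarray:
    v = np.zeros(ATTACH_DIM)
    v[ATTACH_RELATIONS.index(relation)] = 1.0
    return v


def laplacian_positions(n_atoms: int, bonds: list[tuple[int, int]],
                        k: int = POS_DIM) -> np.ndarray:
    """Rows are per-atom positional vectors from the k lowest Laplacian modes."""
    if n_atoms == 0:
        return np.zeros((0, k))
    a = np.zeros((n_atoms, n_atoms))
    for i, j in bonds:
        a[i, j] = a[j, i] = 1.0
    lap = np.diag(a.sum(axis=1)) - a
    _, vecs = np.linalg.eigh(lap)
    vecs = vecs[:, :min(k, n_atoms)]
    for c in range(vecs.shape[1]):  # sign fix: first nonzero component > 0
        col = vecs[:, c]
        nz = np.nonzero(np.abs(col) > 1e-9)[0]
        if nz.size and col[nz[0]] < 0:
            vecs[:, c] = -col
    out = np.zeros((n_atoms, k))
    out[:, :vecs.shape[1]] = vecs
    return out


def build_molecule_view(smiles: str) -> HMGraph:
    """Build the (unfeaturized) molecule view 𝒢M from a SMILES string."""
    mol = _mol(smiles)
    fmap = brics_fragments(smiles)
    g = HMGraph("M", meta={"smiles": smiles,
                           "atom_to_frag": list(fmap.atom_to_frag)})

    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        g.add_node(Node(f"atom:{i}", "atom", meta={
            "symbol": atom.GetSymbol(),
            "feature": _atom_feature(atom),
            "frag": fmap.atom_to_frag[i],
        }))
    for f in range(fmap.n_fragments):
        members = [i for i, fi in enumerate(fmap.atom_to_frag) if fi == f]
        g.add_node(Node(f"frag:{f}", "fragment", meta={"atoms": members}))

    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        g.add_edge_pair(f"atom:{i}", f"atom:{j}", "bond",
                        beta=_bond_feature(bond))
    for (i, j), labels in zip(fmap.breakpoints, fmap.bond_labels):
        fi, fj = fmap.atom_to_frag[i], fmap.atom_to_frag[j]
        g.add_edge_pair(f"frag:{fi}", f"frag:{fj}", "reaction",
                        beta=_reaction_feature(labels),
                        key=f"{i}-{j}")
    for i, f in enumerate(fmap.atom_to_frag):
        g.add_edge_pair(f"atom:{i}", f"frag:{f}", "join", beta=np.ones(1))

    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    g.meta["bonds"] = bonds
    return g


def featurize(g: HMGraph) -> HMGraph:
    """Fill raw node/edge feature vectors α, β and positional vectors λ.

    Idempotent; operates in place on the molecule-view content and returns
    the graph.  Knowledge-view nodes/edges carry their features from attach
    time and are left untouched.
    """
    atoms = g.nodes_of_type("atom")
    n_atoms = len(atoms)
    lam = laplacian_positions(n_atoms, g.meta.get("bonds", []))
    for node in atoms:
        idx = int(node.id.split(":")[1])
        node.alpha = np.asarray(node.meta["feature"], dtype=float)
        node.lam = lam[idx]
    atom_by_idx = {int(n.id.split(":")[1]): n for n in atoms}
    for node in g.nodes_of_type("fragment"):
        members = node.meta["atoms"]
        feats = np.stack([atom_by_idx[i].alpha for i in members])
        node.alpha = np.concatenate([feats.mean(axis=0),
                                     [float(len(members))]])
        node.lam = np.zeros(POS_DIM)
    for node in g.nodes:
        if node.lam is None:
            node.lam = np.zeros(POS_DIM)
        if node.alpha is None:
            raise ValueError(f"node {node.id!r} has no raw feature")
    for e in g.edges:
        if e.beta is None:
            raise ValueError(f"edge {e.id!r} has no raw feature")
        want = EDGE_FEATURE_DIMS.get(e.etype)
        if want is not None and e.beta.shape[0] != want:
            raise ValueError(
                f"edge {e.id!r}: feature dim {e.beta.shape[0]} != {want}")
    return g
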