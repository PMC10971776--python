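"""Graph featurization of MHC-peptide molecules.

Each atom becomes a 31-dimensional feature vector and each covalent bond a
12-dimensional vector, both one-hot encoded; bonds are stored as two directed
edges so that message passing can address each direction.

Node feature layout (31 slots)::

    element   {H, C, N, O, S}                      5
    hybridization {SP3, SP2, SP, S, SP3D, SP3D2}   6
    degree    0..5 (all neighbours incl. H)        6
    bonded-H  0..4                                 5
    chirality {CCW, CW, other}                     3
    aromatic flag                                  1
    ring flag                                      1
    formal charge {-1, 0, +1}                      3
    radical-electron count (numeric)               1

Edge feature layout (12 slots)::

    bond type {single, aromatic, double, triple}   4
    stereo    {any, cis, E, none, trans, Z}        6
    ring flag                                      1
    conjugated flag                                1

Ring membership is topological: a bond is in a ring iff it is not a bridge
of the bond graph, and an atom is in a ring iff it touches a non-bridge bond.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .chem import Molecule, build_peptide, combine

__all__ = [
    "NODE_FEATURE_DIM",
    "EDGE_FEATURE_DIM",
    "GraphSample",
    "node_feature_vector",
    "edge_feature_vector",
    "ring_membership",
    "featurize_molecule",
    "featurize_pair",
    "MHCPeptideGraphFeaturizer",
]

NODE_FEATURE_DIM = 31
EDGE_FEATURE_DIM = 12

_ELEMENTS = ("H", "C", "N", "O", "S")
_HYBRIDIZATIONS = ("SP3", "SP2", "SP", "S", "SP3D", "SP3D2")
_CHIRALITIES = ("CCW", "CW", "other")
_BOND_TYPES = ("single", "aromatic", "double", "triple")
_STEREO_TYPES = ("any", "cis", "E", "none", "trans", "Z")
_MAX_DEGREE = 5
_MAX_H_COUNT = 4
_CHARGES = (-1, 0, 1)


class FeatureEncodingError(ValueError):
    pass


@dataclass
class GraphSample:
    """A featurized molecular graph with a binary binding label.

    ``edge_index`` is ``2 x E`` with both directions of every bond;
    the two directed copies share one edge-feature row.
    """

    node_features: np.ndarray  # (num_atoms, 31)
    edge_index: np.ndarray  # (2, num_directed_edges), int64
    edge_features: np.ndarray  # (num_directed_edges, 12)
    label: int | None = None
    group_id: str | None = None

    @property
    def num_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def num_edges(self) -> int:
        return self.edge_index.shape[1]


def _bridges(n_atoms: int, bonds) -> set[int]:
    """Indices of bridge bonds, via iterative Tarjan low-link on the bond graph."""
    adj: list[list[tuple[int, int]]] = [[] for _ in range(n_atoms)]
    for k, b in enumerate(bonds):
        adj[b.i].append((b.j, k))
        adj[b.j].append((b.i, k))
    disc = [-1] * n_atoms
    low = [0] * n_atoms
    bridges: set[int] = set()
    timer = 0
    for root in range(n_atoms):
        if disc[root] >= 0:
            continue
        stack = [(root, -1, iter(adj[root]))]
        disc[root] = low[root] = timer
        timer += 1
        while stack:
            u, in_edge, it = stack[-1]
            advanced = False
            for v, k in it:
                if k == in_edge:
                    continue
                if disc[v] < 0:
                    disc[v] = low[v] = timer
                    timer += 1
                    stack.append((v, k, iter(adj[v])))
                    advanced = True
                    break
                low[u] = min(low[u], disc[v])
            if advanced:
                continue
            stack.pop()
            if stack:
                p, pk, _ = stack[-1]
                low[p] = min(low[p], low[u])
                if low[u] > disc[p]:
                    bridges.add(in_edge)
    return bridges


def ring_membership(m: Molecule) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom and per-bond ring flags (non-bridge criterion)."""
    bridge_ids = _bridges(m.num_atoms, m.bonds)
    bond_in_ring = np.array(
        [k not in bridge_ids for k in range(len(m.bonds))], dtype=bool
    )
    atom_in_ring = np.zeros(m.num_atoms, dtype=bool)
    for k, b in enumerate(m.bonds):
        if bond_in_ring[k]:
            atom_in_ring[b.i] = True
            atom_in_ring[b.j] = True
    return atom_in_ring, bond_in_ring


def _degrees_and_h_counts(m: Molecule) -> tuple[np.ndarray, np.ndarray]:
    deg = np.zeros(m.num_atoms, dtype=np.int64)
    hcount = np.zeros(m.num_atoms, dtype=np.int64)
    for b in m.bonds:
        deg[b.i] += 1
        deg[b.j] += 1
        if m.atoms[b.j].element == "H":
            hcount[b.i] += 1
        if m.atoms[b.i].element == "H":
            hcount[b.j] += 1
    return deg, hcount


def node_feature_vector(m: Molecule, atom_index: int) -> np.ndarray:
    """31-slot one-hot feature vector of one atom (see module docstring)."""
    return featurize_molecule(m).node_features[atom_index]


def edge_feature_vector(m: Molecule, bond_index: int) -> np.ndarray:
    """12-slot one-hot feature vector of one bond."""
    _, bond_ring = ring_membership(m)
    return _encode_bond(m.bonds[bond_index], bool(bond_ring[bond_index]))


def _encode_bond(b, in_ring: bool) -> np.ndarray:
    v = np.zeros(EDGE_FEATURE_DIM, dtype=np.float32)
    v[_BOND_TYPES.index(b.bond_type)] = 1.0
    v[4 + _STEREO_TYPES.index(b.stereo)] = 1.0
    v[10] = 1.0 if in_ring else 0.0
    v[11] = 1.0 if b.conjugated else 0.0
    return v


def featurize_molecule(
    m: Molecule, label: int | None = None, group_id: str | None = None
) -> GraphSample:
    """Encode a molecule as node/edge feature matrices and a directed edge index."""
    n = m.num_atoms
    atom_ring, bond_ring = ring_membership(m)
    deg, hcount = _degrees_and_h_counts(m)

    x = np.zeros((n, NODE_FEATURE_DIM), dtype=np.float32)
    for i, atom in enumerate(m.atoms):
        if atom.element not in _ELEMENTS:
            raise FeatureEncodingError(
                f"atom {i}: element {atom.element!r} outside {{H,C,N,O,S}}"
            )
        if deg[i] > _MAX_DEGREE:
            raise FeatureEncodingError(f"atom {i}: degree {deg[i]} > {_MAX_DEGREE}")
        if hcount[i] > _MAX_H_COUNT:
            raise FeatureEncodingError(f"atom {i}: H-count {hcount[i]} > {_MAX_H_COUNT}")
        if atom.formal_charge not in _CHARGES:
            raise FeatureEncodingError(
                f"atom {i}: formal charge {atom.formal_charge} outside {{-1,0,+1}}"
            )
        x[i, _ELEMENTS.index(atom.element)] = 1.0
        x[i, 5 + _HYBRIDIZATIONS.index(atom.hybridization)] = 1.0
        x[i, 11 + deg[i]] = 1.0
        x[i, 17 + hcount[i]] = 1.0
        x[i, 22 + _CHIRALITIES.index(atom.chirality)] = 1.0
        x[i, 25] = 1.0 if atom.aromatic else 0.0
        x[i, 26] = 1.0 if atom_ring[i] else 0.0
        x[i, 27 + _CHARGES.index(atom.formal_charge)] = 1.0
        x[i, 30] = float(atom.radical_electrons)

    n_bonds = len(m.bonds)
    edge_index = np.empty((2, 2 * n_bonds), dtype=np.int64)
    edge_features = np.empty((2 * n_bonds, EDGE_FEATURE_DIM), dtype=np.float32)
    for k, b in enumerate(m.bonds):
        fv = _encode_bond(b, bool(bond_ring[k]))
        edge_index[:, 2 * k] = (b.i, b.j)
        edge_index[:, 2 * k + 1] = (b.j, b.i)
        edge_features[2 * k] = fv
        edge_features[2 * k + 1] = fv
    return GraphSample(
        node_features=x,
        edge_index=edge_index,
        edge_features=edge_features,
        label=label,
        group_id=group_id,
    )


def featurize_pair(
    mhc_seq: str,
    peptide_seq: str,
    label: int | None = None,
    group_id: str | None = None,
) -> GraphSample:
    """Featurize one MHC pseudo-sequence / peptide pair.

    The two chains are built as separate molecules and joined as disconnected
    components of a single graph (MHC atoms first), so the sample always has
    exactly two connected components.
    """
    mol = combine(build_peptide(mhc_seq), build_peptide(peptide_seq))
    return featurize_molecule(mol, label=label, group_id=group_id)


class MHCPeptideGraphFeaturizer(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer: (MHC pseudo-seq, peptide) pairs to graphs.

    ``transform`` accepts an iterable of ``(mhc_seq, peptide_seq)`` pairs, or
    of ``(mhc_seq, peptide_seq, label)`` triples, and returns a list of
    :class:`GraphSample`.
    """

    def fit(self, X, y=None):  # noqa: D102 - nothing to learn
        return self

    def transform(self, X, y=None) -> list[GraphSample]:
        out = []
        for k, item in enumerate(X):
            item = tuple(item)
            if len(item) == 2:
                mhc, pep = item
                label = None
            elif len(item) == 3:
                mhc, pep, label = item
                label = int(label)
            else:
                raise ValueError(
                    f"item {k}: expected (mhc, peptide[, label]), got {len(item)} fields"
                )
            out.append(featurize_pair(mhc, pep, label=label, group_id=str(k)))
        return out
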