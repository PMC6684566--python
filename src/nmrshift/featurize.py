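"""Featurization: 37-dimensional atom features and bond-order adjacency stacks.

Each molecule becomes

* ``L`` — an ``M x 37`` per-vertex feature matrix (rows beyond the real atoms
  are zero), and
* four ``M x M`` adjacency matrices ``G_k``, one per bond order
  k in {1, 1.5, 2, 3}, each symmetrically normalized with self-loops:
  ``G~ = D^{-1/2} (G + I) D^{-1/2}`` where ``D = diag(rowsums(G + I))``,
  computed over the valid submatrix only so padding never inflates degrees.

The feature layout is fixed (block order and widths):

====================================  =====
atomic number                             1
element one-hot {H,C,O,N,P,S,F,Cl}        8
valence (scalar)                          1
valence one-hot 1-6                       6
aromaticity flag                          1
hybridization one-hot s..sp3d2            6
formal charge one-hot {-1,0,+1}           3
default valence one-hot 1-6               6
ring-size one-hot 3-7                     5
total                                    37
====================================  =====

Out-of-range categorical values (valence 0 or > 6, ring sizes outside 3-7,
exotic hybridizations) encode as all-zero one-hot blocks.  An atom in several
rings sets the position of its smallest ring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .graphs import BOND_ORDERS, ELEMENTS, MolecularGraph

N_FEATURES = 37
M_DEFAULT = 64

_HYB_ORDER = ("s", "sp", "sp2", "sp3", "sp3d", "sp3d2")


@dataclass
class AdjacencyStack:
    """Per-bond-order adjacency matrices of one molecule, padded to M."""

    g: np.ndarray  # (4, M, M) raw 0/1
    g_norm: np.ndarray  # (4, M, M) normalized
    valid_mask: np.ndarray  # (M,) 0/1

    @property
    def m(self) -> int:
        return self.g.shape[-1]


def atom_features(graph: MolecularGraph, i: int) -> np.ndarray:
    """The 37-entry feature vector of atom ``i`` (see module docstring)."""
    a = graph.atoms[i]
    v = np.zeros(N_FEATURES)
    pos = 0
    v[pos] = a.atomic_number
    pos += 1
    if a.element in ELEMENTS:
        v[pos + ELEMENTS.index(a.element)] = 1.0
    pos += len(ELEMENTS)
    v[pos] = a.valence
    pos += 1
    if 1 <= a.valence <= 6:
        v[pos + a.valence - 1] = 1.0
    pos += 6
    v[pos] = 1.0 if a.aromatic else 0.0
    pos += 1
    if a.hybridization in _HYB_ORDER:
        v[pos + _HYB_ORDER.index(a.hybridization)] = 1.0
    pos += 6
    if -1 <= a.formal_charge <= 1:
        v[pos + a.formal_charge + 1] = 1.0
    pos += 3
    if 1 <= a.default_valence <= 6:
        v[pos + a.default_valence - 1] = 1.0
    pos += 6
    if a.ring_sizes:
        smallest = min(a.ring_sizes)
        if 3 <= smallest <= 7:
            v[pos + smallest - 3] = 1.0
    pos += 5
    assert pos == N_FEATURES
    return v


def build_adjacency(graph: MolecularGraph, m_max: int = M_DEFAULT) -> AdjacencyStack:
    """Raw + normalized bond-order adjacency channels, padded to ``m_max``.

    Each bond lives in exactly one order channel; aromatic bonds only in the
    1.5 channel (aromaticity is perceived upstream, at graph construction).
    """
    n = graph.n_atoms
    if n > m_max:
        raise ValueError(f"molecule has {n} atoms, exceeds padding size {m_max}")
    g = np.zeros((len(BOND_ORDERS), m_max, m_max))
    for i, j, order in graph.bonds:
        try:
            k = BOND_ORDERS.index(order)
        except ValueError:
            raise ValueError(f"bond ({i}, {j}) has unsupported order {order}") from None
        g[k, i, j] = 1.0
        g[k, j, i] = 1.0
    mask = np.zeros(m_max)
    mask[:n] = 1.0
    g_norm = np.stack([normalize_adjacency(g[k], mask) for k in range(len(BOND_ORDERS))])
    return AdjacencyStack(g=g, g_norm=g_norm, valid_mask=mask)


def normalize_adjacency(g: np.ndarray, valid_mask: np.ndarray) -> np.ndarray:
    """Symmetric normalization with self-loops, restricted to valid vertices.

    ``G~ = D^{-1/2} (G + I) D^{-1/2}`` with ``D = diag(rowsums(G + I))``;
    the identity is added only on the valid diagonal and the padded region
    stays exactly zero.
    """
    m = g.shape[0]
    valid = valid_mask.astype(bool)
    out = np.zeros((m, m))
    if not valid.any():
        return out
    sub = g[np.ix_(valid, valid)] + np.eye(valid.sum())
    d_inv_sqrt = 1.0 / np.sqrt(sub.sum(axis=1))
    out[np.ix_(valid, valid)] = d_inv_sqrt[:, None] * sub * d_inv_sqrt[None, :]
    return out


def featurize_molecule(
    graph: MolecularGraph, m_max: int = M_DEFAULT
) -> tuple[np.ndarray, AdjacencyStack, np.ndarray]:
    """(L, adjacency stack, valid mask) for one molecule."""
    n = graph.n_atoms
    if n > m_max:
        raise ValueError(f"molecule has {n} atoms, exceeds padding size {m_max}")
    stack = build_adjacency(graph, m_max)
    L = np.zeros((m_max, N_FEATURES))
    for i in range(n):
        L[i] = atom_features(graph, i)
    return L, stack, stack.valid_mask


@dataclass
class FeaturizedBatch:
    """Dense batch of featurized molecules, ready for the network."""

    features: np.ndarray  # (B, M, 37)
    adjacency: np.ndarray  # (B, 4, M, M) normalized
    valid_mask: np.ndarray  # (B, M)


class MolecularGraphFeaturizer(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer: list of graphs -> :class:`FeaturizedBatch`.

    Parameters
    ----------
    m_max : int
        Padding size M; every molecule must have at most this many atoms
        (explicit hydrogens included).
    """

    def __init__(self, m_max: int = M_DEFAULT):
        self.m_max = m_max

    def fit(self, X, y=None):
        self._validate(X)
        self.n_features_out_ = N_FEATURES
        return self

    def transform(self, X) -> FeaturizedBatch:
        self._validate(X)
        b = len(X)
        feats = np.zeros((b, self.m_max, N_FEATURES))
        adj = np.zeros((b, len(BOND_ORDERS), self.m_max, self.m_max))
        mask = np.zeros((b, self.m_max))
        for idx, graph in enumerate(X):
            L, stack, valid = featurize_molecule(graph, self.m_max)
            feats[idx] = L
            adj[idx] = stack.g_norm
            mask[idx] = valid
        return FeaturizedBatch(features=feats, adjacency=adj, valid_mask=mask)

    def _validate(self, X):
        if not all(isinstance(g, MolecularGraph) for g in X):
            raise TypeError("X must be a sequence of MolecularGraph")
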