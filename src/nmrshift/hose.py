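"""HOSE-code nearest-neighbor shift prediction with sphere-depth confidence.

A HOSE (Hierarchically Ordered Spherical Environment) code summarises the
neighborhood of an atom in concentric bond-distance spheres: sphere 0 is the
focus atom, sphere k the canonically ordered atoms k bonds away, annotated
with bond symbols (aromatic ``*``, double ``=``, triple ``%``, single
unmarked) and ring-closure markers (``&``).  Prediction is nearest-neighbor:
the query code's longest prefix (deepest sphere) with matches in the training
database wins, the prediction is the unweighted mean of the matched training
shifts, and the matched sphere depth serves as a discrete confidence.

Canonicality: neighbor branches are ordered by symmetry-invariant canonical
atom ranks (Morgan-style, computed by RDKit without tie-breaking), then by
element symbol and bond symbol, so the code is independent of input atom
numbering and symmetry-equivalent atoms receive identical codes.  Stereo and
charge symbols are omitted (the models here are connectivity-only); this is a
documented simplification of the full historical HOSE grammar.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from sklearn.base import BaseEstimator, RegressorMixin

from .graphs import MolecularGraph

DEFAULT_SPHERES = 6

_BOND_SYMBOL = {1.0: "", 1.5: "*", 2.0: "=", 3.0: "%"}


@dataclass(frozen=True)
class HoseCode:
    """Canonical concentric-sphere code; ``segments[k]`` encodes sphere k."""

    segments: tuple[str, ...]

    def prefix(self, k: int) -> str:
        """The code truncated to spheres 0..k (a prefix of deeper codes)."""
        return "/".join(self.segments[: k + 1])

    @property
    def n_spheres(self) -> int:
        return len(self.segments) - 1

    def __str__(self) -> str:
        return "/".join(self.segments)


def _invariant_ranks(graph: MolecularGraph) -> list[int]:
    """Symmetry-invariant canonical ranks (equal for equivalent atoms)."""
    mol = graph.to_rdkit()
    return list(Chem.CanonicalRankAtoms(mol, breakTies=False, includeChirality=False))


def hose_code(
    graph: MolecularGraph,
    i: int,
    spheres: int = DEFAULT_SPHERES,
    _ranks: list[int] | None = None,
) -> HoseCode:
    """Canonical HOSE code of atom ``i`` with the given number of spheres.

    Deterministic and invariant to the input atom ordering; passing
    precomputed ``_ranks`` (from :func:`_invariant_ranks`) avoids repeated
    canonical-rank computation when coding every atom of a molecule.
    """
    if not 0 <= i < graph.n_atoms:
        raise IndexError(f"atom index {i} out of range")
    ranks = _invariant_ranks(graph) if _ranks is None else _ranks
    segments = [graph.atoms[i].element]
    visited = {i}
    # frontier entries: atom index, in canonical traversal order
    frontier = [i]
    parent_of = {i: None}
    for _depth in range(1, spheres + 1):
        next_frontier: list[int] = []
        parent_parts: list[str] = []
        for parent in frontier:
            children = []
            closures = []
            for nbr, order in graph.neighbors(parent):
                if nbr == parent_of[parent]:
                    continue
                sym = _BOND_SYMBOL[order]
                key = (ranks[nbr], graph.atoms[nbr].element, sym)
                if nbr in visited:
                    closures.append((key, sym + "&"))
                else:
                    children.append((key, nbr, sym))
            children.sort(key=lambda c: c[0])
            closures.sort(key=lambda c: c[0])
            parts = []
            for key, nbr, sym in children:
                if nbr in visited:  # claimed by an earlier parent this sphere
                    parts.append(sym + "&")
                    continue
                visited.add(nbr)
                parent_of[nbr] = parent
                next_frontier.append(nbr)
                parts.append(sym + graph.atoms[nbr].element)
            parts.extend(s for _, s in closures)
            parent_parts.append(",".join(parts))
        segments.append(";".join(parent_parts))
        frontier = next_frontier
        if not frontier:
            # pad remaining spheres so prefix depths stay comparable
            segments.extend([""] * (spheres - _depth))
            break
    return HoseCode(segments=tuple(segments))


@dataclass
class HoseDatabase:
    """Prefix-indexed store of training shifts, per sphere depth.

    ``index[k]`` maps a sphere-k prefix string to the list of training shift
    values whose focus atom matches that prefix; counts at depth k are
    therefore always >= counts at any depth-(k+1) extension.
    """

    spheres: int = DEFAULT_SPHERES
    index: list[dict[str, list[float]]] = field(default_factory=list)
    n_entries: int = 0

    def __post_init__(self):
        if not self.index:
            self.index = [defaultdict(list) for _ in range(self.spheres + 1)]

    def add(self, code: HoseCode, shift: float) -> None:
        for k in range(self.spheres + 1):
            self.index[k][code.prefix(k)].append(float(shift))
        self.n_entries += 1

    def add_molecule(self, graph: MolecularGraph, shifts: np.ndarray) -> None:
        """Add every atom with a finite shift; ``shifts`` is per-atom, NaN-masked."""
        ranks = _invariant_ranks(graph)
        for i, s in enumerate(np.asarray(shifts, dtype=float)):
            if np.isfinite(s):
                self.add(hose_code(graph, i, self.spheres, _ranks=ranks), s)


def hose_predict(
    db: HoseDatabase,
    graph: MolecularGraph,
    i: int,
    _ranks: list[int] | None = None,
) -> tuple[float, int] | None:
    """Predict atom ``i``'s shift from its deepest matching sphere prefix.

    Returns ``(mu, matched_sphere)`` — the unweighted mean of the training
    shifts under the deepest nonempty prefix match — or None when even the
    sphere-0 prefix (the bare element) is absent from the database.
    """
    code = hose_code(graph, i, db.spheres, _ranks=_ranks)
    for k in range(db.spheres, -1, -1):
        matches = db.index[k].get(code.prefix(k))
        if matches:
            return float(np.mean(matches)), k
    return None


class HoseShiftRegressor(RegressorMixin, BaseEstimator):
    """Nearest-neighbor shift predictor over HOSE codes (sklearn-style).

    ``X`` is a sequence of :class:`MolecularGraph`, ``y`` per-atom shift
    arrays with NaN at unobserved atoms — the same contract as
    :class:`~nmrshift.gnn.GraphConvShiftRegressor`, with the matched sphere
    depth playing the role of the (discrete) confidence instead of sigma.
    """

    def __init__(self, spheres: int = DEFAULT_SPHERES):
        self.spheres = spheres

    def fit(self, X, y):
        X, y = list(X), list(y)
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        db = HoseDatabase(spheres=self.spheres)
        for graph, shifts in zip(X, y):
            shifts = np.asarray(shifts, dtype=float)
            if len(shifts) != graph.n_atoms:
                raise ValueError("each y entry must have one value per atom")
            db.add_molecule(graph, shifts)
        if db.n_entries == 0:
            raise ValueError("no observed shifts in y: empty database")
        self.db_ = db
        return self

    def predict(self, X) -> list[np.ndarray]:
        """Per-molecule arrays of predicted shifts (NaN where no match)."""
        return [mu for mu, _ in self._predict_pairs(X)]

    def predict_with_confidence(self, X) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per-molecule (mu, matched_sphere) arrays; sphere -1 where no match."""
        return self._predict_pairs(X)

    def _predict_pairs(self, X):
        if not hasattr(self, "db_"):
            raise RuntimeError("estimator is not fitted; call fit first")
        out = []
        for graph in X:
            ranks = _invariant_ranks(graph)
            mu = np.full(graph.n_atoms, np.nan)
            sphere = np.full(graph.n_atoms, -1, dtype=int)
            for i in range(graph.n_atoms):
                hit = hose_predict(self.db_, graph, i, _ranks=ranks)
                if hit is not None:
                    mu[i], sphere[i] = hit
            out.append((mu, sphere))
        return out
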