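"""Molecular graph container used throughout the package.

A :class:`MolecularGraph` is the sole source of per-atom features and of the
bond-order adjacency structure.  It is a thin, immutable-ish view extracted
from an RDKit molecule: hydrogens are always explicit vertices (1H shifts need
a vertex to attach to), and aromatic bonds carry the fractional order 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem

#: Elements the models operate on.
ELEMENTS = ("H", "C", "O", "N", "P", "S", "F", "Cl")

#: Bond orders recognised by the adjacency builder, in channel order.
BOND_ORDERS = (1.0, 1.5, 2.0, 3.0)

_HYBRIDIZATIONS = ("s", "sp", "sp2", "sp3", "sp3d", "sp3d2")

_RD_HYB = {
    Chem.HybridizationType.S: "s",
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
    Chem.HybridizationType.SP3D: "sp3d",
    Chem.HybridizationType.SP3D2: "sp3d2",
}

_RD_BOND_ORDER = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.AROMATIC: 1.5,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
}

_ORDER_BOND = {v: k for k, v in _RD_BOND_ORDER.items()}


@dataclass(frozen=True)
class AtomInfo:
    """Chemical attributes of one vertex."""

    element: str
    atomic_number: int
    formal_charge: int
    valence: int  # total connectivity including hydrogens
    default_valence: int
    aromatic: bool
    hybridization: str  # one of _HYBRIDIZATIONS or "other"
    ring_sizes: tuple[int, ...]  # sorted sizes of rings (3..7) containing the atom


@dataclass
class MolecularGraph:
    """An undirected molecular graph with explicit hydrogens.

    ``bonds`` are (i, j, order) triples with i < j and order in
    {1, 1.5, 2, 3}; aromatic bonds appear only as order 1.5.
    """

    atoms: list[AtomInfo]
    bonds: list[tuple[int, int, float]]
    mol_id: str = ""
    _rdmol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list[tuple[int, float]]:
        """(neighbor index, bond order) pairs of vertex ``i``."""
        out = []
        for a, b, order in self.bonds:
            if a == i:
                out.append((b, order))
            elif b == i:
                out.append((a, order))
        return out

    # ------------------------------------------------------------------
    # RDKit interop
    # ------------------------------------------------------------------
    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, mol_id: str = "") -> "MolecularGraph":
        """Extract a graph from a sanitized RDKit molecule.

        Hydrogens are made explicit if they are not already; the caller is
        expected to have sanitized the molecule (aromaticity perceived).
        """
        if any(a.GetNumImplicitHs() or a.GetNumExplicitHs() for a in mol.GetAtoms()):
            mol = Chem.AddHs(mol)
        pt = Chem.GetPeriodicTable()
        ring_info = mol.GetRingInfo()
        atoms: list[AtomInfo] = []
        for atom in mol.GetAtoms():
            sizes = tuple(
                sorted(s for s in range(3, 8) if ring_info.IsAtomInRingOfSize(atom.GetIdx(), s))
            )
            atoms.append(
                AtomInfo(
                    element=atom.GetSymbol(),
                    atomic_number=atom.GetAtomicNum(),
                    formal_charge=atom.GetFormalCharge(),
                    valence=atom.GetTotalDegree(),
                    default_valence=pt.GetDefaultValence(atom.GetAtomicNum()),
                    aromatic=atom.GetIsAromatic(),
                    hybridization=_RD_HYB.get(atom.GetHybridization(), "other"),
                    ring_sizes=sizes,
                )
            )
        bonds = []
        for bond in mol.GetBonds():
            order = _RD_BOND_ORDER.get(bond.GetBondType())
            if order is None:
                raise ValueError(
                    f"unsupported bond type {bond.GetBondType()} between atoms "
                    f"{bond.GetBeginAtomIdx()} and {bond.GetEndAtomIdx()}"
                )
            i, j = sorted((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
            bonds.append((i, j, order))
        return cls(atoms=atoms, bonds=sorted(bonds), mol_id=mol_id, _rdmol=mol)

    def to_rdkit(self) -> Chem.Mol:
        """Rebuild a sanitized RDKit molecule (explicit hydrogens kept)."""
        if self._rdmol is not None:
            return self._rdmol
        rw = Chem.RWMol()
        for info in self.atoms:
            a = Chem.Atom(info.element)
            a.SetFormalCharge(info.formal_charge)
            a.SetNoImplicit(True)
            rw.AddAtom(a)
        for i, j, order in self.bonds:
            rw.AddBond(i, j, _ORDER_BOND[order])
        for i, j, order in self.bonds:
            if order == 1.5:
                rw.GetAtomWithIdx(i).SetIsAromatic(True)
                rw.GetAtomWithIdx(j).SetIsAromatic(True)
                rw.GetBondBetweenAtoms(i, j).SetIsAromatic(True)
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        self._rdmol = mol
        return mol

    def canonical_key(self) -> str:
        """Canonical SMILES without stereochemistry, used for split hygiene.

        Stereoisomers share a key on purpose: the model is connectivity-only,
        so they must never straddle a train/test split.
        """
        mol = Chem.RemoveHs(Chem.Mol(self.to_rdkit()))
        return Chem.MolToSmiles(mol, isomericSmiles=False)

    def permuted(self, perm: list[int]) -> "MolecularGraph":
        """Relabel vertices: new index ``perm[i]`` holds old atom ``i``."""
        n = self.n_atoms
        if sorted(perm) != list(range(n)):
            raise ValueError("perm must be a permutation of range(n_atoms)")
        perm = [int(p) for p in perm]
        atoms = [None] * n
        for old, new in enumerate(perm):
            atoms[new] = self.atoms[old]
        bonds = sorted(
            (min(perm[i], perm[j]), max(perm[i], perm[j]), order)
            for i, j, order in self.bonds
        )
        return MolecularGraph(atoms=list(atoms), bonds=bonds, mol_id=self.mol_id)
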