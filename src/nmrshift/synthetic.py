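"""Synthetic molecule sets with a known ground-truth shift structure.

Real chemical-shift corpora need a large download; the generator here builds
desk-scale datasets whose "true" shifts come from a deterministic
1-bond-environment oracle plus controlled heteroscedastic noise, so learning
behaviour (can the network recover the rule? does sigma track the injected
noise?) can be tested exactly.

The oracle deliberately depends only on each atom's immediate (1-bond)
environment — base value per element, additive terms per bonded-partner
element and per bond order, aromatic and ring offsets — so any graph network
with at least one convolution layer has a sufficient receptive field, and a
plain environment-lookup table achieves near-zero error on noiseless data.
A per-element scale maps the same structural terms onto a 13C-like (~100-200
ppm) range for carbon and a 1H-like (~2-10 ppm) range for hydrogen.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from .graphs import ELEMENTS, MolecularGraph
from .io import ShiftAssignment

_HEAVY_VALENCE = {"C": 4, "N": 3, "O": 2, "P": 3, "S": 2, "F": 1, "Cl": 1}
_DEFAULT_WEIGHTS = {"C": 0.6, "O": 0.12, "N": 0.12, "S": 0.05, "P": 0.03, "F": 0.04, "Cl": 0.04}


@dataclass
class SyntheticShiftOracle:
    """Deterministic shift = f(1-bond environment); noise added separately.

    ``shift(graph, i) = base[elem] + scale[elem] * (sum over bonds of
    partner_term[partner] + order_term[order]) + aromatic/ring offsets``.
    Noise standard deviations are per element class, enabling heteroscedastic
    recovery experiments (e.g. quiet carbons vs noisy ones).
    """

    base: dict[str, float] = field(
        default_factory=lambda: {
            "H": 4.0, "C": 90.0, "O": 0.0, "N": 110.0, "P": 30.0,
            "S": 10.0, "F": -150.0, "Cl": 0.0,
        }
    )
    scale: dict[str, float] = field(
        default_factory=lambda: {
            "H": 0.08, "C": 1.0, "O": 1.0, "N": 1.0, "P": 1.0,
            "S": 1.0, "F": 1.0, "Cl": 1.0,
        }
    )
    partner_term: dict[str, float] = field(
        default_factory=lambda: {
            "H": -2.0, "C": 6.0, "O": 28.0, "N": 14.0, "P": 8.0,
            "S": 11.0, "F": 35.0, "Cl": 18.0,
        }
    )
    order_term: dict[float, float] = field(
        default_factory=lambda: {1.0: 0.0, 1.5: 9.0, 2.0: 16.0, 3.0: -22.0}
    )
    aromatic_offset: float = 12.0
    ring_offset: float = -4.0
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {e: 0.0 for e in ELEMENTS}
    )
    #: how atoms map to noise classes: "element", or "carbon_env" which
    #: refines carbon into aromatic / ring / chain classes (other elements
    #: stay keyed by element) for heteroscedastic-recovery experiments
    noise_class_by: str = "element"

    def shift(self, graph: MolecularGraph, i: int) -> float:
        a = graph.atoms[i]
        env = 0.0
        for j, order in graph.neighbors(i):
            env += self.partner_term[graph.atoms[j].element]
            env += self.order_term[order]
        val = self.base[a.element] + self.scale[a.element] * env
        if a.aromatic:
            val += self.scale[a.element] * self.aromatic_offset
        if a.ring_sizes:
            val += self.scale[a.element] * self.ring_offset
        return val

    def noise_class(self, graph: MolecularGraph, i: int) -> str:
        a = graph.atoms[i]
        if self.noise_class_by == "carbon_env" and a.element == "C":
            if a.aromatic:
                return "C:aromatic"
            return "C:ring" if a.ring_sizes else "C:chain"
        return a.element

    def shift_range(self, mols: list[MolecularGraph], element: str) -> float:
        """Empirical spread (max - min) of oracle shifts for one element."""
        vals = [
            self.shift(g, i)
            for g in mols
            for i in range(g.n_atoms)
            if g.atoms[i].element == element
        ]
        return float(np.max(vals) - np.min(vals)) if vals else 0.0

    def to_json(self) -> str:
        d = asdict(self)
        d["order_term"] = {str(k): v for k, v in d["order_term"].items()}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticShiftOracle":
        d = json.loads(text)
        d["order_term"] = {float(k): v for k, v in d["order_term"].items()}
        return cls(**d)


def generate_molecules(
    n: int,
    seed: int,
    max_atoms: int = 16,
    element_weights: dict[str, float] | None = None,
    aromatic_prob: float = 0.25,
    ring_prob: float = 0.15,
    unsaturation_prob: float = 0.25,
) -> list[MolecularGraph]:
    """Random valence-respecting molecular graphs with explicit hydrogens.

    Heavy-atom skeletons are grown as random trees (optionally seeded with a
    benzene ring), some single bonds are upgraded to double/triple bonds and
    occasional aliphatic ring closures are added; hydrogens then fill every
    remaining valence.  Products that fail RDKit sanitization or exceed
    ``max_atoms`` total atoms are rejected and regenerated, so every emitted
    molecule passes the standard dataset filters unchanged.
    """
    if max_atoms > 64:
        raise ValueError("max_atoms must be <= 64")
    weights = dict(element_weights or _DEFAULT_WEIGHTS)
    if not any(_HEAVY_VALENCE.get(e, 0) >= 2 for e, w in weights.items() if w > 0):
        raise ValueError("element_weights admit no chain-forming (valence >= 2) element")
    elems = sorted(weights)
    probs = np.array([weights[e] for e in elems], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("element_weights must have positive total weight")
    probs /= probs.sum()

    rng = np.random.default_rng(seed)
    out: list[MolecularGraph] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 50 * n + 100:
            raise RuntimeError("molecule generation rejection rate too high")
        mol = _grow_molecule(rng, elems, probs, max_atoms, aromatic_prob,
                             ring_prob, unsaturation_prob)
        if mol is None or mol.GetNumAtoms() > max_atoms:
            continue
        out.append(MolecularGraph.from_rdkit(mol, mol_id=f"synth-{seed}-{len(out)}"))
    return out


def _grow_molecule(rng, elems, probs, max_atoms, aromatic_prob, ring_prob, unsat_prob):
    rw = Chem.RWMol()
    free: list[int] = []  # remaining valence per atom

    def add_atom(symbol):
        a = Chem.Atom(symbol)
        idx = rw.AddAtom(a)
        free.append(_HEAVY_VALENCE[symbol])
        return idx

    if rng.random() < aromatic_prob:
        ring = [add_atom("C") for _ in range(6)]
        for k in range(6):
            i, j = ring[k], ring[(k + 1) % 6]
            rw.AddBond(i, j, Chem.BondType.AROMATIC)
            rw.GetBondBetweenAtoms(i, j).SetIsAromatic(True)
        for idx in ring:
            rw.GetAtomWithIdx(idx).SetIsAromatic(True)
            free[idx] = 1  # one substituent slot per aromatic carbon
        n_heavy_target = int(rng.integers(6, max(7, max_atoms // 2 + 1)))
    else:
        add_atom(str(rng.choice(elems, p=probs)))
        n_heavy_target = int(rng.integers(2, max(3, max_atoms // 3 + 1)))

    while rw.GetNumAtoms() < n_heavy_target:
        anchors = [i for i, f in enumerate(free) if f >= 1]
        if not anchors:
            break
        anchor = int(rng.choice(anchors))
        new = add_atom(str(rng.choice(elems, p=probs)))
        rw.AddBond(anchor, new, Chem.BondType.SINGLE)
        free[anchor] -= 1
        free[new] -= 1

    # upgrade some single bonds between atoms with spare valence
    for bond in list(rw.GetBonds()):
        if bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if free[i] >= 1 and free[j] >= 1 and rng.random() < unsat_prob:
            if free[i] >= 2 and free[j] >= 2 and rng.random() < 0.25:
                bond.SetBondType(Chem.BondType.TRIPLE)
                free[i] -= 2
                free[j] -= 2
            else:
                bond.SetBondType(Chem.BondType.DOUBLE)
                free[i] -= 1
                free[j] -= 1

    # occasional aliphatic ring closure
    if rng.random() < ring_prob:
        open_idx = [i for i, f in enumerate(free) if f >= 1]
        rng.shuffle(open_idx)
        for a in open_idx:
            for b in open_idx:
                if b <= a or rw.GetBondBetweenAtoms(a, b) is not None:
                    continue
                path = Chem.GetShortestPath(rw.GetMol(), a, b)
                if 3 <= len(path) <= 6:
                    rw.AddBond(a, b, Chem.BondType.SINGLE)
                    free[a] -= 1
                    free[b] -= 1
                    break
            else:
                continue
            break

    try:
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        mol = Chem.AddHs(mol)
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def assign_shifts(
    mols: list[MolecularGraph],
    oracle: SyntheticShiftOracle,
    seed: int,
    nuclei: tuple[str, ...] = ("C13", "H1"),
    n_spectra: int = 1,
) -> list[ShiftAssignment]:
    """Oracle shifts plus seeded per-class Gaussian noise, per spectrum.

    With ``n_spectra > 1`` each molecule gets multiple spectra with fresh
    noise draws, emulating repeated measurements of the same nuclei.
    """
    nucleus_elem = {"C13": "C", "H1": "H"}
    rng = np.random.default_rng(seed)
    out: list[ShiftAssignment] = []
    for g in mols:
        for s in range(n_spectra):
            sid = f"{g.mol_id}-s{s}"
            for i, atom in enumerate(g.atoms):
                for nuc in nuclei:
                    if atom.element != nucleus_elem[nuc]:
                        continue
                    sd = oracle.noise_sd.get(oracle.noise_class(g, i), 0.0)
                    val = oracle.shift(g, i) + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                    out.append(
                        ShiftAssignment(
                            molecule_id=g.mol_id, spectrum_id=sid, atom_index=i,
                            nucleus=nuc, shift=float(val),
                        )
                    )
    return out


def write_dataset(
    mols: list[MolecularGraph],
    assignments: list[ShiftAssignment],
    outdir: str | Path,
    oracle: SyntheticShiftOracle | None = None,
) -> dict[str, Path]:
    """Write the SDF + assignments CSV dialect that ``nmrshift.io`` reads."""
    from . import io as dataset_io  # local import to avoid cycle at import time

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sdf": outdir / "molecules.sdf",
        "assignments": outdir / "assignments.csv",
    }
    dataset_io.write_sdf(mols, paths["sdf"])
    dataset_io.write_assignments_csv(assignments, paths["assignments"])
    if oracle is not None:
        paths["oracle"] = outdir / "oracle.json"
        paths["oracle"].write_text(oracle.to_json())
    return paths


def targets_from_assignments(
    mols: list[MolecularGraph],
    assignments: list[ShiftAssignment],
    nucleus: str,
) -> list[np.ndarray]:
    """Per-molecule per-atom target arrays (NaN unobserved) for one nucleus.

    Multiple spectra of the same nucleus are averaged into one target value.
    """
    by_mol: dict[str, dict[int, list[float]]] = {}
    for a in assignments:
        if a.nucleus != nucleus:
            continue
        by_mol.setdefault(a.molecule_id, {}).setdefault(a.atom_index, []).append(a.shift)
    out = []
    for g in mols:
        t = np.full(g.n_atoms, np.nan)
        for i, vals in by_mol.get(g.mol_id, {}).items():
            t[i] = float(np.mean(vals))
        out.append(t)
    return out
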