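"""Dataset ingestion: molecules, shift assignments, filters, splits.

Two assignment dialects are supported:

* a plain CSV sidecar with columns ``molecule_id, spectrum_id, atom_index,
  nucleus, shift`` (0-based atom indices; the canonical interchange format
  every tool in this package emits), and
* SD property tags in the nmrshiftdb2 style: a multi-record SDF whose
  records carry properties named like ``Spectrum 13C 0`` holding
  ``shift;atom_index`` pairs separated by ``|`` (atom indices 1-based in the
  tag, converted at this boundary).

Filtering follows the standard inclusion rules for connectivity-only shift
prediction: elements restricted to {H, C, O, N, P, S, F, Cl}, at most 64
atoms counting explicit hydrogens, and RDKit sanitization must succeed.
Train/test splits group molecules by stereo-free canonical SMILES so
duplicate structures (and stereoisomers) never straddle the split.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from .graphs import ELEMENTS, MolecularGraph

logger = logging.getLogger(__name__)

MAX_ATOMS = 64

_NUCLEI = ("C13", "H1")
_NUCLEUS_ELEMENT = {"C13": "C", "H1": "H"}
_TAG_RE = re.compile(r"^Spectrum (13C|1H)\b")
_TAG_NUCLEUS = {"13C": "C13", "1H": "H1"}


@dataclass(frozen=True)
class ShiftAssignment:
    """One observed chemical shift: (molecule, spectrum, atom, nucleus, ppm)."""

    molecule_id: str
    spectrum_id: str
    atom_index: int  # 0-based
    nucleus: str  # "C13" or "H1"
    shift: float

    def __post_init__(self):
        if self.nucleus not in _NUCLEI:
            raise ValueError(f"unknown nucleus {self.nucleus!r}")
        if not np.isfinite(self.shift):
            raise ValueError("shift must be finite")


@dataclass
class DatasetSplit:
    """Disjoint train/test molecule-id sets with their canonical keys."""

    train_ids: set[str]
    test_ids: set[str]
    canonical_key: dict[str, str]

    def __post_init__(self):
        if self.train_ids & self.test_ids:
            raise ValueError("train and test ids overlap")


@dataclass
class FilterReport:
    n_input: int = 0
    n_excluded_element: int = 0
    n_excluded_size: int = 0
    n_excluded_sanitize: int = 0
    n_retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


# ----------------------------------------------------------------------
# Loading
# ----------------------------------------------------------------------

def load_molecules(
    path: str | Path,
    assignment_source: str | Path | None = None,
) -> list[tuple[MolecularGraph, list[ShiftAssignment]]]:
    """Read a multi-record SDF plus shift assignments.

    ``assignment_source`` is either a CSV path (the canonical sidecar) or
    None, in which case assignments are parsed from nmrshiftdb2-style
    ``Spectrum ...`` property tags on each record.  Records that fail
    sanitization are skipped with a logged warning; assignments addressing
    out-of-range atoms are dropped (the molecule is kept).  Only molecules
    carrying at least one assignment are returned; hydrogens are explicit on
    every returned graph.
    """
    path = Path(path)
    sidecar = None
    if assignment_source is not None and Path(assignment_source).suffix.lower() == ".csv":
        sidecar = read_assignments_csv(assignment_source)

    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    out: list[tuple[MolecularGraph, list[ShiftAssignment]]] = []
    n_skipped = 0
    for rec_no, mol in enumerate(supplier):
        if mol is None:
            n_skipped += 1
            logger.warning("record %d: unparseable, skipped", rec_no)
            continue
        try:
            Chem.SanitizeMol(mol)
        except Exception as exc:
            n_skipped += 1
            logger.warning("record %d: sanitization failed (%s), skipped", rec_no, exc)
            continue
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol-{rec_no}"
        graph = MolecularGraph.from_rdkit(mol, mol_id=mol_id)
        if sidecar is not None:
            raw = [a for a in sidecar if a.molecule_id == mol_id]
        else:
            raw = _assignments_from_tags(mol, mol_id)
        assigns = []
        for a in raw:
            if not 0 <= a.atom_index < graph.n_atoms:
                logger.warning(
                    "%s: assignment to atom %d out of range (n=%d), dropped",
                    mol_id, a.atom_index, graph.n_atoms,
                )
                continue
            if graph.atoms[a.atom_index].element != _NUCLEUS_ELEMENT[a.nucleus]:
                logger.warning(
                    "%s: atom %d is %s, not the %s element, dropped",
                    mol_id, a.atom_index, graph.atoms[a.atom_index].element, a.nucleus,
                )
                continue
            assigns.append(a)
        if assigns:
            out.append((graph, assigns))
    if n_skipped:
        logger.info("skipped %d unreadable records", n_skipped)
    return out


def read_sdf(path: str | Path) -> list[MolecularGraph]:
    """Read every sanitizable record of an SDF as a graph (no assignments)."""
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    out = []
    for rec_no, mol in enumerate(supplier):
        if mol is None:
            logger.warning("record %d: unparseable, skipped", rec_no)
            continue
        try:
            Chem.SanitizeMol(mol)
        except Exception as exc:
            logger.warning("record %d: sanitization failed (%s), skipped", rec_no, exc)
            continue
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol-{rec_no}"
        out.append(MolecularGraph.from_rdkit(mol, mol_id=mol_id))
    return out


def _assignments_from_tags(mol: Chem.Mol, mol_id: str) -> list[ShiftAssignment]:
    """Parse ``Spectrum 13C <id>`` style tags; 1-based indices in the tag."""
    out = []
    for prop in mol.GetPropNames():
        m = _TAG_RE.match(prop)
        if not m:
            continue
        nucleus = _TAG_NUCLEUS[m.group(1)]
        spectrum_id = f"{mol_id}:{prop}"
        for entry in mol.GetProp(prop).split("|"):
            entry = entry.strip()
            if not entry:
                continue
            parts = entry.split(";")
            try:
                shift = float(parts[0])
                atom_1based = int(float(parts[-1]))
            except (ValueError, IndexError):
                logger.warning("%s: malformed tag entry %r, dropped", mol_id, entry)
                continue
            out.append(
                ShiftAssignment(
                    molecule_id=mol_id, spectrum_id=spectrum_id,
                    atom_index=atom_1based - 1, nucleus=nucleus, shift=shift,
                )
            )
    return out


def read_assignments_csv(path: str | Path) -> list[ShiftAssignment]:
    """Read the canonical CSV sidecar (0-based atom indices)."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                ShiftAssignment(
                    molecule_id=row["molecule_id"],
                    spectrum_id=row["spectrum_id"],
                    atom_index=int(row["atom_index"]),
                    nucleus=row["nucleus"],
                    shift=float(row["shift"]),
                )
            )
    return out


def write_assignments_csv(assignments: list[ShiftAssignment], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["molecule_id", "spectrum_id", "atom_index", "nucleus", "shift"])
        for a in assignments:
            w.writerow([a.molecule_id, a.spectrum_id, a.atom_index, a.nucleus, repr(a.shift)])


def write_sdf(mols: list[MolecularGraph], path: str | Path) -> None:
    """Write graphs as a V2000 multi-record SDF with explicit hydrogens."""
    writer = Chem.SDWriter(str(path))
    try:
        for g in mols:
            mol = Chem.Mol(g.to_rdkit())
            mol.SetProp("_Name", g.mol_id)
            writer.write(mol)
    finally:
        writer.close()


# ----------------------------------------------------------------------
# Filtering
# ----------------------------------------------------------------------

def filter_dataset(
    mols: list[MolecularGraph],
    max_atoms: int = MAX_ATOMS,
    elements: tuple[str, ...] = ELEMENTS,
) -> tuple[list[MolecularGraph], FilterReport]:
    """Apply the element / size / sanitization inclusion rules.

    The atom cap counts all vertices including explicit hydrogens.  Returns
    the survivors plus per-rule exclusion counts; filtering is idempotent.
    """
    report = FilterReport(n_input=len(mols))
    allowed = set(elements)
    kept = []
    for g in mols:
        if any(a.element not in allowed for a in g.atoms):
            report.n_excluded_element += 1
            continue
        if g.n_atoms > max_atoms:
            report.n_excluded_size += 1
            continue
        try:
            g.to_rdkit()  # re-runs sanitization for graphs built by hand
        except Exception:
            report.n_excluded_sanitize += 1
            continue
        kept.append(g)
    report.n_retained = len(kept)
    return kept, report


# ----------------------------------------------------------------------
# Splitting
# ----------------------------------------------------------------------

def split_by_structure(
    mols: list[MolecularGraph], test_fraction: float, seed: int
) -> DatasetSplit:
    """Structure-grouped train/test split.

    Molecules sharing a stereo-free canonical SMILES form one group; whole
    groups are shuffled (seeded) and assigned to the test side until its
    molecule count reaches ``test_fraction`` of the total, so duplicates can
    never leak across the split.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    keys = {g.mol_id: g.canonical_key() for g in mols}
    groups: dict[str, list[str]] = {}
    for mol_id, key in keys.items():
        groups.setdefault(key, []).append(mol_id)
    group_keys = sorted(groups)
    rng = np.random.default_rng(seed)
    rng.shuffle(group_keys)
    n_total = len(mols)
    target = test_fraction * n_total
    test_ids: set[str] = set()
    for key in group_keys:
        if len(test_ids) >= target:
            break
        # take the group if it brings us closer to the target than skipping it
        if abs(len(test_ids) + len(groups[key]) - target) <= abs(len(test_ids) - target):
            test_ids.update(groups[key])
    train_ids = {g.mol_id for g in mols} - test_ids
    return DatasetSplit(train_ids=train_ids, test_ids=test_ids, canonical_key=keys)


# ----------------------------------------------------------------------
# Intrinsic measurement variability
# ----------------------------------------------------------------------

def intrinsic_variability(
    assignments: list[ShiftAssignment], nucleus: str
) -> tuple[float, int]:
    """Repeated-measurement noise floor for one nucleus type.

    Groups observations by (molecule, atom); taking each nucleus's "true"
    value to be the mean of its measurements, returns the mean absolute
    deviation over all observations belonging to nuclei measured more than
    once, together with the count of such nuclei.  With no repeats, returns
    (nan, 0).
    """
    groups: dict[tuple[str, int], list[float]] = {}
    for a in assignments:
        if a.nucleus != nucleus:
            continue
        groups.setdefault((a.molecule_id, a.atom_index), []).append(a.shift)
    deviations: list[float] = []
    n_repeated = 0
    for vals in groups.values():
        if len(vals) < 2:
            continue
        n_repeated += 1
        mean = float(np.mean(vals))
        deviations.extend(abs(v - mean) for v in vals)
    if n_repeated == 0:
        return float("nan"), 0
    return float(np.mean(deviations)), n_repeated
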