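import numpy as np
import pytest
from rdkit import Chem

from nmrshift.graphs import MolecularGraph


def graph_from_smiles(smiles: str, mol_id: str = "") -> MolecularGraph:
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    return MolecularGraph.from_rdkit(mol, mol_id=mol_id or smiles)


@pytest.fixture(scope="session")
def methane():
    return graph_from_smiles("C", "methane")


@pytest.fixture(scope="session")
def ethane():
    return graph_from_smiles("CC", "ethane")


@pytest.fixture(scope="session")
def ethene():
    return graph_from_smiles("C=C", "ethene")


@pytest.fixture(scope="session")
def ethanol():
    return graph_from_smiles("CCO", "ethanol")


@pytest.fixture(scope="session")
def benzene():
    return graph_from_smiles("c1ccccc1", "benzene")


@pytest.fixture(scope="session")
def chloromethane():
    return graph_from_smiles("CCl", "chloromethane")


@pytest.fixture(scope="session")
def small_molecule_set():
    """A seeded, reusable pool of small random molecules."""
    from nmrshift.synthetic import generate_molecules

    return generate_molecules(40, seed=100, max_atoms=14, aromatic_prob=0.3, ring_prob=0.3)


def random_adjacency(rng: np.random.Generator, n: int, m: int, n_channels: int = 4):
    """Random symmetric 0/1 channels (each edge in exactly one channel), padded to m."""
    g = np.zeros((n_channels, m, m))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.5:
                k = rng.integers(n_channels)
                g[k, i, j] = g[k, j, i] = 1.0
    mask = np.zeros(m)
    mask[:n] = 1.0
    return g, mask
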