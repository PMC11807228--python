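import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from plignet import SyntheticSpec, build_graph, generate_dataset

ALA_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.575   5.515  -4.201  1.00  0.00           C
ATOM      4  O   ALA A   1       9.653   4.826  -4.630  1.00  0.00           O
ATOM      5  CB  ALA A   1      12.919   5.241  -5.092  1.00  0.00           C
END
"""

TWO_CHAIN_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O
TER
ATOM      5  N   SER B   1      10.000   0.000   0.000  1.00  0.00           N
ATOM      6  CA  SER B   1      11.458   0.000   0.000  1.00  0.00           C
ATOM      7  C   SER B   1      12.009   1.420   0.000  1.00  0.00           C
ATOM      8  O   SER B   1      11.251   2.390   0.000  1.00  0.00           O
ATOM      9  CB  SER B   1      12.009  -0.767  -1.208  1.00  0.00           C
ATOM     10  OG  SER B   1      11.469  -2.079  -1.251  1.00  0.00           O
END
"""


def sdf_from_smiles(smiles: str, path: str) -> None:
    mol = Chem.MolFromSmiles(smiles)
    AllChem.Compute2DCoords(mol)
    writer = Chem.SDWriter(str(path))
    writer.write(mol)
    writer.close()


@pytest.fixture
def ala_pdb(tmp_path):
    p = tmp_path / "ala.pdb"
    p.write_text(ALA_PDB)
    return str(p)


@pytest.fixture
def two_chain_pdb(tmp_path):
    p = tmp_path / "two_chain.pdb"
    p.write_text(TWO_CHAIN_PDB)
    return str(p)


@pytest.fixture
def ethanol_sdf(tmp_path):
    p = tmp_path / "ethanol.sdf"
    sdf_from_smiles("CCO", p)
    return str(p)


@pytest.fixture
def benzene_sdf(tmp_path):
    p = tmp_path / "benzene.sdf"
    sdf_from_smiles("c1ccccc1", p)
    return str(p)


@pytest.fixture
def selenium_sdf(tmp_path):
    p = tmp_path / "selenoether.sdf"
    sdf_from_smiles("C[Se]C", p)
    return str(p)


@pytest.fixture(scope="session")
def small_dataset():
    """60 labeled synthetic complexes shared across tests (read-only)."""
    complexes, weights = generate_dataset(SyntheticSpec(n_complexes=60, seed=11))
    return complexes, weights


@pytest.fixture(scope="session")
def small_graphs(small_dataset):
    complexes, _ = small_dataset
    return [build_graph(c) for c in complexes]


def rigid_motion(coords: np.ndarray, seed: int = 0, mirror: bool = False):
    """A random rotation (+ optional mirror) and translation."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(3, 3))
    q, _ = np.linalg.qr(a)
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    if mirror:
        q[:, 0] *= -1
    t = rng.uniform(-20, 20, size=3)
    return coords @ q.T + t
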