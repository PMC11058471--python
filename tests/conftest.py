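import numpy as np
import pytest

import phylotda as pt

TWO_RESIDUE_PDB = """\
ATOM      1  N   GLY A   1       0.000   1.000   0.000  1.00 95.00           N
ATOM      2  CA  GLY A   1       1.000   0.000   0.000  1.00 95.00           C
ATOM      3  C   GLY A   1       2.000   0.500   0.000  1.00 95.00           C
ATOM      4  O   GLY A   1       2.000   1.700   0.000  1.00 95.00           O
ATOM      5  H   GLY A   1       0.000   2.000   0.000  1.00 95.00           H
ATOM      6  N   ALA A   2       3.000   0.000   0.000  1.00 60.00           N
ATOM      7  CA  ALA A   2       4.000   0.500   0.500  1.00 60.00           C
ATOM      8  C   ALA A   2       5.000   0.000   0.000  1.00 60.00           C
ATOM      9  O   ALA A   2       5.500   1.000   0.000  1.00 60.00           O
ATOM     10  CB  ALA A   2       4.200   2.000   0.500  1.00 60.00           C
HETATM   11  O   HOH A 101       9.000   9.000   9.000  1.00  0.00           O
END
"""


@pytest.fixture
def two_residue_pdb() -> str:
    return TWO_RESIDUE_PDB


@pytest.fixture
def two_residue_structure() -> pt.ProteinStructure:
    return pt.read_structure(TWO_RESIDUE_PDB, id="toy")


def random_cloud(rng: np.random.Generator, n: int, scale: float = 3.0) -> np.ndarray:
    return rng.normal(size=(n, 3)) * scale


@pytest.fixture(scope="session")
def small_family() -> pt.SyntheticFamily:
    return pt.make_family(
        pt.SyntheticFamilyConfig(n_taxa=7, seq_length=60, indel_rate=3.0, seed=11)
    )


@pytest.fixture(scope="session")
def small_bundle(small_family) -> pt.FamilyBundle:
    return pt.FamilyBundle.from_synthetic(small_family, "fam0")
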