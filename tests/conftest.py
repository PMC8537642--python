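import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from nbrank.featset import FeatureSchema
from nbrank.structio import Atom, ComplexStructure, Residue
from nbrank.synthpose import SyntheticConfig, generate_dataset, make_native

TOY_PDB = """\
HEADER    TOY COMPLEX
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  H   ALA A   1       0.500   0.900   0.000  1.00  0.00           H
ATOM      6  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      7  CA  GLY A   2       3.988   2.839   0.000  1.00  0.00           C
ATOM      8  C   GLY A   2       5.504   2.693   0.000  1.00  0.00           C
ATOM      9  O   GLY A   2       6.030   1.580   0.000  1.00  0.00           O
HETATM   10  N   MSE A   3       6.232   3.810   0.000  1.00  0.00           N
HETATM   11  CA  MSE A   3       7.684   3.810   0.000  1.00  0.00           C
HETATM   12 SE   MSE A   3       8.400   5.500   0.000  1.00  0.00          SE
ATOM     13  N   CYS H  10       2.000   0.000   4.000  1.00  0.00           N
ATOM     14  CA  CYS H  10       3.458   0.000   4.000  1.00  0.00           C
ATOM     15  SG  CYS H  10       4.100   1.600   4.200  1.00  0.00           S
ATOM     16  HG  CYS H  10       4.500   1.900   4.300  1.00  0.00           H
ATOM     17  N   TRP H  11       5.000   0.500   4.000  1.00  0.00           N
ATOM     18  CA  TRP H  11       6.458   0.500   4.000  1.00  0.00           C
ATOM     19  C   TRP H  11       7.000   1.900   4.000  1.00  0.00           C
ATOM     20  N   LYS H  12A      8.300   2.100   4.000  1.00  0.00           N
ATOM     21  CA  LYS H  12A      9.300   3.100   4.000  1.00  0.00           C
TER
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


def single_atom_residue(chain_id, resseq, name3, xyz, atom_name="CA"):
    return Residue(chain_id, resseq, "", name3, [Atom(atom_name, atom_name[0], np.array(xyz, float))])


def two_point_complex(distance: float) -> ComplexStructure:
    """One antigen residue and one nanobody residue a given distance apart."""
    return ComplexStructure(
        antigen=[single_atom_residue("A", 1, "ALA", (0, 0, 0))],
        nanobody=[single_atom_residue("H", 1, "GLY", (distance, 0, 0))],
    )


@pytest.fixture(scope="session")
def contact_schema():
    return FeatureSchema(blocks=("contact", "property"))


@pytest.fixture(scope="session")
def tiny_native():
    """One deterministic synthetic native complex with its CDR spans."""
    config = SyntheticConfig(seed=7)
    return make_native(config, 0)


@pytest.fixture(scope="session")
def small_dataset(contact_schema):
    """3-complex synthetic dataset shared by unit tests (fast)."""
    config = SyntheticConfig(
        n_complexes=3, parents_per_complex=6, refined_per_parent=3, seed=11
    )
    records, manifest, parent_native, truth = generate_dataset(config, contact_schema)
    return records, manifest, parent_native, truth
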