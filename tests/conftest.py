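import numpy as np
import pytest

from sdpnet.alignment_io import alignment_from_records
from sdpnet.grouping import GroupAssignment
from sdpnet.synthetic_data import (
    CsiSpec,
    PairSpec,
    SyntheticTruth,
    generate,
)


@pytest.fixture
def tiny_alignment():
    return alignment_from_records(
        [("s1", "AC-D"), ("s2", "AC-D"), ("s3", "GCAD")]
    )


@pytest.fixture
def two_group_assignment():
    return GroupAssignment(
        groups={
            "G1": frozenset({"a1", "a2"}),
            "G2": frozenset({"b1", "b2"}),
        }
    )


@pytest.fixture(scope="session")
def background_dataset():
    """Two clades of 60 sequences, 60 columns, no planted signal."""
    return generate({"A": 60, "B": 60}, 60, SyntheticTruth(seed=101))


@pytest.fixture(scope="session")
def planted_dataset():
    """Two clades of 100, four coupled diagnostic pairs and one insert."""
    truth = SyntheticTruth(
        seed=202,
        planted_pairs=tuple(
            PairSpec(col_i=5 + 4 * k, col_j=7 + 4 * k, rho=1.0,
                     diagnostic=True, q=0.9)
            for k in range(4)
        ),
        planted_csis=(
            CsiSpec(clade="A", col_start=45, col_end=69,
                    presence_prob=1.0, length_jitter=0),
        ),
    )
    return generate({"A": 100, "B": 100}, 80, truth)


SYNTHETIC_PDB = """\
HEADER    SYNTHETIC TEST STRUCTURE
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  CB  ALA A   1       2.000  -1.000   1.000  1.00  0.00           C
ATOM      5  N   GLY A   2       3.000   3.000   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       4.000   4.000   0.000  1.00  0.00           C
ATOM      7  N   SER A   3      10.000  10.000  10.000  1.00  0.00           N
ATOM      8  CA ASER A   3      11.000  10.000  10.000  0.70  0.00           C
ATOM      9  CA BSER A   3      19.000  10.000  10.000  0.30  0.00           C
ATOM     10  OG  SER A   3      11.000  11.000  10.000  1.00  0.00           O
ATOM     11  N   LEU B   1       0.000   0.000   5.000  1.00  0.00           N
ATOM     12  CA  LEU B   1       1.000   0.000   5.000  1.00  0.00           C
HETATM   13 ZN    ZN A 101       5.000   5.000   5.000  1.00  0.00          ZN
END
"""


@pytest.fixture
def synthetic_pdb(tmp_path):
    """Hand-set coordinates; synthetic stand-in for a crystal structure."""
    path = tmp_path / "synthetic_structure.pdb"
    path.write_text(SYNTHETIC_PDB)
    return path
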