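"""Shared fixtures: tiny hand-written structures and synthetic systems."""

import numpy as np
import pytest

from groovedyn.io import read_structure
from groovedyn.synthetic import ToyGrooveSpec, build_toy_groove, truncate_peptide

GLYCINE_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  O   GLY A   1       2.100   1.100   0.000  1.00  0.00           O
END
"""

TWO_CHAIN_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  N   GLY A   2       3.000   1.000   0.000  1.00  0.00           N
ATOM      4  CA  GLY A   2       4.458   1.000   0.000  1.00  0.00           C
ATOM      5  CA  SER C   1       9.000   5.000   1.000  1.00  0.00           C
END
"""


@pytest.fixture
def glycine_pdb(tmp_path):
    p = tmp_path / "gly.pdb"
    p.write_text(GLYCINE_PDB)
    return p


@pytest.fixture
def two_chain_pdb(tmp_path):
    p = tmp_path / "two_chain.pdb"
    p.write_text(TWO_CHAIN_PDB)
    return p


@pytest.fixture
def two_chain_system(two_chain_pdb):
    return read_structure(two_chain_pdb)


@pytest.fixture(scope="session")
def toy_groove():
    return build_toy_groove(ToyGrooveSpec())


@pytest.fixture(scope="session")
def toy_groove_truncated(toy_groove):
    top, frame, rows = toy_groove
    return truncate_peptide(top, frame, rows, n_remove_c=1)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
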