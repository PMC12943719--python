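import numpy as np
import pytest

from ligpocket import build_toy_pocket

WATER_PDB = """\
ATOM      1  OW  SOL W   1       0.000   0.000   0.000  1.00  0.00           O
ATOM      2  HW1 SOL W   1       0.960   0.000   0.000  1.00  0.00           H
ATOM      3  HW2 SOL W   1      -0.240   0.930   0.000  1.00  0.00           H
END
"""

METHANE_PDB = """\
HETATM    1  C1  MTH L   1       0.000   0.000   0.000  1.00  0.00           C
HETATM    2  H1  MTH L   1       1.090   0.000   0.000  1.00  0.00           H
HETATM    3  H2  MTH L   1      -0.363   1.027   0.000  1.00  0.00           H
HETATM    4  H3  MTH L   1      -0.363  -0.514   0.890  1.00  0.00           H
HETATM    5  H4  MTH L   1      -0.363  -0.514  -0.890  1.00  0.00           H
END
"""


@pytest.fixture
def water_pdb_text():
    return WATER_PDB


@pytest.fixture
def methane_pdb_text():
    return METHANE_PDB


@pytest.fixture(scope="session")
def toy_pocket():
    return build_toy_pocket(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng):
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def rigid_transform(cplx, rotation, translation):
    coords = cplx.coords @ rotation.T + translation
    return cplx.with_coords(coords)
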