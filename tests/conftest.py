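import numpy as np
import pytest

from mdinteract.structure_io import AtomRecord, Trajectory

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  O   HOH A   2       3.000   0.000   0.000  1.00  0.00           O
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1       0.000   0.000   1.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.500   0.000   1.000  1.00  0.00           C
ATOM      3  O   HOH A   2       3.000   0.000   1.000  1.00  0.00           O
ENDMDL
END
"""

SINGLE_MODEL_PDB = """\
ATOM      1  ZN  ZN  A   1       0.000   0.000   0.000  1.00  0.00          ZN
ATOM      2  O   HOH A   2       2.030   0.000   0.000  1.00  0.00           O
END
"""

GLU_PDB = """\
ATOM      1  CA  GLU A 177       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CB  GLU A 177       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  CG  GLU A 177       2.200   1.200   0.000  1.00  0.00           C
ATOM      4  CD  GLU A 177       3.700   1.200   0.000  1.00  0.00           C
ATOM      5  OE1 GLU A 177       4.400   0.200   0.000  1.00  0.00           O
ATOM      6  OE2 GLU A 177       4.300   2.400   0.000  1.00  0.00           O
ATOM      7  HA  GLU A 177       0.000   1.000   0.500  1.00  0.00           H
END
"""


@pytest.fixture
def two_model_pdb(tmp_path):
    p = tmp_path / "two_model.pdb"
    p.write_text(TWO_MODEL_PDB)
    return p


@pytest.fixture
def single_model_pdb(tmp_path):
    p = tmp_path / "single.pdb"
    p.write_text(SINGLE_MODEL_PDB)
    return p


@pytest.fixture
def glu_pdb(tmp_path):
    p = tmp_path / "glu.pdb"
    p.write_text(GLU_PDB)
    return p


def make_trajectory(coords_per_frame, elements=None, residue_numbers=None,
                    names=None, residue_names=None):
    """Build a small Trajectory from raw coordinate frames."""
    frames = [np.asarray(f, dtype=float) for f in coords_per_frame]
    n = frames[0].shape[0]
    elements = elements or ["C"] * n
    residue_numbers = residue_numbers or [1] * n
    names = names or [f"{e}{i + 1}" for i, e in enumerate(elements)]
    residue_names = residue_names or ["UNK"] * n
    topo = [
        AtomRecord(serial=i + 1, name=names[i], element=elements[i],
                   residue_name=residue_names[i], residue_number=residue_numbers[i])
        for i in range(n)
    ]
    return Trajectory(topo, frames)


def random_rotation(rng):
    """Uniform random proper rotation matrix (QR-based)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
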