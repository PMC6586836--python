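import numpy as np
import pytest

from tmdselect.structure import ResidueRecord, StructureModel

TINY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       1.986  -0.760  -1.221  1.00  0.00           C
ATOM      6  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      7  CA  GLY A   2       3.988   2.839   0.000  1.00  0.00           C
ATOM      8  C   GLY A   2       5.504   2.693   0.000  1.00  0.00           C
ATOM      9  O   GLY A   2       6.030   1.580   0.000  1.00  0.00           O
ATOM     10  N   LEU A   3       6.235   3.800   0.000  1.00  0.00           N
ATOM     11  CA  LEU A   3       7.694   3.776   0.000  1.00  0.00           C
ATOM     12  C   LEU A   3       8.253   5.192   0.000  1.00  0.00           C
ATOM     13  O   LEU A   3       7.510   6.177   0.000  1.00  0.00           O
ATOM     14  CB  LEU A   3       8.232   3.005   1.215  1.00  0.00           C
TER
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    p = tmp_path / "tiny.pdb"
    p.write_text(TINY_PDB)
    return p


def toy_model(coords, model_id="toy", aa=None, cb=None):
    """Model from bare Cα coordinates (and optional Cβ rows); defaults to
    poly-glycine so the Cα fallback is the intended representative atom."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    aa = aa or "G" * n
    residues = [
        ResidueRecord(
            index=k + 1,
            aa=aa[k],
            ca=coords[k],
            cb=None if cb is None or cb[k] is None else np.asarray(cb[k], float),
        )
        for k in range(n)
    ]
    return StructureModel(model_id, residues)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
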