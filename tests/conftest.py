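"""Shared fixtures: hand-written PDB texts and synthetic-world factories."""

from __future__ import annotations

import numpy as np
import pytest

from parchlab import (
    Atom,
    ProteinStructure,
    ResidueRecord,
    SyntheticSpec,
    generate_world,
)

GLY_ALA_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  H   GLY A   1      -0.500  -0.800   0.000  1.00  0.00           H
ATOM      6  N   ALA A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      7  CA  ALA A   2       3.988   2.839   0.000  1.00  0.00           C
ATOM      8  C   ALA A   2       5.504   2.693   0.000  1.00  0.00           C
ATOM      9  O   ALA A   2       6.030   1.580   0.000  1.00  0.00           O
ATOM     10  CB  ALA A   2       3.511   3.672   1.192  1.00  0.00           C
END
"""

HOH_ONLY_PDB = """\
HETATM    1  O   HOH W   1       0.000   0.000   0.000  1.00  0.00           O
HETATM    2  O   HOH W   2       3.100   0.000   0.000  1.00  0.00           O
END
"""

# three models of a single glycine, shifted along x by the model number
MULTIMODEL_PDB = "".join(
    f"""MODEL     {k + 1:4d}
ATOM      1  N   GLY A   1       {k:.3f}   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       {k + 1.458:.3f}   0.000   0.000  1.00  0.00           C
ENDMDL
"""
    for k in range(3)
) + "END\n"

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  SER A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  CB ASER A   1       2.000   1.000   0.000  0.40  0.00           C
ATOM      4  CB BSER A   1       2.000  -1.000   0.000  0.60  0.00           C
END
"""

NONSTANDARD_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
HETATM    3 SE   MSE A   2       5.000   0.000   0.000  1.00  0.00          SE
END
"""


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


@pytest.fixture
def gly_ala_pdb(tmp_path):
    return _write(tmp_path, "gly_ala.pdb", GLY_ALA_PDB)


@pytest.fixture
def hoh_only_pdb(tmp_path):
    return _write(tmp_path, "hoh_only.pdb", HOH_ONLY_PDB)


@pytest.fixture
def multimodel_pdb(tmp_path):
    return _write(tmp_path, "multimodel.pdb", MULTIMODEL_PDB)


@pytest.fixture
def altloc_pdb(tmp_path):
    return _write(tmp_path, "altloc.pdb", ALTLOC_PDB)


@pytest.fixture
def nonstandard_pdb(tmp_path):
    return _write(tmp_path, "nonstandard.pdb", NONSTANDARD_PDB)


def make_point_structure(aa_coords, structure_id="toy") -> ProteinStructure:
    """Structure of single-heavy-atom residues from [(aa, (x, y, z)), ...]."""
    residues = [
        ResidueRecord(
            chain_id="A", seq_index=i + 1, aa_type=aa,
            atoms=[Atom(name="CA", element="C", coords=np.asarray(xyz, dtype=float))],
        )
        for i, (aa, xyz) in enumerate(aa_coords)
    ]
    return ProteinStructure(id=structure_id, residues=residues)


@pytest.fixture
def point_structure():
    """Factory for single-atom-per-residue toy structures."""
    return make_point_structure


@pytest.fixture(scope="session")
def small_world():
    """A 150-residue synthetic world with three annealing replicates."""
    return generate_world(SyntheticSpec(n_residues=150, seed=7))
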