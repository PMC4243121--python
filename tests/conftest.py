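import numpy as np
import pytest

from ssbdsb import synth, tunnels


@pytest.fixture(scope="session")
def template70():
    return synth.make_template_like(70, fold_seed=1)


@pytest.fixture(scope="session")
def template80():
    return synth.make_template_like(80, fold_seed=2)


@pytest.fixture(scope="session")
def straight_phantom():
    return synth.make_phantom(synth.PhantomSpec(kind="straight_channel", seed=0))


@pytest.fixture(scope="session")
def straight_tunnels(straight_phantom):
    chain, _ = straight_phantom
    return tunnels.detect_tunnels(chain)


@pytest.fixture(scope="session")
def bent_phantom():
    return synth.make_phantom(synth.PhantomSpec(kind="bent_channel", seed=0))


@pytest.fixture
def tiny_pdb(tmp_path):
    """Protein chain + DNA + water + two models, with an altloc pair."""
    text = """MODEL        1
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.000   2.500   3.100  1.00  0.00           C
ATOM      3  C   ALA A   1       3.200   2.100   3.000  1.00  0.00           C
ATOM      4  CA AGLY A   2       5.000   5.000   5.000  0.40  0.00           C
ATOM      5  CA BGLY A   2       5.500   5.000   5.000  0.60  0.00           C
ATOM      6  CA  SER A   3       8.000   5.200   5.100  1.00  0.00           C
ATOM      7  O5' DA  B   1       0.000   0.000   9.000  1.00  0.00           O
ATOM      8  O   HOH C   1       0.000   0.000   1.000  1.00  0.00           O
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1      11.000  12.000  13.000  1.00  0.00           N
ATOM      2  CA  ALA A   1      12.000  12.500  13.100  1.00  0.00           C
ATOM      3  C   ALA A   1      13.200  12.100  13.000  1.00  0.00           C
ATOM      4  CA  GLY A   2      15.000  15.000  15.000  1.00  0.00           C
ATOM      5  CA  SER A   3      18.000  15.200  15.100  1.00  0.00           C
ENDMDL
END
"""
    path = tmp_path / "tiny.pdb"
    path.write_text(text)
    return path
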