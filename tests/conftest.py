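import numpy as np
import pytest

from trefoilforge import symmetry as sym
from trefoilforge import synthetic as syn

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


TOY_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  N   ASP A   2       3.326   1.557   0.000  1.00  0.00           N
ATOM      5  CA  ASP A   2       3.970   2.862   0.123  1.00  0.00           C
ATOM      6  C   ASP A   2       5.475   2.720   0.250  1.00  0.00           C
ATOM      7  N   GLY A   3       6.150   3.850   0.300  1.00  0.00           N
ATOM      8  CA  GLY A   3       7.598   3.905   0.450  1.00  0.00           C
ATOM      9  C   GLY A   3       8.200   5.280   0.600  1.00  0.00           C
TER      10
END
"""


@pytest.fixture(scope="session")
def toy_pdb(tmp_path_factory):
    path = tmp_path_factory.mktemp("pdb") / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA ASER A   1       1.400   0.000   0.000  0.60  0.00           C
ATOM      3  CA BSER A   1       1.600   0.100   0.000  0.40  0.00           C
ATOM      4  C   SER A   1       2.000   1.400   0.000  1.00  0.00           C
TER       5
END
"""


@pytest.fixture(scope="session")
def altloc_pdb(tmp_path_factory):
    path = tmp_path_factory.mktemp("pdb") / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path


@pytest.fixture(scope="session")
def exact_c3():
    """Noise-free exactly C3-symmetric trefoil fixture, L=47."""
    return syn.make_c3_backbone(syn.TrefoilParams(L=47, seed=1))


@pytest.fixture(scope="session")
def exact_c3_repeats(exact_c3):
    rdef = sym.RepeatDefinition([("A", 1, 47), ("B", 1, 47), ("C", 1, 47)])
    return sym.extract_repeats(exact_c3, rdef)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rigid_transform(rng):
    from scipy.spatial.transform import Rotation

    from trefoilforge.superpose import RigidTransform

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.normal(0, 10.0, 3)
    return RigidTransform(R, t)
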