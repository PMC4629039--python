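import numpy as np
import pytest

from fdsw import load_substitution_matrix

TOY_MATRIX_TEXT = """\
# toy two-residue matrix
   A  B
A  1 -1
B -1  1
"""


@pytest.fixture(scope="session")
def blosum62():
    return load_substitution_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def toy_matrix(tmp_path_factory):
    path = tmp_path_factory.mktemp("matrices") / "toy.mat"
    path.write_text(TOY_MATRIX_TEXT)
    return load_substitution_matrix(path)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, length, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(rng.choice(list(alphabet), size=length)) if length else ""
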