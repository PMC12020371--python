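import numpy as np
import pytest

from pdfl.flag_complex import build_flag_complex
from pdfl.synthetic_fixtures import FixtureSpec, directed_clique, random_complex


@pytest.fixture
def four_clique():
    """The complete directed 4-clique on vertices a, b, c, d."""
    return directed_clique(4)


@pytest.fixture
def four_clique_complex(four_clique):
    return build_flag_complex(four_clique, max_dim=3)


@pytest.fixture
def small_complex():
    """A small deterministic protein-ligand-like complex (8 + 4 atoms)."""
    c, _ = random_complex(FixtureSpec(seed=3, n_protein=8, n_ligand=4))
    return c


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
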