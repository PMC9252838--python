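import numpy as np
import pytest

from protpeel.contact_map import compute_contact_map
from protpeel.fixtures import FixtureSpec, make_globule_chain


@pytest.fixture(scope="session")
def two_globule():
    """Two 30-residue globules joined by a 5-residue linker (seed 1)."""
    return make_globule_chain(FixtureSpec([30, 30], [5], seed=1))


@pytest.fixture(scope="session")
def two_globule_cm(two_globule):
    return compute_contact_map(two_globule.structure)


@pytest.fixture(scope="session")
def three_globule():
    return make_globule_chain(FixtureSpec([25, 25, 25], [5, 5], seed=3))


@pytest.fixture(scope="session")
def three_globule_cm(three_globule):
    return compute_contact_map(three_globule.structure)


def random_contact_map(rng, n):
    """Symmetric random matrix in [0,1] with zero diagonal (test helper)."""
    from protpeel.contact_map import ContactMap

    m = rng.random((n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return ContactMap(probs=m, d0=8.0, delta=1.5)
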