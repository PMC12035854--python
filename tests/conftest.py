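import numpy as np
import pytest

from fibrinpull import em, sop, synthetic
from fibrinpull.structure import make_toy_chain


@pytest.fixture(scope="session")
def components():
    """The default five-type component table (simulation statistics)."""
    return synthetic.default_components()


@pytest.fixture(scope="session")
def truth_model(components):
    return em.model_from_components(components)


@pytest.fixture(scope="session")
def mixture_5000(components):
    """One n=5000 draw from the default mixture (seed 0)."""
    return synthetic.sample_mixture(components, 5000, seed=0)


@pytest.fixture(scope="session")
def helix30():
    st = make_toy_chain(30, "helix")
    return st, sop.build_topology(st)


@pytest.fixture(scope="session")
def two_strand20():
    st = make_toy_chain(20, "two_strand")
    return st, sop.build_topology(st)
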