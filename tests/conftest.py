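import numpy as np
import pytest

from bfbdna.defaults import plausibility_forcefield
from bfbdna.dynamics import build_ideal_duplex
from bfbdna.topology import build_duplex_topology


@pytest.fixture(scope="session")
def ff():
    """Shipped plausibility force field (gaussian fan-bond mode)."""
    return plausibility_forcefield()


@pytest.fixture(scope="session")
def duplex8():
    """8-bp duplex: topology, ideal coordinates, and a thermally perturbed copy."""
    seq = "ACGTTGCA"
    topo = build_duplex_topology(seq)
    ideal = build_ideal_duplex(8)
    rng = np.random.default_rng(42)
    perturbed = ideal + rng.normal(scale=0.03, size=ideal.shape)
    return topo, ideal, perturbed
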