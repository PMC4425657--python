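import numpy as np
import pytest

from prime_dmd import (AB17_42, SystemTopology, build_chain, default_forcefield,
                       generate_initial_configuration)


@pytest.fixture(scope="session")
def ff():
    return default_forcefield()


@pytest.fixture(scope="session")
def ab_chain(ff):
    return build_chain(AB17_42, ff.residues, numbering_offset=17)


@pytest.fixture(scope="session")
def ab_top8(ab_chain):
    return SystemTopology.replicate(ab_chain, 8)


@pytest.fixture(scope="session")
def fresh_coils(ab_top8, ff):
    """The 8-chain random-coil initial configuration (no inter-chain contacts)."""
    rng = np.random.default_rng(1)
    return generate_initial_configuration(ab_top8, 160.0, 0.5, rng, ff=ff)


@pytest.fixture(scope="session")
def strand_pair(ff):
    """Idealized parallel two-strand geometry satisfying the H-bond cutoffs."""
    from prime_dmd.fixtures import parallel_strand_pair
    return parallel_strand_pair("AVAVAVA", ff)
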