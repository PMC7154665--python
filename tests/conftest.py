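import numpy as np
import pytest

from cmphelix.builder import HelixSpec, TORSION_PRESETS, build_strand, build_triple_helix


@pytest.fixture(scope="session")
def ppg10_strand():
    return build_strand(HelixSpec(n_triplets=10))


@pytest.fixture(scope="session")
def ppg10_helix():
    return build_triple_helix(HelixSpec(n_triplets=10, n_chains=3))


@pytest.fixture(scope="session")
def prom2_helix():
    spec = HelixSpec(n_triplets=10, n_chains=3,
                     torsions=dict(TORSION_PRESETS["prom2_cmp"]))
    return build_triple_helix(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
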