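import numpy as np
import pytest

from cgslatm import (
    Configuration,
    SlatmParams,
    build_channel_index,
    build_registry,
    default_cg_registry,
)


@pytest.fixture(scope="session")
def registry3():
    """Three-type registry: one solute, one lipid, one solvent type."""
    return build_registry(
        [
            {"type_name": "T1", "category": "solute"},
            {"type_name": "Nda", "category": "lipid"},
            {"type_name": "POL", "category": "solvent"},
        ]
    )


@pytest.fixture(scope="session")
def registry14():
    return default_cg_registry()


@pytest.fixture(scope="session")
def index3(registry3):
    return build_channel_index(registry3, triplet_policy="all")


@pytest.fixture(scope="session")
def index14(registry14):
    return build_channel_index(registry14, triplet_policy="all")


@pytest.fixture(scope="session")
def params():
    return SlatmParams()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_configuration(rng, registry, n_beads, n_solute=1, spread=6.0):
    """Random bead cloud with a minimum separation, for oracle checks."""
    names = registry.names
    pos = []
    while len(pos) < n_beads:
        cand = rng.uniform(-spread, spread, size=3)
        if all(np.linalg.norm(cand - p) > 1.0 for p in pos):
            pos.append(cand)
    types = rng.choice(names, size=n_beads)
    flags = np.zeros(n_beads, dtype=bool)
    flags[:n_solute] = True
    return Configuration(np.array(pos), types, flags)
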