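import numpy as np
import pytest

from tr1seq import (
    RepertoireConfig,
    build_recombinome,
    generate_germline_reference,
    simulate_repertoire,
)


@pytest.fixture(scope="session")
def germline_small():
    """Compact germline: 3 V / 2 J per chain, enough for product structure."""
    return generate_germline_reference(3, 2, 3, 2, seed=42)


@pytest.fixture(scope="session")
def recombinome_small(germline_small):
    return build_recombinome(germline_small)


@pytest.fixture(scope="session")
def germline_default():
    return generate_germline_reference(seed=1)


@pytest.fixture(scope="session")
def recombinome_default(germline_default):
    return build_recombinome(germline_default)


@pytest.fixture(scope="session")
def repertoire_small(germline_small):
    """60-cell error-free repertoire over two pools."""
    cfg = RepertoireConfig(
        n_cells={"Tconv": 20, "R1": 40},
        clone_size_p={"Tconv": 0.9, "R1": 0.5},
        error_rate=0.0,
        leak_rate=0.0,
        shared_r2_r3=0,
    )
    return simulate_repertoire(germline_small, cfg, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
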