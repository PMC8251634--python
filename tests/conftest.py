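import numpy as np
import pytest

from duplexmut import SimulationConfig, generate_panel
from duplexmut.panel_sim import PanelLocus, ReferencePanel


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_loci=4, locus_length=600, duplex_depth=30,
                            rng_seed=42)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return generate_panel(small_config)


@pytest.fixture(scope="session")
def default_panel():
    """Full-geometry panel: 20 loci x 2,400 bp."""
    return generate_panel(SimulationConfig(rng_seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def toy_panel():
    """Hand-written two-locus panel for exact-arithmetic fixtures."""
    return ReferencePanel((
        PanelLocus("locusA", "locusA", 0, 24, "ACGTACGTACGTACGTACGTACGT"),
        PanelLocus("locusB", "locusB", 0, 20, "TTTTCCCCGGGGAAAATTTT"),
    ))
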