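import numpy as np
import pytest

from coldchem import synthetic


@pytest.fixture(scope="session")
def grid():
    """The instrument acquisition grid (4000-400 cm-1, 1.928 cm-1)."""
    return synthetic.default_grid()


@pytest.fixture(scope="session")
def small_panel():
    """One strain per genus, deterministic seed; shared across tests."""
    config = synthetic.PanelConfig(strains_per_genus=1)
    strains, truth = synthetic.generate_panel(config, seed=7)
    return config, strains, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
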