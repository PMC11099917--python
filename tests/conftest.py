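import pytest

from ligprofiler import (
    NoiseModel,
    make_reference_panel,
    pool_curves,
    reference_table,
    reference_tree,
    simulate_panel,
)

PANEL_SEED = 11


@pytest.fixture(scope="session")
def panel():
    return make_reference_panel(PANEL_SEED)


@pytest.fixture(scope="session")
def noiseless():
    return NoiseModel(sigma_rel=0.0, sigma_abs=0.0, replicates=1, seed=PANEL_SEED)


@pytest.fixture(scope="session")
def default_noise():
    return NoiseModel(seed=PANEL_SEED)


@pytest.fixture(scope="session")
def pooled_panel_fits(panel, default_noise):
    """Pooled per-(fibril, assay) fits of one simulated reference panel."""
    return pool_curves(simulate_panel(panel, default_noise))


@pytest.fixture(scope="session")
def ref_table():
    return reference_table()


@pytest.fixture(scope="session")
def ref_tree():
    return reference_tree()
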