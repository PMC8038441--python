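import pytest

from emtquad import SimConfig, simulate_cell_lines, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default-sized simulated tumor cohort (expression, clinical, truth)."""
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def cell_panel():
    """Default-sized simulated cell-line panel."""
    return simulate_cell_lines(SimConfig(seed=11))
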