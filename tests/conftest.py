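import warnings

import pytest

from acylscape.synthetic import SimulationConfig, simulate

warnings.filterwarnings("ignore", message="Precision loss occurred")


@pytest.fixture(scope="session")
def sim_small():
    """A small but fully populated simulated study (with coverage)."""
    config = SimulationConfig(
        n_genes=600, n_chroms=3, n_deg=60, n_diurnal=60, seed=5
    )
    annotation, truth, chip, expression = simulate(
        config, conditions=("control", "starvation"), coverage=True
    )
    return config, annotation, truth, chip, expression


@pytest.fixture(scope="session")
def sim_fast():
    """A larger peaks-only simulation for statistical checks."""
    config = SimulationConfig(n_genes=4000, n_chroms=4, seed=9)
    annotation, truth, chip, expression = simulate(
        config, conditions=("control",), coverage=False
    )
    return config, annotation, truth, chip, expression
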