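import pytest
from hypothesis import HealthCheck, settings

from pccelv.sequence_model import ProteinRecord
from pccelv.synthetic_data import simulate_preset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def pc1_table():
    """One pc1_fig1 cohort (seed 7) shared across read-only tests."""
    table, truth = simulate_preset("pc1_fig1", seed=7)
    return table, truth


@pytest.fixture(scope="session")
def fcys_table():
    table, truth = simulate_preset("fibrocystin_ppc", seed=7)
    return table, truth


@pytest.fixture
def tiny_protein():
    return ProteinRecord(id="P1", sequence="MKTRA", name="toy")
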