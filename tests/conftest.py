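import pytest

from vte_sim.pipeline import build_base_case


@pytest.fixture(scope="session")
def base_case():
    """Full-size calibrated base case shared across test modules."""
    return build_base_case(seed=20, n=10_000)


@pytest.fixture(scope="session")
def small_base():
    """Small calibrated base case for fast end-to-end checks."""
    return build_base_case(seed=20, n=800)
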