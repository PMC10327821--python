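import pytest

from gscea.parameters import base_case_config
from gscea.outcomes import run_model


@pytest.fixture
def base_config():
    """Fresh base-case configuration (safe to mutate)."""
    return base_case_config()


@pytest.fixture(scope="session")
def base_result():
    """Deterministic base-case model result, shared across tests."""
    return run_model(base_case_config())
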