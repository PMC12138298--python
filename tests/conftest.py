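import pytest

from boafhir import (
    BuildContext,
    assemble_bundle,
    generate_synthetic_result,
)
from boafhir.terminology import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def result():
    """One complete synthetic analysis result (all regions, all organs)."""
    return generate_synthetic_result(42)


@pytest.fixture(scope="session")
def bundle(result):
    """The deterministic bundle for the session result (treat as read-only;
    tests that mutate must deep-copy)."""
    return assemble_bundle(result, BuildContext())
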