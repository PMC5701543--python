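import hypothesis
import pytest

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[hypothesis.HealthCheck.too_slow],
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def default_bundle():
    """One default-parameter synthetic bundle, shared across tests."""
    from netpharm import generate_bundle

    return generate_bundle(seed=7)
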