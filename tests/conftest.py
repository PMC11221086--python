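import pytest

from teloopkit.synthetic import SyntheticConfig, generate, write_bundle


@pytest.fixture(scope="session")
def bundle():
    """The default synthetic bundle (seed 42), shared across the session."""
    return generate(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    write_bundle(bundle, out)
    return out
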