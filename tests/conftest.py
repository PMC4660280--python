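import pytest
from hypothesis import settings

settings.register_profile("deltabc", deadline=None, derandomize=True)
settings.load_profile("deltabc")


@pytest.fixture
def toy():
    """The deterministic 7-node documentation toy."""
    from deltabc.synth import make_toy_barbell

    return make_toy_barbell()
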