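import pytest

from extraudit import load_fixture_corpus


@pytest.fixture(scope="session")
def corpus():
    """The packaged three-review hip-arthroplasty corpus."""
    return load_fixture_corpus()
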