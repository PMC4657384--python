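import pytest

from qssakit import make_genetic_nfl, make_linear_cascade


@pytest.fixture(scope="session")
def genetic_pair():
    """Genetic negative feedback at the reference parameters (k_f = 10/h)."""
    return make_genetic_nfl()


@pytest.fixture(scope="session")
def cascade_pair():
    """Linear transcription/translation cascade at the reference parameters."""
    return make_linear_cascade()
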