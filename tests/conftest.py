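import pytest

from tisk.params import preset
from tisk.phonolex import (
    SyntheticLexiconSpec,
    default_inventory,
    ganong_lexicon,
    generate_synthetic_lexicon,
)


@pytest.fixture(scope="session")
def inventory():
    return default_inventory()


@pytest.fixture(scope="session")
def fixture_lexicon():
    return ganong_lexicon()


@pytest.fixture(scope="session")
def synthetic_lexicon():
    """50-word competitor-rich lexicon used by the heavier dynamics tests."""
    return generate_synthetic_lexicon(
        SyntheticLexiconSpec(n_words=50, length_range=(2, 9), seed=7)
    )


@pytest.fixture(scope="session")
def fb_params():
    return preset("OPT_FB")
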