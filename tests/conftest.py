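import numpy as np
import pytest

from protolex.phonology import default_inventory
from protolex.synthetic import (
    Experiment1Config,
    LanguageSpec,
    RaterSpec,
    generate_language,
    make_experiment1_dataset,
)


@pytest.fixture(scope="session")
def inv():
    return default_inventory()


@pytest.fixture(scope="session")
def small_lexicon():
    """A small segmented synthetic lexicon shared by fast unit tests."""
    return generate_language(LanguageSpec(n_morphs=300, n_words=800, seed=11))


@pytest.fixture(scope="session")
def e1_bundle():
    """Desk-scale word-identification bundle (200 matched pairs, 6 raters)."""
    return make_experiment1_dataset(
        Experiment1Config(seed=5, n_participants=6, raters=RaterSpec(slopes={"NMS": 1.5}))
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
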