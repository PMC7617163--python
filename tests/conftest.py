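import pytest

from soles.fixtures import Planting, SyntheticSpec, default_lexicons, generate_corpus


@pytest.fixture(scope="session")
def lexicons():
    return default_lexicons()


@pytest.fixture(scope="session")
def planted_corpus():
    """A 50-record corpus with one planted tag per category, no traps."""
    spec = SyntheticSpec(
        n_citations=50,
        fulltext_fraction=0.8,
        planted=[
            Planting("model", "APP/PS1", "title"),
            Planting("outcome", "Morris water maze", "abstract"),
            Planting("intervention", "donepezil", "abstract"),
            Planting("species", "mouse", "model_sentence"),
            Planting("sex", "female", "model_sentence"),
        ],
        seed=11,
    )
    return generate_corpus(spec)
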