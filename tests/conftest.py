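import numpy as np
import pandas as pd
import pytest

from evspan import (
    ArticulationConfig,
    CorpusConfig,
    OculomotorConfig,
    build_layout,
    generate_corpus,
    simulate_experiment,
)


@pytest.fixture
def toy_layout():
    """Three-word sentence at origin 100 px, 14 px per letter."""
    props = pd.DataFrame(
        {
            "word": ["Der", "Hund", "bellt"],
            "frequency_per_million": [20000.0, 50.0, 5.0],
            "predictability": [0.1, 0.2, 0.6],
        }
    )
    return build_layout("Der Hund bellt", props, origin_px=100.0, px_per_char=14.0)


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(CorpusConfig(n_sentences=12), seed=11)


@pytest.fixture(scope="session")
def small_experiment(small_corpus):
    """3 subjects x 12 sentences, default (uncoupled) configs."""
    return simulate_experiment(3, small_corpus, seed=101)


@pytest.fixture(scope="session")
def coupled_experiment(small_corpus):
    oculo = OculomotorConfig(coupling_enabled=True, blink_trial_prob=0.0)
    return simulate_experiment(3, small_corpus, oculo=oculo, seed=202)
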