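import numpy as np
import pytest

from mirscape import (
    MIR_100_5P,
    SynthConfig,
    derive_scr_elements,
    simulate_ranked_experiment,
    simulate_utr_universe,
)


@pytest.fixture(scope="session")
def mir100_elements():
    return derive_scr_elements(MIR_100_5P)


@pytest.fixture(scope="session")
def small_synthetic():
    """A small spiked experiment shared across tests (seed fixed)."""
    elements = derive_scr_elements(MIR_100_5P)
    cfg = SynthConfig(
        seed=7,
        n_genes=600,
        n_responders=200,
        spike_words=(elements.word_for((1, 8)),),
        utr_len_median=400.0,
    )
    universe, truth = simulate_utr_universe(cfg)
    matrix, annotation, truth = simulate_ranked_experiment(cfg, truth)
    return cfg, universe, matrix, annotation, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
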