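"""Shared fixtures: synthetic datasets at two scales.

The small dataset keeps unit tests fast; the default-scale dataset (123
neurons, 810 trials per task per neuron) reproduces the full study design
and is shared, session-scoped, by the qualitative-reproduction tests.
"""
import numpy as np
import pytest

from itpopcode import SimulationConfig, compute_selectivity, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    cfg = SimulationConfig(
        n_neurons=30, n_stimuli_per_category=30, n_noise_stimuli=30, seed=11
    )
    df, manifest = generate_dataset(cfg)
    return df, manifest


@pytest.fixture(scope="session")
def default_dataset():
    cfg = SimulationConfig(seed=0)
    df, manifest = generate_dataset(cfg)
    return df, manifest


@pytest.fixture(scope="session")
def default_selectivity(default_dataset):
    df, _ = default_dataset
    return compute_selectivity(df)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
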