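"""Shared fixtures: a default design and small, fast synthetic cohorts.

Epoch generation for tests runs at reduced scale (16 channels, 64 Hz, 4
repetitions) so the whole suite stays quick; the generative model is scale-
free in channels and rate, so nothing about the analyses changes.
"""

import numpy as np
import pytest

import entdec as e


@pytest.fixture(scope="session")
def design():
    return e.build_design(seed=0)


@pytest.fixture(scope="session")
def vectors(design):
    return e.generate_entity_vectors(
        design, dim=20, sigma_coarse=1.0, sigma_fine=0.5, sigma_entity=0.2,
        seed=1)


@pytest.fixture(scope="session")
def small_config():
    return e.GeneratorConfig(
        n_channels=16, rate=64.0, n_repetitions=4,
        sigma_coarse=1.0, sigma_fine=1.0, sigma_entity=1.0,
        noise_sd=1.0, seed=3)


@pytest.fixture(scope="session")
def epochs(design, vectors, small_config):
    return e.generate_epoch_dataset(design, vectors, small_config, "s00")


@pytest.fixture(scope="session")
def evoked(design, epochs):
    return e.preprocess(epochs, design)


@pytest.fixture(scope="session")
def noiseless_evoked(design, vectors, small_config):
    from dataclasses import replace
    cfg = replace(small_config, noise_sd=0.0, n_repetitions=1)
    return e.preprocess(e.generate_epoch_dataset(design, vectors, cfg, "s00"),
                        design)


@pytest.fixture(scope="session")
def fine_plan(design):
    cands = e.enumerate_balanced_test_sets(design)
    return e.select_confound_controlled(cands, design, n_select=50, level="fine")
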