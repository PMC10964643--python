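"""Shared fixtures: synthetic datasets and (expensive) trained augmenters.

Everything is generated programmatically with fixed seeds; the heavyweight
fixtures (full 110-recording dataset, six 200-epoch adversarial autoencoders)
are session-scoped so the acceptance checks share one training run.
"""

from __future__ import annotations

import numpy as np
import pytest

from swpkit.augment import AAEConfig, augment_dataset
from swpkit.preprocess import preprocess_pipeline
from swpkit.synthetic import SyntheticConfig, synthesize_leaf


@pytest.fixture(scope="session")
def synth_config() -> SyntheticConfig:
    return SyntheticConfig(seed=10)


@pytest.fixture(scope="session")
def leaf8_recordings(synth_config):
    return synthesize_leaf(synth_config, 8)


@pytest.fixture(scope="session")
def leaf8_traces(leaf8_recordings):
    return [preprocess_pipeline(r, provenance="synthetic") for r in leaf8_recordings]


@pytest.fixture(scope="session")
def dataset_traces(synth_config, leaf8_traces):
    """All 110 preprocessed traces (both leaves, 20+20+15 per leaf)."""
    leaf13 = [
        preprocess_pipeline(r, provenance="synthetic")
        for r in synthesize_leaf(synth_config, 13)
    ]
    return leaf8_traces + leaf13


@pytest.fixture(scope="session")
def groups(dataset_traces):
    by_group: dict = {}
    for t in dataset_traces:
        by_group.setdefault((t.leaf, t.condition), []).append(t)
    return by_group


@pytest.fixture(scope="session")
def aae_augmentation(dataset_traces):
    """Published-scale AAE augmentation: 6 groups x 200 epochs x 50 samples."""
    return augment_dataset(
        dataset_traces, method="aae", n_per_group=50, cfg=AAEConfig(seed=10)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
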