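"""Shared fixtures.

The expensive artifacts — the planted synthetic cell line, its
preprocessed dataset, and the two fitted classifiers (signal and null)
— are session-scoped so the full suite builds each exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from sebird import (  # noqa: E402
    SparseAttentionConfig,
    SuperEnhancerClassifier,
    SyntheticSpec,
    make_fixture,
    train_bpe,
)


@pytest.fixture(scope="session")
def tiny_config() -> SparseAttentionConfig:
    return SparseAttentionConfig(
        n_layers=2, n_heads=2, hidden_size=32, intermediate_size=128,
        block_size=16, n_random_blocks=1, n_global_blocks=1, n_window_blocks=3,
        max_positions=256, vocab_size=512, dropout=0.1,
    )


@pytest.fixture(scope="session")
def micro_config() -> SparseAttentionConfig:
    """Even smaller geometry for gradient checks and oracle comparisons."""
    return SparseAttentionConfig(
        n_layers=2, n_heads=2, hidden_size=16, intermediate_size=32,
        block_size=4, n_random_blocks=0, n_global_blocks=3, n_window_blocks=1,
        max_positions=32, vocab_size=16, dropout=0.0,
    )


@pytest.fixture(scope="session")
def signal_spec() -> SyntheticSpec:
    return SyntheticSpec(seed=11)


@pytest.fixture(scope="session")
def signal_fixture(signal_spec):
    return make_fixture(signal_spec)


@pytest.fixture(scope="session")
def signal_classifier(signal_fixture):
    return SuperEnhancerClassifier.from_fixture(signal_fixture, seed=11)


@pytest.fixture(scope="session")
def signal_result(signal_classifier):
    return signal_classifier.fit(seed=11)


@pytest.fixture(scope="session")
def null_result(signal_spec):
    fixture = make_fixture(signal_spec.null_signal())
    clf = SuperEnhancerClassifier.from_fixture(fixture, seed=11)
    return clf.fit(seed=11)


@pytest.fixture(scope="session")
def small_vocab():
    """A small BPE vocabulary trained on random sequence."""
    rng = np.random.default_rng(5)
    corpus = ["".join(rng.choice(list("ACGT"), size=2000)) for _ in range(10)]
    return train_bpe(corpus, target_size=64)
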