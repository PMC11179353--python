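import numpy as np
import pytest

from growsim import (
    CriticSpec,
    EmbeddingConfig,
    Generator,
    GeneratorSpec,
    generate_dataset,
)
from growsim.critic import Critic


@pytest.fixture(scope="session")
def small_dataset():
    """64-sequence, 8-date, 32 px synthetic mixture dataset."""
    return generate_dataset(image_size=32, n_sequences=64, seed=1)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Very small dataset for fast I/O and sampling tests."""
    return generate_dataset(image_size=32, n_sequences=10, seed=7)


def tiny_specs(signature=("t",), image_size=32, width=8, vocab=76):
    gen = GeneratorSpec(
        image_size=image_size,
        width=width,
        blocks_per_stage=1,
        embedding=EmbeddingConfig(signature=signature, dim=64, vocab_size=vocab),
    )
    crit = CriticSpec(
        image_size=image_size,
        width=width,
        embedding=EmbeddingConfig(signature=signature, dim=256, vocab_size=vocab),
    )
    return gen, crit


@pytest.fixture()
def tiny_generator():
    spec, _ = tiny_specs(signature=("t", "c", "b"))
    return Generator(spec, np.random.default_rng(0))


@pytest.fixture()
def tiny_critic():
    _, spec = tiny_specs(signature=("t", "c", "b"))
    return Critic(spec, np.random.default_rng(1))
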