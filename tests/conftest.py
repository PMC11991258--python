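import numpy as np
import pytest

from ecgmark import SynthConfig, generate_corpus, generate_record


@pytest.fixture(scope="session")
def record():
    """Default-condition synthetic record: 12 leads, 500 Hz, 10 s."""
    return generate_record(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def noisy_record():
    """Record whose derived limb leads carry inter-lead noise."""
    return generate_record(SynthConfig(seed=2, interlead_noise_sd=3.0))


@pytest.fixture(scope="session")
def corpus100():
    """The 100-record synthetic corpus used by the reversibility suite."""
    return generate_corpus(100, base_seed=100)


@pytest.fixture(scope="session")
def corpus20(corpus100):
    return corpus100[:20]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def payload64(rng):
    return rng.integers(0, 2, 64).astype(np.uint8)
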