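import numpy as np
import pytest

from motkit import ChainParams, SynthSpec


@pytest.fixture
def chain_params():
    return ChainParams()


@pytest.fixture
def rest_spec():
    """Spec with the envelope held at zero: pure baseline noise."""
    return SynthSpec(envelope=((0.0, 0.0),), seed=42)


def random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4096, size=n, dtype=np.uint16)
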