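import numpy as np
import pytest

from hsqcmatch import Spectrum


def random_spectrum(
    rng: np.random.Generator, n: int, compound_id: str = "rand"
) -> Spectrum:
    """A spectrum with n peaks uniform over the full normalization window."""
    return Spectrum.from_shifts(
        compound_id, rng.uniform(0.0, 10.0, n), rng.uniform(0.0, 200.0, n)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20120)


@pytest.fixture
def spectrum_pair(rng):
    return random_spectrum(rng, 10, "p"), random_spectrum(rng, 12, "q")
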