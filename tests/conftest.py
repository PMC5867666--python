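import numpy as np
import pytest

from druscan.phantom import PhantomSpec, generate_phantom, phantom_suite


@pytest.fixture(scope="session")
def easy_bundle():
    """One flat-illumination, high-contrast phantom (the seed-42 example)."""
    return generate_phantom(
        PhantomSpec(seed=42, drusen_contrast=60, gradient_amplitude=0)
    )


@pytest.fixture(scope="session")
def easy_suite():
    """The five-seed easy suite used for end-to-end recovery checks."""
    return phantom_suite(range(5), "easy")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_histogram(rng, n_nonzero=256):
    """Random normalized 256-bin histogram with a chosen support size."""
    p = np.zeros(256)
    support = rng.choice(256, size=n_nonzero, replace=False)
    p[support] = rng.random(n_nonzero) + 1e-3
    return p / p.sum()
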