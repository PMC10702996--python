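import numpy as np
import pytest

from pdfuse import phantoms


def make_phantom_set(n_per_class: int, image_size: int = 64, seed0: int = 0):
    """Stack of labeled phantoms (in memory, no disk IO)."""
    X, y = [], []
    for c in range(3):
        for i in range(n_per_class):
            spec = phantoms.PhantomSpec(
                image_size=image_size, class_label=c, seed=seed0 + 1000 * c + i)
            X.append(phantoms.generate_phantom(spec))
            y.append(c)
    return np.stack(X), np.array(y)


@pytest.fixture(scope="session")
def small_phantom_set():
    return make_phantom_set(8, image_size=64)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
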