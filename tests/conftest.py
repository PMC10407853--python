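import numpy as np
import pytest

from foldmimic.mimicry import MotifCriteria
from foldmimic.synthetic import PlantSpec, gen_ensemble, gen_toy_crystal


@pytest.fixture(scope="session")
def criteria():
    return MotifCriteria()


@pytest.fixture(scope="session")
def mixed_ensemble():
    """Noise-free ensemble with overlapping planted motifs."""
    spec = PlantSpec(
        n=40, f_alpha=0.5, f_beta=0.4, f_three10=0.3, sigma=0.0,
        global_min="alpha", seed=7,
    )
    return gen_ensemble(spec)


@pytest.fixture(scope="session")
def toy_crystal():
    return gen_toy_crystal()


def random_rotation(rng) -> np.ndarray:
    """Uniform-ish random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
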