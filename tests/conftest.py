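import numpy as np
import pytest

from erbnet.phantom import PhantomConfig


@pytest.fixture
def small_phantom_config():
    """A quick-to-generate phantom with a handful of lesions."""
    return PhantomConfig(volume_shape=(64, 64, 32), n_nodules=3, n_non_nodules=3,
                         nodule_diameter_mm=(4.0, 8.0), vessel_length_mm=(8.0, 14.0),
                         min_nodule_separation_mm=10.0, seed=7)


@pytest.fixture
def lesion_free_config():
    """Body/lung phantom with no lesions (dose-simulation fixtures)."""
    return PhantomConfig(volume_shape=(64, 64, 8), n_nodules=0, n_non_nodules=0,
                         noise_sigma_hu=0.0, seed=3)


def antialiased_disk(n: int = 128, radius: float = 20.0, value: float = 0.02,
                     supersample: int = 4) -> np.ndarray:
    """A centred disk with fractional-coverage (antialiased) edge pixels.

    Reduces discretization error at the rim so analytic line-integral
    oracles are meaningful at sub-percent tolerances.
    """
    m = n * supersample
    c = np.arange(m, dtype=np.float64)
    x = (c + 0.5) / supersample - n / 2
    xx, yy = np.meshgrid(x, x, indexing="ij")
    fine = (np.sqrt(xx**2 + yy**2) <= radius).astype(np.float64)
    return fine.reshape(n, supersample, n, supersample).mean(axis=(1, 3)) * value


@pytest.fixture
def disk_slice():
    return antialiased_disk()
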