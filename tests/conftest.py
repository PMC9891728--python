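import numpy as np
import pytest

from coloc_stress import SceneParams, make_coloc_stack

# small, fast scene geometry reused across tests; deep enough in z for
# the PSF placement margin
SMALL_GRID = (96, 96, 16)


@pytest.fixture
def clean_params():
    """Noise-free small scene."""
    return SceneParams(grid_shape=SMALL_GRID, n_puncta=40, poisson_noise=False,
                       read_noise_sd=0.0, background=0.0, seed=11)


@pytest.fixture
def noisy_params():
    return SceneParams(grid_shape=SMALL_GRID, n_puncta=40, seed=11)


@pytest.fixture
def clean_pair(clean_params):
    return make_coloc_stack(clean_params)


def pearson_brute(a, b):
    """Brute-force loop evaluation of the correlation quotient."""
    a = [float(v) for v in np.ravel(a)]
    b = [float(v) for v in np.ravel(b)]
    ma = sum(a) / len(a)
    mb = sum(b) / len(b)
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    da = sum((x - ma) ** 2 for x in a)
    db = sum((y - mb) ** 2 for y in b)
    return num / (da * db) ** 0.5


def icq_brute(a, b):
    """Brute-force loop: fraction of positive-covariance pixels minus 0.5."""
    a = [float(v) for v in np.ravel(a)]
    b = [float(v) for v in np.ravel(b)]
    ma = sum(a) / len(a)
    mb = sum(b) / len(b)
    n_pos = sum(1 for x, y in zip(a, b) if (x - ma) * (y - mb) > 0)
    return n_pos / len(a) - 0.5
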