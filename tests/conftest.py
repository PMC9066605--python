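import numpy as np
import pytest

from sphellipse.cli_io import random_pair


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det fixed)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] = -q[:, 2]
    return q


def pair_stream(n, start_seed=0, xi_range=(0.08, 0.6)):
    """Deterministic stream of random ellipse-pair fixtures."""
    return [random_pair(start_seed + k, xi_range=xi_range) for k in range(n)]
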