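import numpy as np
import pytest

import scorerecon as sr
from scorerecon.score_model import TrainConfig, train_prior


@pytest.fixture(scope="session")
def phantom_slices_32():
    """60 z-normalized 32x32 slices, both contrast classes, fixed seeds."""
    slices = []
    for i in range(20):
        cls = sr.SequenceClass.T2 if i % 2 else sr.SequenceClass.T1
        vol = sr.generate_phantom(500 + i, size=32, depth=4, sequence_class=cls)
        slices.extend(sr.slice_volume(vol, 3, seed=i))
    return slices


@pytest.fixture(scope="session")
def trained_state_32(phantom_slices_32):
    """A small prior trained at 32x32 — shared by training/sampling tests."""
    cfg = TrainConfig(size=32, channels=8, steps=700, batch_size=8, seed=11)
    state, log = train_prior(phantom_slices_32, cfg)
    return state, log


@pytest.fixture(scope="session")
def gaussian_instance():
    """A fixed smooth 8x8 Gaussian prior with a ground-truth draw."""
    from scorerecon.experiments import smooth_gaussian_prior

    n = 8
    rng = np.random.default_rng(42)
    prior = smooth_gaussian_prior(n)
    chol = np.linalg.cholesky(prior.covariance)
    x_true = (prior.mean + chol @ rng.standard_normal(n * n)).reshape(n, n)
    return prior, x_true
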