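import numpy as np
import pytest

import leidyn as ld


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small noisy three-state cohort shared by read-only tests."""
    spec = ld.default_cohort_spec(n_per_group=(4, 4), N=30, T=60, seed=7)
    scans, truth, manifest = ld.generate_cohort(spec)
    return spec, scans, truth, manifest


@pytest.fixture(scope="session")
def small_eigenseries(small_cohort):
    _, scans, _, _ = small_cohort
    return [ld.eigenseries(s) for s in scans]


def planted_pool(n_copies=20, noise_sd=0.0, n_regions=12, seed=0):
    """Pool built from 3 planted orthogonal-ish patterns, each repeated
    ``n_copies`` times with optional Gaussian perturbation; returns the
    pool and the true labels."""
    rng = np.random.default_rng(seed)
    masks = [range(0, 4), range(4, 8), range(8, 12)]
    patterns = []
    for m in masks:
        v = -np.ones(n_regions)
        v[list(m)] = 1.0
        patterns.append(v / np.linalg.norm(v))
    x = np.repeat(np.stack(patterns), n_copies, axis=0)
    labels = np.repeat(np.arange(3), n_copies)
    if noise_sd > 0:
        x = x + rng.normal(0, noise_sd, size=x.shape)
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    return x, labels
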