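import numpy as np
import pytest

from msgcn import CohortSpec, generate_cohort, graphs_from_cohort


def random_symmetric_nonneg(rng, n, density=1.0):
    """Random symmetric non-negative weight matrix with zero diagonal."""
    a = np.abs(rng.normal(size=(n, n)))
    if density < 1.0:
        mask = rng.random((n, n)) < density
        a = a * (mask | mask.T)
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return a


def random_connectivity(rng, n):
    """Random symmetric signed matrix with unit diagonal (Pearson-like)."""
    c = np.clip(rng.normal(scale=0.4, size=(n, n)), -1, 1)
    c = (c + c.T) / 2.0
    np.fill_diagonal(c, 1.0)
    return c


@pytest.fixture(scope="session")
def tiny_cohort():
    """30 subjects, 20/10 ROIs, strong planted effect: fast but learnable."""
    return generate_cohort(CohortSpec(n_subjects=30, n_timepoints=60,
                                      fine_rois=20, coarse_rois=10, seed=42))


@pytest.fixture(scope="session")
def tiny_samples(tiny_cohort):
    return graphs_from_cohort(tiny_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
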