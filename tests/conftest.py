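import numpy as np
import pytest

import segstab as ss


@pytest.fixture
def tiny_matrix():
    """3 genes x 2 cells with hand-written values."""
    return ss.ExpressionMatrix(
        gene_ids=["g1", "g2", "g3"],
        cell_ids=["c1", "c2"],
        values=np.array([[0.0, 4.0], [2.0, 2.0], [8.0, 0.0]]),
    )


@pytest.fixture(scope="session")
def dataset_1k():
    """Default-condition synthetic dataset: 1,000 genes x 1,000 cells,
    4 classes, 20% stable genes."""
    return ss.generate(n_genes=1000, n_cells=1000, n_classes=4,
                       frac_stable=0.2, seed=7)


@pytest.fixture(scope="session")
def fitted_1k(dataset_1k):
    """Full pipeline results on the default synthetic dataset."""
    return ss.StabilityModel(dataset_1k.matrix, dataset_1k.annotation).fit()


@pytest.fixture(scope="session")
def small_dataset():
    """Smaller dataset for pipeline-level tests that refit repeatedly."""
    return ss.generate(n_genes=120, n_cells=300, n_classes=3,
                       frac_stable=0.3, seed=5)


def draw_gamma_gaussian(rng, n, lam, shape, rate, mu, sd):
    """Sample from lam*Gamma(shape, rate) + (1-lam)*N(mu, sd^2), keeping
    the strictly positive values (mixture-fit input convention)."""
    comp = rng.random(n) < lam
    x = np.where(comp, rng.gamma(shape, 1.0 / rate, n), rng.normal(mu, sd, n))
    return x[x > 0]


def draw_gamma_gamma(rng, n, lam, a1, b1, a2, b2):
    comp = rng.random(n) < lam
    return np.where(comp, rng.gamma(a1, 1.0 / b1, n), rng.gamma(a2, 1.0 / b2, n))
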