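import numpy as np
import pytest

from spotcount.matrix import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def poisson_matrix():
    """Factory: G x n Poisson matrix with uniform per-gene rates."""

    def make(G=50, n=200, lam_range=(0.5, 5.0), seed=0, depth_sd=0.0):
        r = np.random.default_rng(seed)
        lam = r.uniform(*lam_range, G)
        depths = np.exp(r.normal(0.0, depth_sd, n))
        counts = r.poisson(lam[:, None] * depths[None, :]).astype(np.int64)
        return CountMatrix(counts)

    return make


def mc_se_moments(y):
    """Monte-Carlo standard errors for (mean, variance, zero proportion)."""
    n = len(y)
    se_mean = y.std(ddof=1) / np.sqrt(n)
    s2 = y.var(ddof=1)
    m4 = ((y - y.mean()) ** 4).mean()
    se_var = np.sqrt(max(m4 - s2**2, 1e-12) / n)
    p0 = (y == 0).mean()
    se_p0 = np.sqrt(max(p0 * (1 - p0), 1.0 / n) / n)
    return se_mean, se_var, se_p0
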