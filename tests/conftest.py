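import numpy as np
import pytest

from breedopt import GenomicTest, Trait, default_program


@pytest.fixture(scope="session")
def trait() -> Trait:
    """The single milk trait: h² = 0.25, σ_p = 700 kg (σ_a = 350 kg)."""
    return Trait(h2=0.25, sigma_p=700.0)


@pytest.fixture(scope="session")
def program():
    return default_program()


@pytest.fixture(scope="session")
def genomic() -> GenomicTest:
    return GenomicTest(r_gebv=0.75, cost_per_individual=150.0)


def mc_truncated_mean(R, thresholds, sigma_a, n_draws, seed):
    """Monte-Carlo oracle: mean aggregate genotype (last variable of R)
    among draws exceeding the stage thresholds; returns (mean, se)."""
    rng = np.random.default_rng(seed)
    m = R.shape[0] - 1
    X = rng.multivariate_normal(np.zeros(R.shape[0]), R, size=n_draws,
                                method="cholesky")
    sel = np.all(X[:, :m] > np.asarray(thresholds), axis=1)
    h = X[sel, -1] * sigma_a
    if h.size < 10:
        raise RuntimeError("selection too extreme for the MC oracle")
    return float(h.mean()), float(h.std(ddof=1) / np.sqrt(h.size))
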