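import numpy as np
import pytest

from gencorr import (
    GridSpec,
    default_grid,
    make_synthetic_kinship,
    run_grid,
)

#: shared study conditions for the simulation experiments: 50 equicorrelated
#: families of 10 with relationship coefficient 0.5 (n = 500, Neff = 1125),
#: residual correlation held at 0.2 in every data-generating model
FAMILY_KWARGS = dict(n_families=50, family_size=10, within_coefficient=0.5)
RHO_E = 0.2


@pytest.fixture(scope="session")
def family_kinship():
    return make_synthetic_kinship(**FAMILY_KWARGS)


@pytest.fixture(scope="session")
def tiny_kinship():
    return make_synthetic_kinship(n_families=10, family_size=4, within_coefficient=0.5)


@pytest.fixture(scope="session")
def tiny_store(tiny_kinship):
    """A quick bootstrap store: 3 heritability values per trait, full rho axis."""
    grid = GridSpec(
        h1_values=(0.25, 0.55, 0.85),
        h2_values=(0.25, 0.55, 0.85),
        rho_values=tuple(np.round(np.arange(-0.95, 1.0, 0.1), 10)),
        rho_e=RHO_E,
        n_reps=200,
        seed=7,
    )
    return run_grid(tiny_kinship, grid)


@pytest.fixture(scope="session")
def family_store(family_kinship):
    """Full default-grid store on the n = 500 family kinship (n_reps = 500)."""
    return run_grid(family_kinship, default_grid(rho_e=RHO_E, n_reps=500, seed=11))


def random_pmfs(n, seed, scheme=None):
    """Seeded stream of random ConditionalPMFs with varied support patterns."""
    from gencorr import BinScheme, ConditionalPMF

    scheme = scheme or BinScheme()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        k = scheme.n_rho
        support = rng.integers(2, k + 1)
        start = rng.integers(0, k - support + 1)
        probs = np.zeros(k)
        probs[start : start + support] = rng.dirichlet(np.full(support, 0.8))
        probs /= probs.sum()
        out.append(ConditionalPMF(probs=probs, observed=(0, 0, 0), scheme=scheme))
    return out
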