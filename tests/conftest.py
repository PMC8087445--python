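import numpy as np
import pandas as pd
import pytest

from methclock import (
    SimulationConfig,
    filter_sites,
    impute_missing,
    simulate_metadata,
    simulate_methylation,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_individuals=40,
        n_sites=300,
        n_age_sites=60,
        longitudinal_fraction=0.2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """A small but fully structured synthetic study: metadata, counts, truth."""
    meta = simulate_metadata(small_config)
    counts, truth = simulate_methylation(meta, small_config)
    return meta, counts, truth


@pytest.fixture(scope="session")
def small_ratios(small_study):
    meta, counts, _ = small_study
    retained = filter_sites(counts)
    return impute_missing(counts, retained, k=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def toy_counts(rng, n_sites=50, n_samples=20, missing=0.05):
    """Random count matrix with controlled missingness, as plain frames."""
    total = rng.integers(1, 40, size=(n_sites, n_samples)).astype(float)
    meth = rng.binomial(total.astype(int), rng.uniform(0.05, 0.95, size=n_sites)[:, None])
    mask = rng.random((n_sites, n_samples)) < missing
    total[mask] = np.nan
    meth = meth.astype(float)
    meth[mask] = np.nan
    sites = pd.Index([f"chr1:{100 + 10 * i}" for i in range(n_sites)], name="site")
    cols = pd.Index([f"s{j:02d}" for j in range(n_samples)])
    return pd.DataFrame(meth, index=sites, columns=cols), pd.DataFrame(
        total, index=sites, columns=cols
    )
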