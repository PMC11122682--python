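import numpy as np
import pandas as pd
import pytest

from nfdstools import MCMCSettings, SimulationConfig, gen_timeseries


@pytest.fixture(scope="session")
def fast_mcmc():
    """Chain settings sized for unit tests."""
    return MCMCSettings(chains=2, warmup=800, samples=1000)


@pytest.fixture(scope="session")
def small_series():
    """A 6-locality, 14-year synthetic morph-count series plus its truth."""
    cfg = SimulationConfig(
        n_localities=6, years_per_locality=14, D_true=-0.5, sample_size=100, seed=602
    )
    return gen_timeseries(cfg)


@pytest.fixture(scope="session")
def two_cycle_trajectories():
    """Constant-amplitude two-cycle latent trajectories for 10 localities."""
    rng = np.random.default_rng(7)
    rows = []
    for j in range(10):
        years = np.arange(2000, 2020)
        p = 0.5 + 0.1 * np.where(years % 2 == 0, 1, -1) + rng.normal(0, 0.004, 20)
        rows += [(f"L{j:02d}", int(y), float(v)) for y, v in zip(years, p)]
    return pd.DataFrame(rows, columns=["locality", "year", "p"])
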