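import numpy as np
import pytest

from stratatrend import (SamplerSettings, SimConfig, build_proximity_matrix,
                         fit_model, min_connecting_threshold, preset,
                         simulate_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(20121116)


@pytest.fixture(scope="session")
def path3_graph():
    """Three collinear strata forming a path graph."""
    return build_proximity_matrix([(0, 0), (1, 0), (2, 0)], threshold=1.5)


def random_connected_graph(m, rng, box=20.0):
    """Random centroids with the threshold set by the connectivity rule."""
    cent = rng.uniform(0, box, size=(m, 2))
    thr = min_connecting_threshold(cent)
    return build_proximity_matrix(cent, thr)


@pytest.fixture(scope="session")
def small_sim():
    """A small ZINB + CAR + AR(1) dataset with known truth."""
    cfg = SimConfig(m=8, T=15, segments_per_stratum=10,
                    alpha_range=(0.5, 2.0), beta_range=(-0.04, 0.04),
                    tau_eta=4.0, tau_gamma=4.0, rho=0.6, lam=0.5,
                    p_zero=0.1, size_n=2.0, seed=42)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """One shared full-model fit of the small dataset (module-expensive)."""
    return fit_model(small_sim.counts, small_sim.graph, preset("both-zinb"),
                     SamplerSettings(chains=2, warmup=600, draws=600, seed=7))


@pytest.fixture(scope="session")
def trend_sim():
    """No-random-effect NB data with 3 declining / 3 increasing / 6 flat
    strata (strong effects)."""
    beta = np.array([-0.15] * 3 + [0.15] * 3 + [0.0] * 6)
    cfg = SimConfig(m=12, T=15, segments_per_stratum=10,
                    alpha_values=np.full(12, 1.5), beta_values=beta,
                    data_model="nb", spatial=False, temporal=False,
                    size_n=2.0, seed=99)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def trend_fit(trend_sim):
    return fit_model(trend_sim.counts, trend_sim.graph, preset("none-nb"),
                     SamplerSettings(chains=2, warmup=500, draws=500, seed=3))
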