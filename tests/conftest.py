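import numpy as np
import pandas as pd
import pytest

import streammeta as sm


@pytest.fixture(scope="session")
def small_design():
    """One within-stream design shared (read-only) across tests."""
    sites, net, surface = sm.generate_design(sm.DesignConfig(design="within_stream", seed=11))
    return sites, net, surface


@pytest.fixture(scope="session")
def small_triplet(small_design):
    sites, net, surface = small_design
    return sm.design_distances(sites, net, surface)


@pytest.fixture(scope="session")
def small_env(small_design):
    sites, _, _ = small_design
    return sm.generate_environment(sites, autocorr_range=10.0, n_vars=10, seed=12)


@pytest.fixture(scope="session")
def small_community(small_design, small_env, small_triplet):
    sites, _, _ = small_design
    return sm.generate_community(
        sites, small_env, small_triplet,
        sm.ScenarioConfig(regime="species_sorting", seed=13))


@pytest.fixture(scope="session")
def small_basis(small_triplet):
    return sm.compute_mem(sm.build_swm(small_triplet["GEO"], "gabriel", "binary"))


def square(values, labels=None):
    """Small helper: labeled square DataFrame from an array."""
    a = np.asarray(values, float)
    labels = labels or [f"s{i}" for i in range(a.shape[0])]
    return pd.DataFrame(a, index=labels, columns=labels)
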