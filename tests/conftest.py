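import numpy as np
import pandas as pd
import pytest

import fgmsim as f


@pytest.fixture(scope="session")
def small_spec():
    return f.SyntheticCountrySpec(
        n_communities=30, women_per_community=80, seed=11
    )


@pytest.fixture(scope="session")
def small_microdata(small_spec):
    return f.generate_microdata(small_spec)


@pytest.fixture(scope="session")
def fitted_model(small_microdata):
    return f.fit(small_microdata)


@pytest.fixture(scope="session")
def small_countries():
    """Six varied synthetic countries with fitted models attached."""
    countries = f.synthetic_scenario_inputs(
        6, 7, n_communities=30, women_per_community=60
    )
    from fgmsim.scenarios import fit_models

    return fit_models(countries)


@pytest.fixture
def random_incidence():
    rng = np.random.default_rng(42)
    years = np.arange(2000, 2030)
    values = rng.uniform(0, 0.05, size=(15, len(years)))
    return f.IncidenceSurface(values, np.arange(15), years)
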