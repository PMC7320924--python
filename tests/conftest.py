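import numpy as np
import pandas as pd
import pytest

import stagemap as sm


@pytest.fixture(scope="session")
def lattice5():
    return sm.generate_geography(5, 5, income_spatial_trend=0.0, seed=11)


@pytest.fixture(scope="session")
def pop5(lattice5):
    return sm.generate_population(lattice5, mean_area_pop=1600, n_years=9, seed=12)


@pytest.fixture(scope="session")
def cases5(lattice5, pop5):
    params = sm.RiskModelParams(seed=13)
    return sm.simulate_cases(pop5, lattice5, params)


@pytest.fixture(scope="session")
def hot_lattice():
    """10x10 lattice with a planted relative-risk-2 block, E = 5 per area."""
    geo = sm.generate_geography(10, 10, income_spatial_trend=0.0, seed=21)
    E = pd.Series(5.0, index=geo.area_ids)
    hot = [a for a in geo.area_ids
           if geo.areas.loc[a, "x"] < 3.5 and geo.areas.loc[a, "y"] < 3.5]
    rr = pd.Series(1.0, index=geo.area_ids)
    rr[hot] = 2.0
    rng = np.random.default_rng(22)
    O = pd.Series(rng.poisson(E.values * rr.values), index=geo.area_ids)
    return geo, O, E, hot


@pytest.fixture(scope="session")
def hot_fit(hot_lattice):
    geo, O, E, hot = hot_lattice
    sir = sm.compute_sir(O, E)
    fit = sm.BYMSmoother(n_iter=4000, burn_in=2000, thin=2, n_chains=2,
                         random_state=23).fit(sir[["O", "E"]], geo)
    return fit, geo, O, E, hot
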