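import numpy as np
import pytest

from demest.ages import build_age_grid, five_year_grid
from demest.lifetable import lifetable_from_mx
from demest.mlt import make_standard_library


@pytest.fixture(scope="session")
def gbd23():
    return build_age_grid("gbd23")


@pytest.fixture(scope="session")
def grid5():
    return five_year_grid(95.0)


@pytest.fixture(scope="session")
def std_library():
    return make_standard_library()


@pytest.fixture(scope="session")
def gompertz_lt(gbd23):
    """A plain senescent-mortality life table on the 23-group grid."""
    mids = np.array(
        [s + (w if not np.isnan(w) else 10.0) / 2 for s, w in zip(gbd23.starts, gbd23.widths)]
    )
    mx = 3e-4 * np.exp(0.09 * mids)
    return lifetable_from_mx(mx, gbd23)


@pytest.fixture(scope="session")
def small_world():
    """One-location classical-transition world, shared across tests."""
    from demest.world import WorldConfig, build_world

    cfg = WorldConfig(locations=("loc_a",), seed=3,
                      census_years=(1960, 1980, 2000, 2015))
    return build_world(cfg)


@pytest.fixture(scope="session")
def stationary_world():
    """Constant-rates world satisfying indirect-method stationarity assumptions."""
    from demest.world import WorldConfig, build_world

    cfg = WorldConfig(
        locations=("loc_a",),
        seed=11,
        tfr0=4.0,
        tfr1=4.0,
        q5_0=0.08,
        q5_1=0.08,
        q45_0=0.25,
        q45_1=0.25,
        survey_n_mothers=6000,
    )
    return build_world(cfg)
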