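import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from trichoproj.grid import generate_grid
from trichoproj.ocean import ERA_FUTURE, GriddedField, OceanState, SyntheticConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Coarse resolution used throughout the suite; keeps generated states at
#: 18 x 36 cells so the full suite stays fast.
COARSE = dict(lat_resolution=10.0, lon_resolution=10.0)


@pytest.fixture(scope="session")
def coarse_config():
    return SyntheticConfig(seed=7, **COARSE)


@pytest.fixture(scope="session")
def small_grid():
    return generate_grid(10.0)


def make_uniform_state(
    nf=1.0, r_tr=0.5, ph=7.81, po4=0.05, dop=0.1, era=ERA_FUTURE, resolution=30.0
) -> OceanState:
    """A spatially uniform ocean state with closed-form integrals."""
    geom = generate_grid(resolution)
    full = lambda v: np.full(geom.shape, float(v))
    return OceanState(
        era=era,
        geometry=geom,
        ph_t=GriddedField("ph_t", "pH", full(ph), era),
        po4=GriddedField("po4", "mmol m-3", full(po4), era),
        dop=GriddedField("dop", "mmol m-3", full(dop), era),
        nf=GriddedField("nf", "g N m-2 yr-1", full(nf), era),
        r_tr=GriddedField("r_tr", "1", full(r_tr), era),
        aux_limits={"fe": GriddedField("aux_limit_fe", "1", full(0.5), era)},
    )


@pytest.fixture
def uniform_state():
    return make_uniform_state()
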