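import numpy as np
import pytest

from tlrhm.leaf_ek import LeafEKParams
from tlrhm.rhm_surface import build_surface
from tlrhm.synthgen import SynthConfig, generate_site_year


@pytest.fixture(scope="session")
def default_params() -> LeafEKParams:
    return LeafEKParams()


@pytest.fixture(scope="session")
def default_surface():
    """Full default parameter surface (1-40 degC x 20-180 umol m-2 s-1)."""
    return build_surface()


@pytest.fixture(scope="session")
def coarse_surface():
    """Small surface for cheap canopy-level tests; spans 1-40 degC."""
    return build_surface(t_grid=np.arange(1.0, 41.0, 3.0),
                         vcmax_grid=np.array([20.0, 60.0, 100.0, 180.0]))


@pytest.fixture(scope="session")
def synth_year():
    """One default synthetic site-year (seed 0) with its half-hourly table."""
    return generate_site_year(SynthConfig(seed=0))
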