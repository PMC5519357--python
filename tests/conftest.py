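import numpy as np
import pytest

from bilayermech import AreaSeries, SyntheticMembraneSpec

#: the reference surrogate condition: 400-lipid bilayer patch at 30 °C
REFERENCE_KWARGS = dict(
    target_area_modulus=240.0,
    reference_area=130.0,
    temperature=303.15,
    n_frames=20_000,
    correlation_rho=0.0,
)


@pytest.fixture
def reference_spec() -> SyntheticMembraneSpec:
    return SyntheticMembraneSpec(seed=1, **REFERENCE_KWARGS)


@pytest.fixture
def small_series() -> AreaSeries:
    """A short iid Gaussian area series around 130 nm² for interface tests."""
    rng = np.random.default_rng(7)
    areas = 130.0 + 1.5 * rng.standard_normal(600)
    return AreaSeries(times=np.arange(600.0), areas=areas, temperature=303.15)
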