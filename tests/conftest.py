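import numpy as np
import pytest

import wpqa
from wpqa.simulate import MechanisticConfig, generate_mechanistic_cohort


@pytest.fixture(scope="session")
def small_phantom():
    return wpqa.WaterPhantomGeometry(extent_a=200.0, extent_b=120.0,
                                     extent_c=120.0)


@pytest.fixture(scope="session")
def sobp_field():
    target = wpqa.TargetRegion(depth_min=80.0, depth_max=130.0, diameter=50.0)
    return wpqa.optimize_sobp("proton", target, 2.0)


@pytest.fixture(scope="session")
def sobp_grid(sobp_field, small_phantom):
    return wpqa.compute_dose_grid(sobp_field, small_phantom, spacing=2.0)


def uniform_grid(value=2.0, n=21, spacing=2.0):
    """Constant-dose grid centered on the origin laterally."""
    return wpqa.DoseGrid(origin=(0.0, -n * spacing / 2, -n * spacing / 2),
                         spacing=spacing,
                         values=np.full((n, n, n), value))


@pytest.fixture(scope="session")
def zero_error_cohort():
    """20 mechanistic fields on 2 mm grids with all error terms off."""
    cfg = MechanisticConfig(n_fields=20, spacing_mm=2.0, zero_error=True,
                            seed=20)
    return generate_mechanistic_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Small mechanistic cohort with the default error model."""
    cfg = MechanisticConfig(n_fields=8, spacing_mm=2.0, seed=7)
    return generate_mechanistic_cohort(cfg)
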