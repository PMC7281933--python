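import numpy as np
import pytest

import ivimpipe as ip


@pytest.fixture(scope="session")
def b_schedule() -> np.ndarray:
    return np.array(ip.DEFAULT_B_VALUES, dtype=float)


@pytest.fixture()
def tiny_spec() -> ip.PhantomSpec:
    """Desk-scale phantom for fast unit tests (not the study defaults)."""
    return ip.PhantomSpec(
        grid_shape=(10, 10, 6),
        n_per_group=3,
        effect_region=ip.EllipsoidRegion(radii_mm=(14.0, 12.0, 10.0)),
        seed=7,
    )


@pytest.fixture()
def uniform_noiseless_spec() -> ip.PhantomSpec:
    """Noiseless, spatially uniform phantom: every voxel at the baseline."""
    return ip.PhantomSpec(
        grid_shape=(6, 6, 4),
        n_per_group=2,
        noise_sigma=0.0,
        between_subject_sd={"vbw": 0.0, "d": 0.0, "dstar": 0.0},
        seed=1,
    )
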