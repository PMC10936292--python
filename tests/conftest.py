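import numpy as np
import pytest

from metamorphsim import (
    DistortionField,
    GridSpec,
    RasterSpec,
    make_kernel,
    random_metamorphopsia,
)


@pytest.fixture(scope="session")
def raster() -> RasterSpec:
    """Small square raster covering the default Amsler grid with margin."""
    return RasterSpec(128, 128, 36.0)


@pytest.fixture(scope="session")
def grid() -> GridSpec:
    return GridSpec()


@pytest.fixture(scope="session")
def canonical_field() -> DistortionField:
    """The canonical single-kernel field used across examples."""
    return DistortionField(
        (make_kernel((1.0, -0.5), 2.0, luminance_loss=0.5,
                     rotation_strength_rad=0.3, radial_stretch=0.2,
                     boundary_alpha=3.0),)
    )


@pytest.fixture(scope="session")
def seeded_fields() -> list[DistortionField]:
    """Twenty random metamorphopsia templates, seeds 1..20."""
    return [random_metamorphopsia(seed) for seed in range(1, 21)]


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
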