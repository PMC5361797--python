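import numpy as np
import pytest

from fishfat.io import AcquisitionGeometry
from fishfat.phantom import Depot, Ellipsoid, PhantomSpec, ShellSector


@pytest.fixture
def small_geometry() -> AcquisitionGeometry:
    """Down-scaled acquisition for fast unit tests: 8 x 8 mm in-plane,
    32 x 32 matrix, 12 slices of 0.5 mm."""
    return AcquisitionGeometry(
        fov_mm=(8.0, 8.0), matrix=(32, 32), n_slices=12, slice_thickness_mm=0.5
    )


@pytest.fixture
def small_spec(small_geometry) -> PhantomSpec:
    """A small fish-in-agarose phantom matching the default design but on
    the down-scaled grid."""
    body = Ellipsoid(center_mm=(0.0, 0.0, 0.0), semi_axes_mm=(1.8, 2.0, 2.4))
    return PhantomSpec(
        geometry=small_geometry,
        body=body,
        tube_radius_mm=2.4,
        depots=(
            Depot("subcutaneous", ShellSector(outer=body, inner_scale=0.8), 0.90),
            Depot(
                "visceral",
                Ellipsoid(center_mm=(0.0, 0.5, -0.4), semi_axes_mm=(0.8, 0.9, 1.0)),
                0.90,
            ),
        ),
        lean_fat_fraction=0.05,
        sigma=0.0,
        seed=7,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
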