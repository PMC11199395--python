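import numpy as np
import pytest

from tractokit import (
    BundleSpec,
    ScalarMap,
    SpatialReference,
    Tractogram,
    make_bundle,
    make_scalar_map,
)

CENTERLINE = np.array(
    [[-60.0, -40.0, -20.0], [-20.0, 0.0, -10.0], [20.0, 20.0, 10.0],
     [60.0, 40.0, 20.0]]
)


@pytest.fixture(scope="session")
def friendly_reference():
    """Reference whose affine makes the TrackVis voxel-mm map exact in fp:
    diagonal voxel size 2 with translation = voxel_size / 2."""
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = 1.0
    return SpatialReference((96, 96, 96), (2.0, 2.0, 2.0), affine)


@pytest.fixture(scope="session")
def outlier_bundle():
    """100-streamline bundle with 5 planted far outliers (offset >> 3 SD)."""
    spec = BundleSpec(
        "ARC_L", CENTERLINE, n_streamlines=100, radial_sd=1.0,
        outlier_fraction=0.05, outlier_offset=12.0, seed=7,
    )
    return make_bundle(spec)


@pytest.fixture(scope="session")
def clean_bundle():
    """60-streamline coherent bundle, no outliers."""
    spec = BundleSpec(
        "CST_L", CENTERLINE, n_streamlines=60, radial_sd=1.5, seed=11
    )
    return make_bundle(spec)


@pytest.fixture(scope="session")
def constant_map(clean_bundle):
    return make_scalar_map(
        clean_bundle.reference.shape, clean_bundle.reference.affine,
        lambda p: np.full(len(p), 0.5), metric_name="FA",
    )


@pytest.fixture(scope="session")
def x_map(clean_bundle):
    """Scalar map whose value equals the RAS x coordinate."""
    return make_scalar_map(
        clean_bundle.reference.shape, clean_bundle.reference.affine,
        lambda p: p[:, 0], metric_name="xcoord",
    )
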