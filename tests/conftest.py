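import numpy as np
import pytest

from nucmech import morpho, synthgen


@pytest.fixture(scope="session")
def flat_ellipsoid():
    """Noiseless voxelized oblate ellipsoid (z,y,x semi-axes 1.4112, 8, 8 um)
    with its segmentation and morphometry."""
    spec = synthgen.NucleusPhantomSpec(
        semi_axes=(1.4112, 8.0, 8.0), n_spots=0, snr=np.inf, seed=1
    )
    img, truth = synthgen.gen_nucleus_stack(spec)
    nucleus = morpho.segment_nucleus(img, 0.1)
    metrics = morpho.measure_nucleus(img, nucleus)
    return spec, img, truth, nucleus, metrics


@pytest.fixture(scope="session")
def spotted_phantom():
    """Confined-preset phantom: 8 well-separated 0.6-um spots at SNR 10."""
    spec = synthgen.NucleusPhantomSpec(
        semi_axes=(1.4112, 8.0, 8.0),
        n_spots=8,
        spot_diameter=0.6,
        min_spot_separation=2.0,
        snr=10.0,
        seed=3,
    )
    img, truth = synthgen.gen_nucleus_stack(spec)
    nucleus = morpho.segment_nucleus(img, 0.1)
    metrics = morpho.measure_nucleus(img, nucleus)
    return spec, img, truth, nucleus, metrics


@pytest.fixture(scope="session")
def voxel_sphere():
    """Binary voxel sphere, radius 20 voxels, isotropic unit voxels."""
    n = 47
    g = np.mgrid[:n, :n, :n] - (n - 1) / 2.0
    return (g[0] ** 2 + g[1] ** 2 + g[2] ** 2 <= 20.0**2).astype(np.int32)
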