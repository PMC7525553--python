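"""Shared fixtures: small synthetic patterns and PSF sets."""

import numpy as np
import pytest

from srsaxs.simulate import (
    GroundTruthPattern,
    PSFModel,
    default_psf_set,
    render_ground_truth,
    two_ring_pattern,
)


@pytest.fixture(scope="session")
def doublet_native():
    """Two rings (radii 30/34, width 0.9) on a native 129x129 grid (f=1)."""
    return two_ring_pattern(f=1, lr_grid=129)


@pytest.fixture(scope="session")
def doublet_native_gt(doublet_native):
    return render_ground_truth(doublet_native)


@pytest.fixture(scope="session")
def small_psf_pool():
    """Six slit x Gaussian kernels (slit sizes 2/3/4 px, sigma 0.5)."""
    return default_psf_set(2.0, source_sigma=0.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def subpixel_doublet():
    """Rings 2/3 detector pixel apart (resolvable only by sub-pixel sampling)."""
    return two_ring_pattern(
        r1=20.0,
        r2=20.0 + 2.0 / 3.0,
        width=0.2,
        amp1=10.0,
        amp2=10.0,
        f=3,
        lr_grid=61,
        background_coeff=2.0,
        beamstop_radius=3.0,
    )
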