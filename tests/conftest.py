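import dataclasses

import pytest

from oculens import phantom, ssoct


@pytest.fixture(scope="session")
def noise_free_params():
    return phantom.PhantomParams(speckle_sd=0.0)


@pytest.fixture(scope="session")
def noise_free_phantom(noise_free_params):
    """Default phantom B-scan without speckle, with ground truth."""
    return phantom.generate_bscan(noise_free_params)


@pytest.fixture(scope="session")
def noise_free_segmentation(noise_free_phantom):
    scan, _ = noise_free_phantom
    return ssoct.segment_lens(scan)


@pytest.fixture(scope="session")
def speckle_phantom():
    params = phantom.PhantomParams(speckle_sd=0.1, seed=11)
    return phantom.generate_bscan(params)


def randomized_params(rng, speckle_sd=0.0):
    """Draw phantom parameters with randomized lens surfaces and intensities.

    Varying apex depth, thickness and width reshapes both derived quartic
    surfaces; intensities move over clinically plausible contrast ranges
    while keeping chamber < cortex < nucleus ordering.
    """
    return phantom.PhantomParams(
        chamber_depth_px=int(rng.integers(150, 221)),
        lens_thickness_px=int(rng.integers(240, 321)),
        lens_width_px=int(rng.integers(500, 701)),
        intensity_chamber=float(rng.uniform(10, 30)),
        intensity_cortex=float(rng.uniform(80, 120)),
        intensity_nucleus=float(rng.uniform(125, 160)),
        speckle_sd=speckle_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
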