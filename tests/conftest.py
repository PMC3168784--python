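"""Shared fixtures: phantoms and AIFs are generated, never stored."""

import numpy as np
import pytest

from patlakp import generate_phantom
from patlakp.phantom import default_aif, default_phantom_spec


@pytest.fixture(scope="session")
def tri_aif():
    """Default bolus-shaped AIF with an exactly mono-exponential 0.04/min tail."""
    return default_aif()


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default 32x32x8 noiseless phantom: (spec, image, ground truth, aif)."""
    spec = default_phantom_spec(noise_sigma=0.0, seed=0)
    img, truth, aif = generate_phantom(spec)
    return spec, img, truth, aif


@pytest.fixture(scope="session")
def body_mask(noiseless_phantom):
    spec = noiseless_phantom[0]
    return spec.region_map > 0
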