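"""Shared fixtures: deterministic images, fields and sample sets."""

from __future__ import annotations

import numpy as np
import pytest

from cwriig.models import RiIGParams
from cwriig.synthetic import SpeckleConfig, simulate_speckle


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def speckle_image():
    """One 256 x 256 synthetic B-mode frame with a benign-style lesion."""
    return simulate_speckle(SpeckleConfig(seed=7))


@pytest.fixture(scope="session")
def random_image():
    return np.random.default_rng(42).random((256, 256))


@pytest.fixture(scope="session")
def riig_params():
    return RiIGParams(alpha=2.0, beta=0.0, delta=1.0)
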