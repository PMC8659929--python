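import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

import rnflseg as rs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free default phantom: no vessels, no floaters."""
    spec = rs.PhantomSpec()
    img, truth = rs.generate(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def clean_segmentation(clean_phantom):
    """Full pipeline result on the clean phantom (computed once)."""
    _, img, _ = clean_phantom
    return rs.segment(img)


@pytest.fixture(scope="session")
def vesseled_phantom():
    """Standard-conditions phantom: 5 vessels, 3 floaters, speckle sd 0.05."""
    spec = rs.standard_spec(seed=11, speckle_sd=0.05)
    img, truth = rs.generate(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def vesseled_segmentation(vesseled_phantom):
    _, img, _ = vesseled_phantom
    return rs.segment(img)
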