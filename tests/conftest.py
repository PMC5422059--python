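import numpy as np
import pytest

from branchnav.motion_detect import DetectionConfig
from branchnav.synthgen import ScanSpec, WalkSpec, gen_branch_image, gen_scan_trace, gen_walk_trace


@pytest.fixture(scope="session")
def detection_cfg() -> DetectionConfig:
    return DetectionConfig()


@pytest.fixture(scope="session")
def walk_trace():
    """One default-noise single-step walk (1 m at 0.44 m/s, seed 42)."""
    return gen_walk_trace(WalkSpec(step_lengths=[1.0], seed=42))


@pytest.fixture(scope="session")
def scan_trace():
    """One default low-speed branch scan (15 s, seed 0)."""
    return gen_scan_trace(ScanSpec(seed=0))


@pytest.fixture(scope="session")
def sharp_frame():
    """The designated sharp branch fixture (seed 7, no blur)."""
    frame, truth = gen_branch_image(seed=7, blur_sigma=0.0)
    return frame


@pytest.fixture(scope="session")
def blurred_frame():
    """Heavily defocused copy of the sharp fixture (sigma = 8 px)."""
    frame, truth = gen_branch_image(seed=7, blur_sigma=8.0)
    return frame


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
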