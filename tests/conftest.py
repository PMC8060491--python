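import numpy as np
import pytest

from vaskit.kymo import LineRoi
from vaskit.synth import FlowSimParams, simulate_vessel_movie


def centerline_roi(stack, inset: float = 2.0) -> LineRoi:
    """Axial ROI along the horizontal vessel center of a synthetic movie."""
    _, height, length = stack.shape
    cy = height / 2.0
    return LineRoi(points=[(inset, cy), (length - 1 - inset, cy)], kind="axial")


def cross_roi(stack, x: float | None = None) -> LineRoi:
    _, height, length = stack.shape
    x = length / 2.0 if x is None else x
    return LineRoi(points=[(x, 1.0), (x, height - 2.0)], kind="cross")


@pytest.fixture(scope="session")
def steady_flow_movie():
    """A young-like vessel movie at 2 px/frame used by several tests."""
    params = FlowSimParams(velocity_profile=2.0, seed=1)
    return params, simulate_vessel_movie(params)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
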