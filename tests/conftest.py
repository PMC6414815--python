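import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def render_disk(radius: float, shape=None, center=None) -> np.ndarray:
    """Rasterised disk mask (pixel centres within `radius` of the centre)."""
    if shape is None:
        n = int(2 * radius + 11)
        shape = (n, n)
    if center is None:
        center = (shape[0] // 2, shape[1] // 2)
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


@pytest.fixture
def disk20():
    return render_disk(20)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
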