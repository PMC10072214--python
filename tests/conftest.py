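import numpy as np
import pytest

from radsurv.volume import ImageVolume, VOIMask


@pytest.fixture(scope="session")
def unit_spacing():
    return (1.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def ball_mask():
    """Digital ball of radius 10 mm at 1 mm isotropic spacing."""
    n = 25
    c = (n - 1) / 2
    g = np.arange(n)
    xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
    arr = (xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2 <= 10.0**2
    return VOIMask(arr, (1.0, 1.0, 1.0))


@pytest.fixture
def toy_volume_4x4():
    """4x4x1 integer toy image with a full mask (printed fixture)."""
    vals = np.array(
        [[[1], [2], [5], [2]],
         [[3], [5], [1], [3]],
         [[1], [3], [5], [5]],
         [[3], [1], [1], [1]]],
        dtype=float,
    )
    vol = ImageVolume(vals, (1.0, 1.0, 1.0))
    mask = VOIMask(np.ones_like(vals, dtype=bool), (1.0, 1.0, 1.0))
    return vol, mask


@pytest.fixture(scope="session")
def survival_fixture_8():
    """8 patients with censoring, distinct times, known risks."""
    time = np.array([2.0, 5.0, 7.0, 11.0, 13.0, 17.0, 19.0, 23.0])
    event = np.array([1, 0, 1, 1, 0, 1, 0, 1])
    risk = np.array([3.1, 2.0, 2.0, 1.5, 0.7, 0.9, 0.9, 0.1])
    return time, event, risk
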