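import numpy as np
import pytest

from pris.imaging import CTVolume, TumorMask


@pytest.fixture
def disk_phantom():
    """Disk tumor of radius 20 px centered in a 90x90 uniform 40-HU slice,
    1 mm grid: the analytic-annulus geometry fixture."""
    n = 90
    yy, xx = np.mgrid[0:n, 0:n]
    disk = ((yy - 45) ** 2 + (xx - 45) ** 2) <= 20 ** 2
    vol = CTVolume(np.full((n, n, 1), 40.0), (1.0, 1.0, 1.0))
    mask = TumorMask(disk[:, :, None], (1.0, 1.0, 1.0))
    return vol, mask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
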