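import numpy as np
import pytest

from scoutlmd.image_io import ImageGrid
from scoutlmd.phantom import PhantomSpec, make_phantom
from scoutlmd.voi import build_voi_set, segment_body


@pytest.fixture(scope="session")
def default_phantom():
    """One default-geometry phantom shared by read-only tests."""
    return make_phantom(PhantomSpec(), seed=1)


@pytest.fixture(scope="session")
def default_vois(default_phantom):
    body = segment_body(default_phantom.density)
    return build_voi_set(default_phantom.labels, body, margin_mm=20.0)


@pytest.fixture
def small_grid():
    return ImageGrid(dims=(16, 16, 16), spacing_mm=(2.0, 2.0, 3.0))


def brute_force_dilate(members: np.ndarray, spacing, margin_mm: float) -> np.ndarray:
    """O(N*M) nearest-member-distance dilation oracle (voxel-centre metric)."""
    spacing = np.asarray(spacing, dtype=float)
    member_mm = np.argwhere(members) * spacing
    all_mm = np.indices(members.shape).reshape(3, -1).T * spacing
    d2 = ((all_mm[:, None, :] - member_mm[None, :, :]) ** 2).sum(-1).min(1)
    return (np.sqrt(d2) <= margin_mm).reshape(members.shape)
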