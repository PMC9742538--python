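import numpy as np
import pytest

from biofilmoct import DEFAULT_GEOMETRY, PhantomSpec, SegmentationParams


def brute_force_median(image: np.ndarray, kernel: int) -> np.ndarray:
    """Independent neighborhood-median oracle: explicit double loop with
    edge replication via index clipping."""
    h, w = image.shape
    r = kernel // 2
    out = np.empty_like(image, dtype=float)
    for i in range(h):
        for j in range(w):
            vals = []
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii = min(max(i + di, 0), h - 1)
                    jj = min(max(j + dj, 0), w - 1)
                    vals.append(image[ii, jj])
            out[i, j] = np.median(vals)
    return out


@pytest.fixture
def geometry():
    return DEFAULT_GEOMETRY


@pytest.fixture
def default_params():
    return SegmentationParams()


@pytest.fixture
def small_flat_spec():
    """A quick noiseless flat-slab phantom (30 voxels = 43.5 μm)."""
    return PhantomSpec(shape=(4, 128, 48), surface_depth_row=80,
                       thickness_params={"T": 43.5}, seed=7)
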