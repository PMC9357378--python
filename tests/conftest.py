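import numpy as np
import pytest

from organoidmorph.imaging_core import ImageStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_square_image():
    """A single-channel 2D field with two separated bright 4x4 squares."""
    arr = np.zeros((32, 32))
    arr[4:8, 4:8] = 100.0
    arr[20:24, 20:24] = 100.0
    return ImageStack(arr, (1.0, 1.0, 1.0), ["ZO1"])


def brute_force_label_count(mask: np.ndarray) -> int:
    """Flood-fill component count under face connectivity (independent oracle)."""
    mask = np.asarray(mask, dtype=bool)
    visited = np.zeros_like(mask)
    count = 0
    offsets = []
    for axis in range(mask.ndim):
        for d in (-1, 1):
            off = [0] * mask.ndim
            off[axis] = d
            offsets.append(tuple(off))
    for start in zip(*np.nonzero(mask & ~visited)):
        if visited[start]:
            continue
        count += 1
        stack = [start]
        visited[start] = True
        while stack:
            cur = stack.pop()
            for off in offsets:
                nxt = tuple(c + o for c, o in zip(cur, off))
                if any(i < 0 or i >= s for i, s in zip(nxt, mask.shape)):
                    continue
                if mask[nxt] and not visited[nxt]:
                    visited[nxt] = True
                    stack.append(nxt)
    return count
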