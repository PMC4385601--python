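import numpy as np
import pytest

from cervicell.features import NormalReference
from cervicell.regions import LabeledMask, RegionRecord, extract_regions


@pytest.fixture
def ref() -> NormalReference:
    return NormalReference()


def polar_mask(radius_fn, size: int) -> np.ndarray:
    """Rasterize r(theta) about the canvas centre: pixel-centre-inside rule."""
    yy, xx = np.mgrid[:size, :size]
    cy = cx = size / 2 - 0.5
    th = np.arctan2(yy - cy, xx - cx)
    rr = np.hypot(yy - cy, xx - cx)
    return rr <= radius_fn(th)


def disk_mask(r: float, size: int | None = None) -> np.ndarray:
    size = size or int(2 * r + 6)
    return polar_mask(lambda t: r, size)


def ellipse_mask(a: float, b: float, size: int | None = None) -> np.ndarray:
    size = size or int(2 * a + 6)
    return polar_mask(lambda t: a * b / np.hypot(b * np.cos(t), a * np.sin(t)), size)


def star_mask(R: float, lobes: int, amp: float, rot: float = 0.0, size: int | None = None) -> np.ndarray:
    size = size or int(2 * R * (1 + amp) + 8)
    return polar_mask(lambda t: R * (1 + amp * np.cos(lobes * (t - rot))), size)


def region_of(mask: np.ndarray) -> RegionRecord:
    """Extract the single region of a boolean mask."""
    recs = extract_regions(LabeledMask(mask.astype(int)))
    assert len(recs) == 1
    return recs[0]
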