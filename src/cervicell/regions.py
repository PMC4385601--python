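"""Label-mask handling: region extraction, binary cleanup, nucleus-cell pairing.

Conventions used throughout the package:

* pixel indexing is 0-based ``(row, col)``; centroids are sub-pixel floats;
* region labeling uses 8-connectivity;
* outer boundaries are traced clockwise with the Moore neighbourhood and
  returned as ordered pixel coordinates (closed: last point 8-adjacent to
  the first).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .exceptions import ConfigError, FormatError, PairingError

__all__ = [
    "LabeledMask",
    "RegionRecord",
    "CellNucleusPair",
    "load_label_mask",
    "morph_cleanup",
    "extract_regions",
    "pair_nucleus_to_cell",
    "regions_to_frame",
]

_EIGHT = np.ones((3, 3), bool)

# Moore neighbourhood offsets, clockwise starting due north.
_OFFS = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))

# Chain-length coefficients (straight step, diagonal step, corner penalty).
# The naive 1/sqrt(2)-weighted chain length overestimates smooth contours by
# ~5%, which would push the circularity of a digitised disk down to ~0.90;
# the corner-corrected estimator keeps it within a couple of percent of 1.
_L_STRAIGHT, _L_DIAG, _L_CORNER = 0.980, 1.406, -0.091

_MORPH_OPS = ("dilate", "erode", "open", "close", "fill")


@dataclass(frozen=True)
class LabeledMask:
    """2-D integer label image: 0 = background, k > 0 = region k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise FormatError(f"label mask must be 2-D, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise FormatError(f"label mask must be integer, got dtype {arr.dtype}")
        if arr.size and arr.min() < 0:
            raise FormatError("label mask contains negative labels")
        object.__setattr__(self, "labels", arr)

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    @property
    def labels_present(self) -> np.ndarray:
        """Sorted array of the positive labels present in the mask."""
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def n_regions(self) -> int:
        return int(self.labels_present.size)


@dataclass
class RegionRecord:
    """One labeled connected region.

    ``coords`` holds every member pixel as ``(row, col)``; ``boundary`` is
    the clockwise-traced outer contour (ordered, closed).
    """

    label: int
    area: int
    perimeter: float
    centroid: tuple[float, float]  # (row, col), sub-pixel
    coords: np.ndarray  # (area, 2) int
    boundary: np.ndarray  # (n_boundary, 2) int

    @property
    def centroid_xy(self) -> tuple[float, float]:
        """Centroid as (x, y) = (col, row), for tabular output."""
        return (self.centroid[1], self.centroid[0])


@dataclass
class CellNucleusPair:
    """A nucleus linked to its owner cell by minimum centroid distance."""

    cell: RegionRecord
    nucleus: RegionRecord
    centroid_distance: float
    nucleus_outside_cell: bool = False


def load_label_mask(path: str | Path) -> LabeledMask:
    """Read a PNG/TIFF label mask.

    Pixel values are taken as region labels; an image with exactly two
    values {0, v} is treated as binary and connected-component labeled with
    8-connectivity.  RGB images are accepted when all channels agree.
    """
    try:
        arr = iio.imread(path)
    except OSError as exc:  # pragma: no cover - passthrough of I/O failure
        raise OSError(f"cannot read mask {path!r}: {exc}") from exc
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[..., :3]
        if not (arr[..., 0:1] == arr).all():
            raise FormatError(f"{path}: RGB mask with disagreeing channels")
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected 2-D mask, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.floating):
        if not np.all(np.mod(arr, 1) == 0):
            raise FormatError(f"{path}: non-integer pixel data in label mask")
        arr = arr.astype(np.int64)
    vals = np.unique(arr)
    pos = vals[vals > 0]
    if pos.size == 1:  # binary image: label components
        lab, _ = ndi.label(arr > 0, structure=_EIGHT)
        return LabeledMask(lab)
    return LabeledMask(arr.astype(np.int64))


def _disk_footprint(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (yy * yy + xx * xx) <= radius * radius


def morph_cleanup(
    mask: LabeledMask, ops: Sequence[str], radius: int = 1
) -> LabeledMask:
    """Apply named binary morphology operators, in order, per region.

    Each region is treated as its own binary image so that neighbouring
    labels cannot merge.  ``fill`` closes interior holes.  Where a dilation
    makes regions collide, the lower label wins.
    """
    if radius < 1:
        raise ConfigError(f"radius must be >= 1, got {radius}")
    for op in ops:
        if op not in _MORPH_OPS:
            raise ConfigError(f"unknown morphology operator {op!r}; known: {_MORPH_OPS}")
    fp = _disk_footprint(radius)
    out = np.zeros_like(mask.labels)
    for lab in mask.labels_present:
        b = mask.labels == lab
        for op in ops:
            if op == "dilate":
                b = ndi.binary_dilation(b, structure=fp)
            elif op == "erode":
                b = ndi.binary_erosion(b, structure=fp)
            elif op == "open":
                b = ndi.binary_opening(b, structure=fp)
            elif op == "close":
                b = ndi.binary_closing(b, structure=fp)
            else:  # fill
                b = ndi.binary_fill_holes(b)
        out[b & (out == 0)] = lab
    return LabeledMask(out)


def _trace_boundary(sub: np.ndarray) -> np.ndarray:
    """Clockwise Moore-neighbour trace of one region's outer contour.

    ``sub`` is a 2-D boolean array containing a single 8-connected region.
    Returns ordered (row, col) boundary pixels; pixels on one-pixel-wide
    spurs may appear more than once (the trace walks around them).
    """
    ys, xs = np.nonzero(sub)
    if ys.size == 0:
        raise ValueError("empty region")
    start = (int(ys[0]), int(xs[0]))  # row-major first => uppermost-leftmost
    if ys.size == 1:
        return np.array([start], dtype=np.int64)
    h, w = sub.shape
    pts: list[tuple[int, int]] = []
    cur = start
    prev = 6  # backtrack direction: the (background) west neighbour of start
    first_move = -1
    max_steps = 4 * int(sub.sum()) + 8
    for _ in range(max_steps):
        for k in range(1, 9):
            d = (prev + k) % 8
            q = (cur[0] + _OFFS[d][0], cur[1] + _OFFS[d][1])
            if 0 <= q[0] < h and 0 <= q[1] < w and sub[q]:
                break
        else:  # isolated pixel; unreachable for size > 1 connected input
            return np.array([cur], dtype=np.int64)
        if first_move < 0:
            first_move = d
        elif cur == start and d == first_move:
            return np.asarray(pts, dtype=np.int64)
        pts.append(cur)
        cur = q
        prev = (d + 5) % 8  # next scan starts just past the previous contour
    raise RuntimeError("boundary trace failed to close")  # pragma: no cover


_STEP_CODE = {off: i for i, off in enumerate(_OFFS)}


def _chain_perimeter(boundary: np.ndarray) -> float:
    """Corner-corrected chain-code length of a closed boundary."""
    n = len(boundary)
    if n == 1:
        return 4.0  # unit-square convention
    if n == 2:
        return 6.0  # domino convention
    closed = np.vstack([boundary, boundary[:1]])
    steps = np.diff(closed, axis=0)
    dirs = np.array([_STEP_CODE[(int(dy), int(dx))] for dy, dx in steps])
    n_diag = int((np.abs(steps).sum(axis=1) == 2).sum())
    n_straight = len(steps) - n_diag
    n_corner = int((dirs != np.roll(dirs, 1)).sum())
    return _L_STRAIGHT * n_straight + _L_DIAG * n_diag + _L_CORNER * n_corner


def extract_regions(mask: LabeledMask) -> list[RegionRecord]:
    """Extract one :class:`RegionRecord` per positive label.

    Centroid is the arithmetic mean of member pixel coordinates; the
    perimeter comes from the traced chain code.  An empty mask yields an
    empty list.
    """
    records: list[RegionRecord] = []
    labels = mask.labels
    if labels.size == 0 or mask.n_regions == 0:
        return records
    slices = ndi.find_objects(labels)
    for lab in mask.labels_present:
        sl = slices[int(lab) - 1] if int(lab) - 1 < len(slices) else None
        if sl is None:  # non-contiguous numbering handled the slow way
            sub_full = labels == lab
            ys, xs = np.nonzero(sub_full)
            sl = (slice(ys.min(), ys.max() + 1), slice(xs.min(), xs.max() + 1))
        sub = labels[sl] == lab
        ys, xs = np.nonzero(sub)
        off = np.array([sl[0].start, sl[1].start], dtype=np.int64)
        coords = np.column_stack([ys, xs]).astype(np.int64) + off
        centroid = (float(coords[:, 0].mean()), float(coords[:, 1].mean()))
        boundary = _trace_boundary(sub) + off
        records.append(
            RegionRecord(
                label=int(lab),
                area=int(coords.shape[0]),
                perimeter=float(_chain_perimeter(boundary - off)),
                centroid=centroid,
                coords=coords,
                boundary=boundary,
            )
        )
    return records


def _point_in_region(
    region: RegionRecord, point: tuple[int, int], bbox: np.ndarray
) -> bool:
    r, c = point
    if not (bbox[0] <= r <= bbox[2] and bbox[1] <= c <= bbox[3]):
        return False
    return bool(((region.coords[:, 0] == r) & (region.coords[:, 1] == c)).any())


def pair_nucleus_to_cell(
    cells: Sequence[RegionRecord], nuclei: Sequence[RegionRecord]
) -> list[CellNucleusPair]:
    """Assign each nucleus to the cell with minimum centroid distance.

    Ties are broken toward the lower cell label.  A cell may own several
    nuclei (binucleation).  Nuclei whose centroid pixel does not fall inside
    any cell region are still paired but flagged ``nucleus_outside_cell``.
    """
    if len(cells) == 0:
        raise PairingError("cannot pair nuclei: empty cell list")
    if len(nuclei) == 0:
        return []
    cells_sorted = sorted(cells, key=lambda r: r.label)
    cell_cent = np.array([c.centroid for c in cells_sorted])
    bboxes = np.array(
        [np.concatenate([c.coords.min(axis=0), c.coords.max(axis=0)]) for c in cells_sorted]
    )
    pairs: list[CellNucleusPair] = []
    for nuc in sorted(nuclei, key=lambda r: r.label):
        d = np.hypot(
            cell_cent[:, 0] - nuc.centroid[0], cell_cent[:, 1] - nuc.centroid[1]
        )
        j = int(np.argmin(d))  # first occurrence -> lowest label on ties
        px = (int(round(nuc.centroid[0])), int(round(nuc.centroid[1])))
        inside = any(
            _point_in_region(c, px, bb) for c, bb in zip(cells_sorted, bboxes)
        )
        pairs.append(
            CellNucleusPair(
                cell=cells_sorted[j],
                nucleus=nuc,
                centroid_distance=float(d[j]),
                nucleus_outside_cell=not inside,
            )
        )
    return pairs


def regions_to_frame(records: Iterable[RegionRecord]) -> pd.DataFrame:
    """Tabulate regions as label, area_px, perimeter_px, centroid_x, centroid_y."""
    rows = [
        {
            "label": r.label,
            "area_px": r.area,
            "perimeter_px": r.perimeter,
            "centroid_x": r.centroid_xy[0],
            "centroid_y": r.centroid_xy[1],
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["label", "area_px", "perimeter_px", "centroid_x", "centroid_y"])
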