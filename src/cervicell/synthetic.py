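"""Synthetic stained-cell scenes with exact ground truth.

Generates RGB images plus cell/nucleus label masks that emulate stained
squamous epithelium: elliptical-to-lobed nuclei inside larger cytoplasm
blobs, with per-stage color and size profiles (jacinth cytoplasm for
LSIL-like cells, dark meganuclei for SCC-like cells).  Every scene records
its ground truth from the rasterized masks, so truth areas equal mask pixel
counts exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .decision import Grade
from .exceptions import ConfigError, GeometryError, PlacementError
from .features import NormalReference
from .regions import LabeledMask

__all__ = [
    "ShapeSpec",
    "CellSpec",
    "SyntheticScene",
    "make_cell",
    "make_population",
    "STAGE_PROFILES",
]

BACKGROUND_RGB = (236.0, 228.0, 238.0)


@dataclass(frozen=True)
class ShapeSpec:
    """Nucleus outline: circle, ellipse(axis_ratio) or star(lobes, amplitude).

    A star has radius ``R * (1 + amplitude * cos(lobes * theta))``; its
    radial signature therefore carries exactly ``2 * lobes`` significant
    extrema.
    """

    kind: str = "circle"  # circle | ellipse | star
    axis_ratio: float = 1.0
    lobes: int = 3
    amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("circle", "ellipse", "star"):
            raise ConfigError(f"unknown shape kind {self.kind!r}")
        if self.kind == "ellipse" and self.axis_ratio < 1.0:
            raise ConfigError("axis_ratio must be >= 1")
        if self.kind == "star":
            if self.lobes < 2:
                raise ConfigError("star needs lobes >= 2")
            if not 0 <= self.amplitude < 1:
                raise ConfigError("star amplitude must be in [0, 1)")

    @property
    def expected_extrema(self) -> int:
        if self.kind == "circle":
            return 0
        if self.kind == "ellipse":
            return 4 if self.axis_ratio > 1.0 else 0
        return 2 * self.lobes

    def radius_fn(self, area: float, rotation: float) -> Callable[[np.ndarray], np.ndarray]:
        """Polar radius function scaled so the enclosed area matches ``area``."""
        if self.kind == "circle" or (self.kind == "ellipse" and self.axis_ratio == 1.0):
            r = math.sqrt(area / math.pi)
            return lambda th: np.full_like(th, r, dtype=float)
        if self.kind == "ellipse":
            r = math.sqrt(area / math.pi)
            a = r * math.sqrt(self.axis_ratio)
            b = r / math.sqrt(self.axis_ratio)
            return lambda th: a * b / np.hypot(
                b * np.cos(th - rotation), a * np.sin(th - rotation)
            )
        # star: area of r = R(1 + e cos(k theta)) is pi R^2 (1 + e^2 / 2)
        R = math.sqrt(area / (math.pi * (1.0 + self.amplitude**2 / 2.0)))
        return lambda th: R * (1.0 + self.amplitude * np.cos(self.lobes * (th - rotation)))

    def max_radius(self, area: float) -> float:
        if self.kind == "circle":
            return math.sqrt(area / math.pi)
        if self.kind == "ellipse":
            return math.sqrt(area / math.pi) * math.sqrt(self.axis_ratio)
        R = math.sqrt(area / (math.pi * (1.0 + self.amplitude**2 / 2.0)))
        return R * (1.0 + self.amplitude)


@dataclass(frozen=True)
class CellSpec:
    """Target parameters for one synthetic cell."""

    stage: Grade = Grade.NORMAL
    nucleus_shape: ShapeSpec = field(default_factory=ShapeSpec)
    nucleus_area: float = 600.0
    cell_area: float = 6600.0
    nucleus_rgb: tuple[float, float, float] = (135.0, 115.0, 170.0)
    cytoplasm_rgb: tuple[float, float, float] = (205.0, 175.0, 215.0)
    noise_sd: float = 0.0
    position: tuple[float, float] = (0.0, 0.0)  # (row, col)
    rotation: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.nucleus_area < self.cell_area:
            raise ConfigError("need cell_area > nucleus_area > 0")
        for trip in (self.nucleus_rgb, self.cytoplasm_rgb):
            if any(not 0 <= c <= 255 for c in trip):
                raise ConfigError(f"channels must be in [0, 255], got {trip}")

    @property
    def cell_radius(self) -> float:
        return math.sqrt(self.cell_area / math.pi)


@dataclass
class SyntheticScene:
    """RGB image + label masks + exact per-cell ground truth."""

    image: np.ndarray  # (H, W, 3) uint8
    cell_mask: LabeledMask
    nucleus_mask: LabeledMask
    truth: pd.DataFrame
    specs: list[CellSpec]
    seed: int


def _rasterize_polar(
    canvas_shape: tuple[int, int],
    center: tuple[float, float],
    radius_fn: Callable[[np.ndarray], np.ndarray],
    max_radius: float,
) -> tuple[tuple[slice, slice], np.ndarray]:
    """Window slice + local boolean mask of pixels inside r(theta)."""
    h, w = canvas_shape
    cy, cx = center
    r0 = int(np.floor(cy - max_radius - 1))
    r1 = int(np.ceil(cy + max_radius + 2))
    c0 = int(np.floor(cx - max_radius - 1))
    c1 = int(np.ceil(cx + max_radius + 2))
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise GeometryError("shape does not fit inside the canvas")
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy = yy - cy
    dx = xx - cx
    rr = np.hypot(dy, dx)
    th = np.arctan2(dy, dx)
    return (slice(r0, r1), slice(c0, c1)), rr <= radius_fn(th)


def _paint(
    patch: np.ndarray, mask: np.ndarray, rgb: Sequence[float], sd: float, rng: np.random.Generator
) -> None:
    n = int(mask.sum())
    vals = np.tile(np.asarray(rgb, float), (n, 1))
    if sd > 0:
        vals = vals + rng.normal(0.0, sd, size=vals.shape)
    patch[mask] = np.clip(vals, 0, 255)


def _render(
    specs: Sequence[CellSpec], canvas_shape: tuple[int, int], seed: int
) -> SyntheticScene:
    rng = np.random.default_rng(seed)
    image = np.zeros(canvas_shape + (3,), dtype=float)
    image[:, :] = BACKGROUND_RGB
    cell_lab = np.zeros(canvas_shape, dtype=np.int32)
    nuc_lab = np.zeros(canvas_shape, dtype=np.int32)
    rows = []
    for i, spec in enumerate(specs, start=1):
        cell_fn = ShapeSpec("circle").radius_fn(spec.cell_area, 0.0)
        sl, cmask = _rasterize_polar(
            canvas_shape, spec.position, cell_fn, spec.cell_radius
        )
        nfn = spec.nucleus_shape.radius_fn(spec.nucleus_area, spec.rotation)
        nsl, nmask_local = _rasterize_polar(
            canvas_shape,
            spec.position,
            nfn,
            spec.nucleus_shape.max_radius(spec.nucleus_area),
        )
        # embed the (smaller) nucleus window inside the cell window
        nmask = np.zeros_like(cmask)
        nmask[
            nsl[0].start - sl[0].start : nsl[0].stop - sl[0].start,
            nsl[1].start - sl[1].start : nsl[1].stop - sl[1].start,
        ] = nmask_local
        if (nmask & ~cmask).any():
            raise GeometryError(f"cell {i}: nucleus extends beyond the cytoplasm")
        if (cell_lab[sl][cmask] != 0).any():
            raise GeometryError(f"cell {i}: overlaps a previously placed cell")
        _paint(image[sl], cmask & ~nmask, spec.cytoplasm_rgb, spec.noise_sd, rng)
        _paint(image[sl], nmask, spec.nucleus_rgb, spec.noise_sd, rng)
        cell_lab[sl][cmask] = i
        nuc_lab[sl][nmask] = i
        nys, nxs = np.nonzero(nmask)
        nys, nxs = nys + sl[0].start, nxs + sl[1].start
        cys, cxs = np.nonzero(cmask)
        cys, cxs = cys + sl[0].start, cxs + sl[1].start
        rows.append(
            {
                "cell_id": i,
                "stage": spec.stage.value,
                "nucleus_area": int(nmask.sum()),
                "cell_area": int(cmask.sum()),
                "nucleus_centroid_y": float(nys.mean()),
                "nucleus_centroid_x": float(nxs.mean()),
                "cell_centroid_y": float(cys.mean()),
                "cell_centroid_x": float(cxs.mean()),
                "nucleus_shape": spec.nucleus_shape.kind,
                "expected_N": spec.nucleus_shape.expected_extrema,
                "nuc_R": spec.nucleus_rgb[0],
                "nuc_G": spec.nucleus_rgb[1],
                "nuc_B": spec.nucleus_rgb[2],
                "cyt_R": spec.cytoplasm_rgb[0],
                "cyt_G": spec.cytoplasm_rgb[1],
                "cyt_B": spec.cytoplasm_rgb[2],
            }
        )
    truth = pd.DataFrame(rows)
    return SyntheticScene(
        image=np.clip(np.round(image), 0, 255).astype(np.uint8),
        cell_mask=LabeledMask(cell_lab),
        nucleus_mask=LabeledMask(nuc_lab),
        truth=truth,
        specs=list(specs),
        seed=seed,
    )


def make_cell(spec: CellSpec, seed: int = 0) -> SyntheticScene:
    """Render a single-cell scene on a canvas that just fits the cell."""
    margin = 4
    side = int(math.ceil(2 * spec.cell_radius)) + 2 * margin + 2
    centered = replace(spec, position=(side / 2.0, side / 2.0))
    return _render([centered], (side, side), seed)


# ---------------------------------------------------------------------------
# population profiles
#
# Each stage draws sizes/ratios/colors with margins wide enough that the
# measured features land on the intended side of every detection criterion
# and grading rule:
#   NORMAL  passes no criterion;
#   LSIL    jacinth cytoplasm (Criterion 4 bands), nucleus ~3x reference,
#           grad_P < 5 with a pale-enough nucleus (LSIL grading rule);
#   HSIL    enlarged nucleus with 5 < grad_P < 10, failing both the SCC and
#           LSIL grading rules (residual class);
#   SCC     dark meganucleus (Criterion 5), grad_A > 2 and grad_P > 10.
# ---------------------------------------------------------------------------


def _profile_normal(ref: NormalReference, rng: np.random.Generator) -> CellSpec:
    area = ref.area * rng.uniform(0.9, 1.1)
    nc = ref.nc * rng.uniform(0.85, 1.2)
    return CellSpec(
        stage=Grade.NORMAL,
        nucleus_shape=ShapeSpec("circle"),
        nucleus_area=area,
        cell_area=area + area / nc,
        nucleus_rgb=(135.0, 115.0, 170.0),
        cytoplasm_rgb=(205.0, 175.0, 215.0),
        noise_sd=4.0,
        rotation=rng.uniform(0, 2 * np.pi),
    )


def _profile_lsil(ref: NormalReference, rng: np.random.Generator) -> CellSpec:
    area = ref.area * rng.uniform(3.0, 3.5)
    nc = ref.nc * rng.uniform(2.2, 3.2)
    return CellSpec(
        stage=Grade.LSIL,
        nucleus_shape=ShapeSpec("ellipse", axis_ratio=1.25),
        nucleus_area=area,
        cell_area=area + area / nc,
        nucleus_rgb=(150.0, 100.0, 150.0),
        cytoplasm_rgb=(145.0, 105.0, 155.0),
        noise_sd=4.0,
        rotation=rng.uniform(0, 2 * np.pi),
    )


def _profile_hsil(ref: NormalReference, rng: np.random.Generator) -> CellSpec:
    area = ref.area * rng.uniform(2.8, 3.3)
    nc = ref.nc * rng.uniform(6.5, 8.0)
    return CellSpec(
        stage=Grade.HSIL,
        nucleus_shape=ShapeSpec("ellipse", axis_ratio=1.4),
        nucleus_area=area,
        cell_area=area + area / nc,
        nucleus_rgb=(150.0, 135.0, 215.0),
        cytoplasm_rgb=(185.0, 150.0, 205.0),
        noise_sd=4.0,
        rotation=rng.uniform(0, 2 * np.pi),
    )


def _profile_scc(ref: NormalReference, rng: np.random.Generator) -> CellSpec:
    area = ref.area * rng.uniform(3.5, 4.5)
    nc = ref.nc * rng.uniform(12.0, 16.0)
    return CellSpec(
        stage=Grade.SCC,
        nucleus_shape=ShapeSpec("star", lobes=3, amplitude=0.18),
        nucleus_area=area,
        cell_area=area + area / nc,
        nucleus_rgb=(70.0, 70.0, 120.0),
        cytoplasm_rgb=(140.0, 90.0, 140.0),
        noise_sd=4.0,
        rotation=rng.uniform(0, 2 * np.pi),
    )


STAGE_PROFILES = {
    Grade.NORMAL: _profile_normal,
    Grade.LSIL: _profile_lsil,
    Grade.HSIL: _profile_hsil,
    Grade.SCC: _profile_scc,
}

_STAGE_ORDER = (Grade.NORMAL, Grade.LSIL, Grade.HSIL, Grade.SCC)


def _stage_counts(n: int, stage_mix: Sequence[float]) -> list[int]:
    mix = np.asarray(stage_mix, dtype=float)
    if mix.size != 4 or (mix < 0).any():
        raise ConfigError("stage_mix needs 4 non-negative fractions (NORMAL, LSIL, HSIL, SCC)")
    if abs(mix.sum() - 1.0) > 1e-6:
        raise ConfigError(f"stage_mix must sum to 1, got {mix.sum()}")
    raw = mix * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    for i in np.argsort(-(raw - counts))[:rem]:
        counts[i] += 1
    return counts.tolist()


def make_population(
    n: int,
    stage_mix: Sequence[float],
    ref: NormalReference | None = None,
    seed: int = 0,
    fill_fraction: float = 0.25,
    max_tries: int = 500,
) -> SyntheticScene:
    """Render ``n`` non-overlapping cells with the given stage mix.

    Positions are drawn by rejection sampling against the already placed
    cells (disjoint bounding circles).  Deterministic for a fixed seed.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    ref = ref or NormalReference()
    rng = np.random.default_rng(seed)
    counts = _stage_counts(n, stage_mix)
    stages = [s for s, c in zip(_STAGE_ORDER, counts) for _ in range(c)]
    rng.shuffle(stages)
    specs = [STAGE_PROFILES[s](ref, rng) for s in stages]
    radii = np.array([s.cell_radius for s in specs])
    side = int(math.ceil(math.sqrt(np.pi * ((radii + 2) ** 2).sum() / fill_fraction)))
    side = max(side, int(2 * radii.max() + 12))
    placed: list[tuple[float, float, float]] = []
    positioned = []
    for spec, r in zip(specs, radii):
        lo, hi = r + 3.0, side - r - 3.0
        for _ in range(max_tries):
            y = rng.uniform(lo, hi)
            x = rng.uniform(lo, hi)
            if all(math.hypot(y - py, x - px) > r + pr + 2.0 for py, px, pr in placed):
                placed.append((y, x, r))
                positioned.append(replace(spec, position=(y, x)))
                break
        else:
            raise PlacementError(
                f"could not place cell {len(positioned) + 1}/{n} after {max_tries} tries"
            )
    return _render(positioned, (side, side), seed=int(rng.integers(2**31)))
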