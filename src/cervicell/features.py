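"""Quantified per-cell descriptors.

Size ratios, nucleus/cytoplasm ratio, circularity, compactness, the
radial-signature shape descriptor (count of significant peaks and valleys
of the centroid-to-boundary distance curve), and per-compartment mean RGB
color strength.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .exceptions import (
    ConfigError,
    DegenerateInputError,
    GeometryError,
    ValidationError,
)
from .regions import CellNucleusPair, RegionRecord

__all__ = [
    "NormalReference",
    "FeatureConfig",
    "RadialSignature",
    "FeatureVector",
    "area_ratio",
    "nc_ratio",
    "circularity",
    "compactness",
    "radial_signature",
    "string_shape_descriptor",
    "color_strength",
    "extract_features",
    "features_to_frame",
    "frame_to_features",
]

#: FeatureVector fields written to / read from the feature CSV, in order.
FEATURE_COLUMNS = [
    "pair_id",
    "A",
    "grad_A",
    "P",
    "grad_P",
    "C",
    "E",
    "N",
    "nuc_R",
    "nuc_G",
    "nuc_B",
    "cyt_R",
    "cyt_G",
    "cyt_B",
    "flags",
]


@dataclass(frozen=True)
class NormalReference:
    """Normal-cell reference values and criterion thresholds.

    ``area``/``nc`` are the reference nucleus size (px) and N/C ratio of
    normal cells; the remaining fields are the decision thresholds: ratio
    caps for Criterion 1, shape floors for Criterion 2, the extrema cap for
    Criterion 3, the jacinth (orange-red) cytoplasm color bands for
    Criterion 4 and the dark-nucleus upper bounds for Criterion 5.
    """

    area: float = 600.0
    nc: float = 0.1
    area_ratio_max: float = 2.5
    nc_ratio_max: float = 2.0
    circularity_min: float = 0.8
    compactness_min: float = 0.7
    extrema_max: int = 4
    jacinth_r: tuple[float, float] = (120.0, 170.0)
    jacinth_g: tuple[float, float] = (70.0, 140.0)
    jacinth_b: tuple[float, float] = (120.0, 190.0)
    dark_r: float = 90.0
    dark_g: float = 90.0
    dark_b: float = 190.0

    def __post_init__(self) -> None:
        if self.area <= 0 or self.nc <= 0:
            raise ConfigError("reference area and nc must be positive")
        if not 0 < self.circularity_min <= 1:
            raise ConfigError("circularity_min must be in (0, 1]")
        if not 0 < self.compactness_min <= 1:
            raise ConfigError("compactness_min must be in (0, 1]")
        if self.extrema_max < 0:
            raise ConfigError("extrema_max must be >= 0")
        for name in ("jacinth_r", "jacinth_g", "jacinth_b"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ConfigError(f"{name}: lower bound {lo} must be < upper bound {hi}")


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs for descriptor computation.

    ``signature_fit`` selects how the radial signature is smoothed before
    extrema counting: a truncated Fourier series (periodic, start-point
    independent; default) or a plain polynomial in the angle.
    """

    fit_order: int = 8
    amp_tol: float = 0.03
    min_amplitude_px: float = 0.8
    signature_fit: str = "fourier"  # or "poly"
    poly_order: int = 10
    compactness_variant: str = "solidity"  # or "extent"
    nc_denominator: str = "cytoplasm"  # or "cell"

    def __post_init__(self) -> None:
        if self.fit_order < 4:
            raise ConfigError("fit_order must be >= 4")
        if not 0 <= self.amp_tol < 1:
            raise ConfigError("amp_tol must be in [0, 1)")
        if self.min_amplitude_px < 0:
            raise ConfigError("min_amplitude_px must be >= 0")
        if self.signature_fit not in ("fourier", "poly"):
            raise ConfigError(f"unknown signature_fit {self.signature_fit!r}")
        if self.compactness_variant not in ("solidity", "extent"):
            raise ConfigError(f"unknown compactness_variant {self.compactness_variant!r}")
        if self.nc_denominator not in ("cytoplasm", "cell"):
            raise ConfigError(f"unknown nc_denominator {self.nc_denominator!r}")


@dataclass
class RadialSignature:
    """Centroid-to-boundary distances ordered by polar angle."""

    angles: np.ndarray  # radians in [0, 2*pi), strictly increasing
    distances: np.ndarray  # px, same length
    non_star_shaped: bool = False
    fitted_values: np.ndarray | None = None  # filled by string_shape_descriptor


@dataclass
class FeatureVector:
    """All quantified descriptors for one cell."""

    pair_id: int
    A: float  # nucleus area, px
    grad_A: float  # A / A_normal
    P: float  # N/C ratio
    grad_P: float  # P / P_normal
    C: float  # circularity
    E: float  # compactness
    N: int  # radial-signature extrema count
    nucleus_rgb: tuple[float, float, float]
    cytoplasm_rgb: tuple[float, float, float]
    flags: tuple[str, ...] = ()


def area_ratio(A: float, A_normal: float) -> float:
    """Nucleus size relative to the normal reference size."""
    if A_normal <= 0:
        raise ConfigError(f"A_normal must be positive, got {A_normal}")
    return A / A_normal


def nc_ratio(nucleus_A: float, cell_A: float, denominator: str = "cytoplasm") -> float:
    """Nucleus-to-cytoplasm area ratio.

    By default the denominator is the cytoplasm-only area (cell minus
    nucleus); ``denominator="cell"`` uses the whole-cell area instead.
    """
    if not 0 < nucleus_A < cell_A:
        raise GeometryError(
            f"need cell_A > nucleus_A > 0, got nucleus={nucleus_A}, cell={cell_A}"
        )
    if denominator == "cell":
        return nucleus_A / cell_A
    return nucleus_A / (cell_A - nucleus_A)


def circularity(region: RegionRecord) -> float:
    """Isoperimetric quotient 4*pi*A / perimeter**2, capped at 1.05.

    Degenerate (<= 2 px) regions return 1.0 by convention.
    """
    if region.area <= 2:
        return 1.0
    if region.perimeter <= 0:
        raise GeometryError(f"region {region.label}: non-positive perimeter")
    return min(4.0 * np.pi * region.area / region.perimeter**2, 1.05)


def _pixel_corner_hull_area(coords: np.ndarray) -> float:
    # Pixels are unit squares; the hull is taken over all 4 corners of each
    # pixel so that e.g. a plus-pentomino gets hull area 7, not the area of
    # the polygon through pixel centres.
    shifts = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
    pts = (coords[:, None, :] + shifts[None, :, :]).reshape(-1, 2).astype(float)
    try:
        return float(ConvexHull(pts).volume)
    except QhullError as exc:  # pragma: no cover - corners are never collinear
        raise GeometryError("degenerate convex hull") from exc


def compactness(region: RegionRecord, variant: str = "solidity") -> float:
    """Shape fullness in (0, 1].

    ``solidity`` (default): pixel area over the area of the convex hull of
    the region's pixels (as unit squares).  ``extent``: pixel area over the
    bounding-box area.
    """
    if variant == "extent":
        span = region.coords.max(axis=0) - region.coords.min(axis=0) + 1
        return region.area / float(span[0] * span[1])
    hull = _pixel_corner_hull_area(region.coords)
    return min(region.area / hull, 1.0)


def radial_signature(region: RegionRecord) -> RadialSignature:
    """Distance from centroid to each boundary point, ordered by polar angle.

    Duplicate angles are averaged.  If the centroid pixel falls outside the
    region (highly non-star-shaped outline) the signature is still computed
    and flagged.
    """
    if len(region.boundary) < 8:
        raise DegenerateInputError(
            f"region {region.label}: boundary has {len(region.boundary)} points, need >= 8"
        )
    r0, c0 = region.centroid
    dy = region.boundary[:, 0] - r0
    dx = region.boundary[:, 1] - c0
    d = np.hypot(dy, dx)
    theta = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
    order = np.argsort(theta, kind="stable")
    theta, d = theta[order], d[order]
    uniq, inv = np.unique(theta, return_inverse=True)
    if uniq.size < theta.size:
        d = np.bincount(inv, weights=d) / np.bincount(inv)
        theta = uniq
    px = (int(round(r0)), int(round(c0)))
    inside = bool(
        ((region.coords[:, 0] == px[0]) & (region.coords[:, 1] == px[1])).any()
    )
    return RadialSignature(angles=theta, distances=d, non_star_shaped=not inside)


def _count_significant_extrema(values: np.ndarray, threshold: float, circular: bool) -> int:
    """Count alternating extrema with peak-to-valley amplitude > threshold.

    Extrema pairs are annihilated smallest-amplitude-first, so ripple riding
    on a large lobe does not inflate the count.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if circular:
        left, right = np.roll(v, 1), np.roll(v, -1)
        idx = np.nonzero(((v > left) & (v >= right)) | ((v < left) & (v <= right)))[0]
    else:
        interior = slice(1, -1)
        left, right = v[:-2], v[2:]
        mid = v[interior]
        idx = 1 + np.nonzero(((mid > left) & (mid >= right)) | ((mid < left) & (mid <= right)))[0]
    ext = list(v[idx])
    while len(ext) >= 2:
        m = len(ext)
        pairs = range(m) if circular else range(m - 1)
        amps = [abs(ext[i] - ext[(i + 1) % m]) for i in pairs]
        i = int(np.argmin(amps))
        if amps[i] > threshold:
            break
        j = (i + 1) % len(ext)
        for k in sorted((i, j), reverse=True):
            del ext[k]
    if len(ext) < 2:
        return 0
    return len(ext)


def string_shape_descriptor(
    sig: RadialSignature,
    fit_order: int = 8,
    amp_tol: float = 0.03,
    method: str = "fourier",
    n_eval: int = 1024,
    min_amplitude_px: float = 0.8,
) -> int:
    """Count significant peaks + valleys of the fitted distance curve.

    The signature is smoothed by a truncated Fourier series of order
    ``fit_order`` (default; periodic, so the count cannot depend on the
    arbitrary traversal starting point) or by a polynomial over the angle
    (``method="poly"``).  Extrema whose amplitude relative to the adjacent
    opposite extremum is below ``amp_tol * mean(distance)`` are discarded.
    """
    if fit_order < 4:
        raise ConfigError("fit_order must be >= 4")
    if not 0 <= amp_tol < 1:
        raise ConfigError("amp_tol must be in [0, 1)")
    theta, d = sig.angles, sig.distances
    threshold = max(amp_tol * float(np.mean(d)), min_amplitude_px)
    if method == "fourier":
        n_coef = 2 * fit_order + 1
        if theta.size < n_coef:
            raise DegenerateInputError(
                f"{theta.size} signature points cannot support Fourier order {fit_order}"
            )
        k = np.arange(1, fit_order + 1)
        design = np.hstack(
            [
                np.ones((theta.size, 1)),
                np.cos(theta[:, None] * k[None, :]),
                np.sin(theta[:, None] * k[None, :]),
            ]
        )
        coef, *_ = np.linalg.lstsq(design, d, rcond=None)
        grid = np.linspace(0.0, 2.0 * np.pi, n_eval, endpoint=False)
        basis = np.hstack(
            [
                np.ones((n_eval, 1)),
                np.cos(grid[:, None] * k[None, :]),
                np.sin(grid[:, None] * k[None, :]),
            ]
        )
        fitted = basis @ coef
        sig.fitted_values = fitted
        return _count_significant_extrema(fitted, threshold, circular=True)
    if method == "poly":
        if theta.size < fit_order + 1:
            raise DegenerateInputError(
                f"{theta.size} signature points cannot support polynomial order {fit_order}"
            )
        coef = np.polynomial.polynomial.polyfit(theta, d, fit_order)
        grid = np.linspace(theta.min(), theta.max(), n_eval)
        fitted = np.polynomial.polynomial.polyval(grid, coef)
        sig.fitted_values = fitted
        return _count_significant_extrema(fitted, threshold, circular=False)
    raise ConfigError(f"unknown signature fit method {method!r}")


def color_strength(
    image: np.ndarray, region_or_coords: RegionRecord | np.ndarray
) -> tuple[float, float, float]:
    """Per-channel mean RGB over the region's pixels."""
    coords = (
        region_or_coords.coords
        if isinstance(region_or_coords, RegionRecord)
        else np.asarray(region_or_coords)
    )
    if image.ndim != 3 or image.shape[2] < 3:
        raise GeometryError(f"expected RGB image, got shape {image.shape}")
    if coords.size == 0:
        raise GeometryError("empty pixel set for color strength")
    if (
        coords.min() < 0
        or coords[:, 0].max() >= image.shape[0]
        or coords[:, 1].max() >= image.shape[1]
    ):
        raise GeometryError("region pixels fall outside the image bounds")
    vals = image[coords[:, 0], coords[:, 1], :3].astype(float)
    means = vals.mean(axis=0)
    return (float(means[0]), float(means[1]), float(means[2]))


def _cytoplasm_coords(pair: CellNucleusPair, width: int) -> np.ndarray:
    cell_idx = pair.cell.coords[:, 0] * width + pair.cell.coords[:, 1]
    nuc_idx = pair.nucleus.coords[:, 0] * width + pair.nucleus.coords[:, 1]
    keep = np.setdiff1d(cell_idx, nuc_idx, assume_unique=True)
    return np.column_stack([keep // width, keep % width])


def extract_features(
    pair: CellNucleusPair,
    image: np.ndarray,
    ref: NormalReference,
    cfg: FeatureConfig | None = None,
    pair_id: int = 0,
) -> FeatureVector:
    """Compute the full descriptor set for one cell/nucleus pair."""
    cfg = cfg or FeatureConfig()
    nucleus, cell = pair.nucleus, pair.cell
    if nucleus.area >= cell.area:
        raise GeometryError(
            f"nucleus area {nucleus.area} must be smaller than cell area {cell.area}"
        )
    flags: list[str] = []
    if pair.nucleus_outside_cell:
        flags.append("nucleus_outside_cell")
    A = float(nucleus.area)
    grad_A = area_ratio(A, ref.area)
    P = nc_ratio(A, float(cell.area), denominator=cfg.nc_denominator)
    grad_P = P / ref.nc
    degenerate = nucleus.area <= 2
    if degenerate:
        flags.append("degenerate_nucleus")
        C, E, N = 1.0, 1.0, 0
    else:
        C = circularity(nucleus)
        E = compactness(nucleus, variant=cfg.compactness_variant)
        sig = radial_signature(nucleus)
        if sig.non_star_shaped:
            flags.append("non_star_shaped")
        N = string_shape_descriptor(
            sig,
            fit_order=cfg.fit_order,
            amp_tol=cfg.amp_tol,
            method=cfg.signature_fit,
            min_amplitude_px=cfg.min_amplitude_px,
        )
    nuc_rgb = color_strength(image, nucleus)
    cyt_coords = _cytoplasm_coords(pair, image.shape[1])
    cyt_rgb = color_strength(image, cyt_coords)
    return FeatureVector(
        pair_id=pair_id,
        A=A,
        grad_A=grad_A,
        P=P,
        grad_P=grad_P,
        C=C,
        E=E,
        N=int(N),
        nucleus_rgb=nuc_rgb,
        cytoplasm_rgb=cyt_rgb,
        flags=tuple(flags),
    )


def features_to_frame(fvs: Iterable[FeatureVector]) -> pd.DataFrame:
    """Tabulate feature vectors with the canonical CSV column set."""
    rows = []
    for fv in fvs:
        rows.append(
            {
                "pair_id": fv.pair_id,
                "A": fv.A,
                "grad_A": fv.grad_A,
                "P": fv.P,
                "grad_P": fv.grad_P,
                "C": fv.C,
                "E": fv.E,
                "N": fv.N,
                "nuc_R": fv.nucleus_rgb[0],
                "nuc_G": fv.nucleus_rgb[1],
                "nuc_B": fv.nucleus_rgb[2],
                "cyt_R": fv.cytoplasm_rgb[0],
                "cyt_G": fv.cytoplasm_rgb[1],
                "cyt_B": fv.cytoplasm_rgb[2],
                "flags": ";".join(fv.flags),
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def frame_to_features(frame: pd.DataFrame) -> list[FeatureVector]:
    """Inverse of :func:`features_to_frame`; validates required columns."""
    required = [c for c in FEATURE_COLUMNS if c != "flags"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"feature table is missing columns: {missing}")
    out = []
    for _, row in frame.iterrows():
        raw_flags = row.get("flags", "")
        flags = tuple(f for f in str(raw_flags).split(";") if f) if pd.notna(raw_flags) else ()
        out.append(
            FeatureVector(
                pair_id=int(row["pair_id"]),
                A=float(row["A"]),
                grad_A=float(row["grad_A"]),
                P=float(row["P"]),
                grad_P=float(row["grad_P"]),
                C=float(row["C"]),
                E=float(row["E"]),
                N=int(row["N"]),
                nucleus_rgb=(float(row["nuc_R"]), float(row["nuc_G"]), float(row["nuc_B"])),
                cytoplasm_rgb=(float(row["cyt_R"]), float(row["cyt_G"]), float(row["cyt_B"])),
                flags=flags,
            )
        )
    return out
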