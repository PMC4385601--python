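import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cervicell.exceptions import ConfigError, DegenerateInputError, GeometryError
from cervicell.features import (
    FeatureConfig,
    NormalReference,
    area_ratio,
    circularity,
    color_strength,
    compactness,
    extract_features,
    features_to_frame,
    frame_to_features,
    nc_ratio,
    radial_signature,
    string_shape_descriptor,
)
from cervicell.regions import (
    LabeledMask,
    RegionRecord,
    extract_regions,
    pair_nucleus_to_cell,
)

from conftest import disk_mask, ellipse_mask, region_of, star_mask


# ------------------------------------------------------------------ area_ratio


def test_area_ratio_identity():
    assert area_ratio(600.0, 600.0) == 1.0


def test_area_ratio_criterion_boundary():
    assert area_ratio(250.0, 100.0) == 2.5


def test_area_ratio_invalid_reference():
    with pytest.raises(ConfigError):
        area_ratio(10.0, 0.0)


@given(
    A=st.floats(1, 1e6),
    A_normal=st.floats(1, 1e6),
    scale=st.floats(0.01, 100),
)
def test_area_ratio_scale_invariance(A, A_normal, scale):
    assert area_ratio(A * scale, A_normal * scale) == pytest.approx(
        area_ratio(A, A_normal), rel=1e-9
    )


@given(A=st.floats(1, 1e6), k=st.floats(0.1, 10))
def test_area_ratio_linear_in_area(A, k):
    assert area_ratio(k * A, 100.0) == pytest.approx(k * area_ratio(A, 100.0), rel=1e-9)


# -------------------------------------------------------------------- nc_ratio


def test_nc_ratio_cytoplasm_denominator():
    assert nc_ratio(100.0, 200.0) == 1.0
    assert nc_ratio(50.0, 550.0) == pytest.approx(0.1)


def test_nc_ratio_whole_cell_denominator():
    assert nc_ratio(100.0, 200.0, denominator="cell") == 0.5


def test_nc_ratio_identity_against_reference():
    P_normal = 0.1
    assert nc_ratio(50.0, 550.0) / P_normal == pytest.approx(1.0)


def test_nc_ratio_rejects_nucleus_not_smaller():
    with pytest.raises(GeometryError):
        nc_ratio(200.0, 200.0)
    with pytest.raises(GeometryError):
        nc_ratio(0.0, 200.0)


# ----------------------------------------------------------------- circularity


def _analytic_record(area, perimeter):
    return RegionRecord(
        label=1,
        area=area,
        perimeter=perimeter,
        centroid=(0.0, 0.0),
        coords=np.zeros((area if isinstance(area, int) else 4, 2), int),
        boundary=np.zeros((4, 2), int),
    )


def test_circularity_ideal_circle_is_one():
    r = 10.0
    rec = _analytic_record(int(np.pi * r * r), 2 * np.pi * r)
    # use exact continuous values
    rec.area = np.pi * r * r
    assert circularity(rec) == pytest.approx(1.0)


def test_circularity_ideal_square_closed_form():
    s = 12.0
    rec = _analytic_record(4, 4 * s)
    rec.area = s * s
    assert circularity(rec) == pytest.approx(np.pi / 4, rel=1e-12)


def test_circularity_digitized_disk_near_one():
    assert circularity(region_of(disk_mask(25))) == pytest.approx(1.0, abs=0.05)


def test_circularity_digitized_ellipse_vs_ramanujan():
    a, b = 40, 20
    rec = region_of(ellipse_mask(a, b))
    h = ((a - b) / (a + b)) ** 2
    per = np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
    analytic = 4 * np.pi * (np.pi * a * b) / per**2
    assert circularity(rec) == pytest.approx(analytic, abs=0.05)


def test_circularity_degenerate_pixel_is_one():
    lab = np.zeros((5, 5), int)
    lab[2, 2] = 1
    (rec,) = extract_regions(LabeledMask(lab))
    assert circularity(rec) == 1.0


def test_circularity_ordering_disk_ellipse_star():
    # equal-area family: C strictly decreasing with irregularity
    area = np.pi * 30 * 30
    disk = region_of(disk_mask(30))
    ell = region_of(ellipse_mask(30 * np.sqrt(2), 30 / np.sqrt(2)))
    star = region_of(star_mask(np.sqrt(area / (np.pi * (1 + 0.5**2 / 2))), 4, 0.5))
    assert circularity(disk) > circularity(ell) > circularity(star)


# ----------------------------------------------------------------- compactness


def test_compactness_plus_pentomino():
    lab = np.zeros((3, 3), int)
    lab[1, :] = 1
    lab[:, 1] = 1
    (rec,) = extract_regions(LabeledMask(lab))
    # brute-force hull of the 5 unit squares: 3x3 square minus 4 corner
    # triangles of area 1/2 each -> hull area 7
    assert compactness(rec) == pytest.approx(5 / 7, rel=1e-9)


@pytest.mark.parametrize(
    "mask",
    [disk_mask(80), ellipse_mask(100, 50)],
    ids=["disk80", "ellipse100x50"],
)
def test_compactness_convex_near_one(mask):
    assert compactness(region_of(mask)) == pytest.approx(1.0, abs=0.02)


def test_compactness_square_exactly_one():
    lab = np.zeros((30, 30), int)
    lab[2:27, 2:27] = 1
    (rec,) = extract_regions(LabeledMask(lab))
    assert compactness(rec) == pytest.approx(1.0, rel=1e-12)


def test_compactness_four_lobed_star_below_threshold():
    rec = region_of(star_mask(30, 4, 0.5))
    assert compactness(rec) < 0.7


def test_compactness_extent_variant():
    lab = np.zeros((10, 10), int)
    lab[2:6, 2:8] = 1
    (rec,) = extract_regions(LabeledMask(lab))
    assert compactness(rec, variant="extent") == 1.0


# ------------------------------------------------------------- radial_signature


def test_radial_signature_circle_constant():
    r = 20
    sig = radial_signature(region_of(disk_mask(r)))
    assert np.all(sig.distances >= r - 1)
    assert np.all(sig.distances <= r + 1)
    assert np.all(np.diff(sig.angles) > 0)
    assert not sig.non_star_shaped


def test_radial_signature_ellipse_extremes():
    a, b = 40, 20
    sig = radial_signature(region_of(ellipse_mask(a, b)))
    # max distance near the semi-major axis (angles 0, pi), min near b
    assert sig.distances.max() == pytest.approx(a, abs=1.5)
    assert sig.distances.min() == pytest.approx(b, abs=1.5)
    ang_at_max = sig.angles[np.argmax(sig.distances)]
    assert min(ang_at_max, abs(ang_at_max - np.pi), 2 * np.pi - ang_at_max) < 0.2


def test_radial_signature_square_corner_maxima():
    s = 21
    lab = np.zeros((s + 4, s + 4), int)
    lab[2 : 2 + s, 2 : 2 + s] = 1
    (rec,) = extract_regions(LabeledMask(lab))
    sig = radial_signature(rec)
    corner = (s - 1) * np.sqrt(2) / 2  # pixel-centre corner distance
    top = np.sort(sig.distances)[-4:]
    assert np.allclose(top, corner, atol=1e-9)


def test_radial_signature_needs_enough_points():
    lab = np.zeros((4, 4), int)
    lab[1:3, 1:3] = 1
    (rec,) = extract_regions(LabeledMask(lab))
    with pytest.raises(DegenerateInputError):
        radial_signature(rec)


# ------------------------------------------------------- string_shape_descriptor


def test_descriptor_circle_zero():
    assert string_shape_descriptor(radial_signature(region_of(disk_mask(20)))) == 0


def test_descriptor_two_to_one_ellipse_four():
    # analytic oracle: radial function of an ellipse has 2 maxima + 2 minima
    sig = radial_signature(region_of(ellipse_mask(40, 20)))
    assert string_shape_descriptor(sig) == 4


def test_descriptor_three_lobed_star_six():
    # r(theta) = R(1 + 0.3 cos 3theta) has 3 peaks + 3 valleys
    sig = radial_signature(region_of(star_mask(20, 3, 0.3)))
    assert string_shape_descriptor(sig) == 6


@pytest.mark.parametrize("deg", list(range(0, 360, 15)))
def test_descriptor_rotation_invariant(deg):
    mask = star_mask(30, 3, 0.3, rot=np.deg2rad(deg))
    assert string_shape_descriptor(radial_signature(region_of(mask))) == 6


def test_descriptor_start_point_invariant():
    rec = region_of(star_mask(30, 3, 0.3))
    base = string_shape_descriptor(radial_signature(rec))
    for shift in (1, 7, len(rec.boundary) // 2):
        rolled = RegionRecord(
            label=rec.label,
            area=rec.area,
            perimeter=rec.perimeter,
            centroid=rec.centroid,
            coords=rec.coords,
            boundary=np.roll(rec.boundary, shift, axis=0),
        )
        assert string_shape_descriptor(radial_signature(rolled)) == base


def test_descriptor_polynomial_variant():
    sig = radial_signature(region_of(ellipse_mask(40, 20)))
    n = string_shape_descriptor(sig, fit_order=10, method="poly")
    # a non-periodic polynomial fit can gain or lose one extremum at the
    # open ends of the angle interval (why "fourier" is the default)
    assert n in (3, 4, 5)


def test_descriptor_rejects_low_order_and_bad_tol():
    sig = radial_signature(region_of(disk_mask(10)))
    with pytest.raises(ConfigError):
        string_shape_descriptor(sig, fit_order=2)
    with pytest.raises(ConfigError):
        string_shape_descriptor(sig, amp_tol=1.5)


def test_descriptor_too_few_points():
    sig = radial_signature(region_of(disk_mask(4)))
    with pytest.raises(DegenerateInputError):
        string_shape_descriptor(sig, fit_order=30)


# -------------------------------------------------------------- color_strength


def test_color_strength_uniform():
    img = np.zeros((10, 10, 3), np.uint8)
    img[:, :] = (100, 50, 200)
    rec = region_of(disk_mask(3, size=10))
    assert color_strength(img, rec) == (100.0, 50.0, 200.0)


def test_color_strength_half_half_mean():
    img = np.zeros((2, 2, 3), np.uint8)
    img[0, :] = (0, 0, 0)
    img[1, :] = (200, 100, 50)
    coords = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
    assert color_strength(img, coords) == (100.0, 50.0, 25.0)


def test_color_strength_equals_brute_force_mean():
    rng = np.random.default_rng(1)
    img = rng.integers(0, 256, size=(20, 20, 3)).astype(np.uint8)
    rec = region_of(disk_mask(7, size=20))
    got = color_strength(img, rec)
    brute = img[rec.coords[:, 0], rec.coords[:, 1]].mean(axis=0)
    assert got == tuple(brute)


def test_color_strength_noisy_mean_within_clt_bound():
    from cervicell.decision import Grade
    from cervicell.synthetic import CellSpec, ShapeSpec, make_cell

    spec = CellSpec(
        stage=Grade.LSIL,
        nucleus_area=700,
        cell_area=4000,
        cytoplasm_rgb=(145.0, 100.0, 150.0),
        noise_sd=5.0,
    )
    scene = make_cell(spec, seed=2)
    cyt = scene.cell_mask.labels.astype(bool) & ~scene.nucleus_mask.labels.astype(bool)
    coords = np.argwhere(cyt)
    assert coords.shape[0] >= 500
    got = color_strength(scene.image, coords)
    assert got == pytest.approx((145.0, 100.0, 150.0), abs=2.0)


def test_color_strength_out_of_bounds():
    img = np.zeros((5, 5, 3), np.uint8)
    with pytest.raises(GeometryError):
        color_strength(img, np.array([[4, 6]]))


# ------------------------------------------------------------- extract_features


def _scene_pair(scene):
    cells = extract_regions(scene.cell_mask)
    nuclei = extract_regions(scene.nucleus_mask)
    (pair,) = pair_nucleus_to_cell(cells, nuclei)
    return pair


def test_extract_features_normal_cell(ref):
    from cervicell.synthetic import STAGE_PROFILES
    from cervicell.decision import Grade
    from cervicell.synthetic import make_cell

    rng = np.random.default_rng(0)
    spec = STAGE_PROFILES[Grade.NORMAL](ref, rng)
    scene = make_cell(spec, seed=1)
    fv = extract_features(_scene_pair(scene), scene.image, ref)
    assert fv.grad_A == pytest.approx(1.0, abs=0.15)
    assert fv.grad_P == pytest.approx(1.0, abs=0.25)
    assert fv.C > 0.9
    # unit-square-hull solidity carries an O(1/r) digitization bias, so a
    # reference-size convex nucleus sits a little below 1
    assert fv.E > 0.9
    assert fv.N == 0


def test_extract_features_scc_cell(ref):
    from cervicell.decision import Grade
    from cervicell.synthetic import STAGE_PROFILES, make_cell

    rng = np.random.default_rng(0)
    spec = STAGE_PROFILES[Grade.SCC](ref, rng)
    scene = make_cell(spec, seed=1)
    fv = extract_features(_scene_pair(scene), scene.image, ref)
    assert fv.grad_A > 2
    assert fv.nucleus_rgb[0] < 90
    assert fv.nucleus_rgb[1] < 90
    assert fv.nucleus_rgb[2] < 190


def test_extract_features_rejects_nucleus_not_smaller(ref):
    from cervicell.regions import CellNucleusPair

    rec = region_of(disk_mask(5, size=16))
    pair = CellNucleusPair(cell=rec, nucleus=rec, centroid_distance=0.0)
    img = np.zeros((16, 16, 3), np.uint8)
    with pytest.raises(GeometryError):
        extract_features(pair, img, ref)


def test_feature_frame_roundtrip(ref):
    from cervicell.decision import Grade
    from cervicell.synthetic import STAGE_PROFILES, make_cell

    rng = np.random.default_rng(4)
    fvs = []
    for stage in (Grade.NORMAL, Grade.LSIL):
        scene = make_cell(STAGE_PROFILES[stage](ref, rng), seed=3)
        fvs.append(extract_features(_scene_pair(scene), scene.image, ref, pair_id=len(fvs)))
    frame = features_to_frame(fvs)
    back = frame_to_features(frame)
    for a, b in zip(fvs, back):
        assert a.pair_id == b.pair_id
        assert a.N == b.N
        assert a.grad_A == pytest.approx(b.grad_A)
        assert a.nucleus_rgb == pytest.approx(b.nucleus_rgb)
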