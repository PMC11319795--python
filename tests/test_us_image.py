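"""Echo-intensity, thickness and GLCM texture measurements."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from echosway.us_image import (
    FEATURE_COLUMNS,
    GLCMConfig,
    GLCMFeatures,
    GrayImage,
    LandmarkSet,
    MuscleMeasures,
    PolygonROI,
    RectROI,
    average_replicates,
    compute_ei,
    compute_glcm,
    glcm_features,
    haralick_features,
    measure_thickness,
    read_image,
    read_sidecar,
    write_image,
    write_sidecar,
)

_OFFSETS = {0: (0, 1), 90: (-1, 0), 180: (0, -1), 270: (1, 0)}


def brute_force_glcm(patch: np.ndarray, levels: int, distance: int, angle: int) -> np.ndarray:
    """Naive double-loop pair enumeration; the independent texture oracle."""
    dr, dc = _OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    out = np.zeros((levels, levels))
    h, w = patch.shape
    for r in range(h):
        for c in range(w):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                out[patch[r, c], patch[rr, cc]] += 1
    return out / out.sum()


class TestEchoIntensity:
    def test_constant_region_returns_constant(self):
        img = GrayImage(np.full((10, 10), 128))
        roi = PolygonROI(((1, 1), (1, 8), (8, 8), (8, 1)))
        assert compute_ei(img, roi) == 128.0

    def test_two_by_two_mean_includes_boundary_pixels(self):
        img = GrayImage(np.array([[0, 255], [255, 0]]))
        roi = PolygonROI(((0, 0), (0, 1), (1, 1), (1, 0)))
        assert compute_ei(img, roi) == 127.5

    def test_empty_polygon_raises(self):
        img = GrayImage(np.zeros((20, 20), dtype=int))
        # tiny triangle strictly between pixel centers
        roi = PolygonROI(((5.2, 5.2), (5.3, 5.4), (5.4, 5.2)))
        with pytest.raises(ValueError, match="encloses no pixel"):
            compute_ei(img, roi)

    def test_self_intersecting_polygon_rejected(self):
        with pytest.raises(ValueError, match="self-intersecting|degenerate"):
            PolygonROI(((0, 0), (5, 5), (0, 5), (5, 0)))


class TestThickness:
    def test_published_group_means_reproduced_from_depths(self):
        # depths chosen so that SAT and MT land on the young-group means
        lm = LandmarkSet(skin_depth=50, superficial_apo_depth=148, deep_boundary_depth=369)
        mt, sat = measure_thickness(lm, 0.01)
        assert sat == pytest.approx(0.98)
        assert mt == pytest.approx(2.21)

    def test_coincident_interfaces_give_zero_thickness(self):
        lm = LandmarkSet(skin_depth=10, superficial_apo_depth=40, deep_boundary_depth=40)
        mt, sat = measure_thickness(lm, 0.01)
        assert mt == 0.0 and sat == pytest.approx(0.30)

    def test_depth_ordering_enforced(self):
        with pytest.raises(ValueError, match="skin <= superficial"):
            LandmarkSet(skin_depth=50, superficial_apo_depth=30, deep_boundary_depth=60)


class TestGLCM:
    def test_constant_roi_single_entry(self):
        img = GrayImage(np.full((6, 6), 7))
        per, avg = compute_glcm(img, RectROI(0, 0, 6, 6), GLCMConfig(levels=16))
        for mat in per.values():
            assert mat[7, 7] == 1.0 and mat.sum() == 1.0
        feats = haralick_features(avg, GLCMConfig(levels=16))
        assert feats.ASM == 1.0 and feats.Contrast == 0.0
        assert feats.IDM == 1.0 and feats.Entropy == 0.0
        assert math.isnan(feats.Correlation)  # degenerate marginals -> sentinel

    def test_checkerboard_horizontal_pairs(self):
        img = GrayImage(np.array([[0, 255], [255, 0]]))
        per, avg = compute_glcm(img, RectROI(0, 0, 2, 2), GLCMConfig(directions=(0, 180)))
        # 4 ordered horizontal pairs: (0,255) twice and (255,0) twice
        assert avg[0, 255] == pytest.approx(0.5)
        assert avg[255, 0] == pytest.approx(0.5)
        feats = haralick_features(avg)
        assert feats.ASM == pytest.approx(0.5)
        assert feats.Contrast == pytest.approx(255**2)
        assert feats.IDM == pytest.approx(1.0 / (1 + 255**2))
        assert feats.Entropy == pytest.approx(math.log(2))
        assert feats.Correlation == pytest.approx(-1.0)

    def test_vertical_directions_equal_horizontal_on_transpose(self):
        rng = np.random.default_rng(11)
        arr = rng.integers(0, 4, size=(7, 9))
        cfg_h = GLCMConfig(levels=4, directions=(0, 180))
        cfg_v = GLCMConfig(levels=4, directions=(90, 270))
        _, h_on_t = compute_glcm(GrayImage(arr.T), RectROI(0, 0, 9, 7), cfg_h)
        _, v = compute_glcm(GrayImage(arr), RectROI(0, 0, 7, 9), cfg_v)
        np.testing.assert_allclose(v, h_on_t)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h, w = rng.integers(3, 9, size=2)
        arr = rng.integers(0, 4, size=(h, w))
        img = GrayImage(arr)
        cfg = GLCMConfig(levels=4)
        per, avg = compute_glcm(img, RectROI(0, 0, int(h), int(w)), cfg)
        mats = []
        for ang in cfg.directions:
            expected = brute_force_glcm(arr, 4, 1, ang)
            np.testing.assert_array_equal(per[ang], expected)
            mats.append(expected)
        np.testing.assert_allclose(avg, np.mean(mats, axis=0))

    def test_matches_skimage_average(self):
        # independent library cross-check on the direction-averaged matrix
        skimage = pytest.importorskip("skimage.feature")
        rng = np.random.default_rng(5)
        arr = rng.integers(0, 8, size=(12, 15))
        _, avg = compute_glcm(GrayImage(arr), RectROI(0, 0, 12, 15), GLCMConfig(levels=8))
        ref = skimage.graycomatrix(
            arr.astype(np.uint8), [1], [0, np.pi / 2, np.pi, 3 * np.pi / 2],
            levels=8, symmetric=False, normed=True,
        )
        np.testing.assert_allclose(avg, ref[:, :, 0, :].mean(axis=-1), atol=1e-12)

    def test_roi_thinner_than_distance_rejected(self):
        img = GrayImage(np.zeros((2, 10), dtype=int))
        with pytest.raises(ValueError, match="too thin"):
            compute_glcm(img, RectROI(0, 0, 2, 10), GLCMConfig(distance=3))

    def test_features_from_avg_equal_convenience_path(self):
        rng = np.random.default_rng(3)
        arr = rng.integers(0, 256, size=(20, 24))
        img = GrayImage(arr)
        roi = RectROI(0, 0, 20, 24)
        _, avg = compute_glcm(img, roi)
        a = haralick_features(avg)
        b = glcm_features(img, roi)
        assert a == b

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            haralick_features(np.ones((4, 4)))

    def test_plugin_compatible_correlation_scale(self):
        # dividing by the variance product shrinks the magnitude toward the
        # ~1e-3 values reported by the common plugin
        rng = np.random.default_rng(9)
        arr = rng.integers(20, 90, size=(30, 30))
        img = GrayImage(arr)
        roi = RectROI(0, 0, 30, 30)
        std = glcm_features(img, roi, GLCMConfig(correlation_variant="standard"))
        plug = glcm_features(img, roi, GLCMConfig(correlation_variant="plugin_compatible"))
        assert abs(std.Correlation) <= 1.0
        assert abs(plug.Correlation) < abs(std.Correlation)
        assert abs(plug.Correlation) < 0.01

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_feature_bounds_on_random_images(self, seed):
        rng = np.random.default_rng(seed)
        levels = int(rng.integers(2, 9))
        h, w = rng.integers(3, 12, size=2)
        arr = rng.integers(0, levels, size=(h, w))
        cfg = GLCMConfig(levels=levels)
        per, avg = compute_glcm(GrayImage(arr), RectROI(0, 0, int(h), int(w)), cfg)
        for mat in list(per.values()) + [avg]:
            assert mat.min() >= 0
            assert abs(mat.sum() - 1) < 1e-9
        f = haralick_features(avg, cfg)
        assert 0 < f.ASM <= 1
        assert 0 < f.IDM <= 1
        assert 0 <= f.Entropy <= math.log(levels**2) + 1e-12
        assert 0 <= f.Contrast <= (levels - 1) ** 2


class TestReplicateAveraging:
    def test_three_identical_records_unchanged(self):
        rec = MuscleMeasures(MT_cm=2.2, SAT_cm=0.9, EI=40.0)
        avg, n = average_replicates([rec, rec, rec])
        assert avg == rec and n == 3

    def test_elementwise_mean(self):
        recs = [MuscleMeasures(MT_cm=2.0, SAT_cm=1.0, EI=e) for e in (30, 32, 34)]
        avg, _ = average_replicates(recs)
        assert avg.EI == 32.0

    def test_nan_correlation_does_not_poison_average(self):
        recs = [
            GLCMFeatures(ASM=0.5, Contrast=1, Correlation=float("nan"), IDM=0.5, Entropy=1),
            GLCMFeatures(ASM=0.3, Contrast=3, Correlation=0.8, IDM=0.7, Entropy=2),
        ]
        avg, _ = average_replicates(recs)
        assert avg.Correlation == 0.8 and avg.ASM == 0.4

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            average_replicates([])


class TestIO:
    def test_png_and_sidecar_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        img = GrayImage(rng.integers(0, 256, size=(30, 40)), pixel_spacing=0.02, id="x")
        write_image(img, tmp_path / "x.png")
        back = read_image(tmp_path / "x.png", pixel_spacing=0.02)
        np.testing.assert_array_equal(back.pixels, img.pixels)

        lm = LandmarkSet(2, 10, 25)
        poly = PolygonROI(((12, 2), (12, 35), (22, 35), (22, 2)))
        rect = RectROI(13, 5, 8, 20)
        write_sidecar(tmp_path / "x.json", lm, poly, rect, 0.02)
        lm2, poly2, rect2, spacing = read_sidecar(tmp_path / "x.json")
        assert lm2 == lm and rect2 == rect and spacing == 0.02
        assert poly2.vertices == poly.vertices

    def test_feature_column_contract(self):
        assert FEATURE_COLUMNS == ["MT_cm", "SAT_cm", "EI", "ASM", "Contrast",
                                   "Correlation", "IDM", "Entropy"]
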