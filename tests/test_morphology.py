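import numpy as np
import pytest

from busfusion.errors import DataError, DegenerateShapeError
from busfusion.imaging import TumorMask
from busfusion.morphology import (
    MORPH_FEATURES,
    basic_morph_features,
    best_fit_ellipse,
    ellipse_features,
    morph_vector,
    nrl_features,
    trace_boundary,
)
from busfusion.phantoms import PhantomParams, generate_phantom

SP = (0.1, 0.1)


def _mask(arr, spacing=SP):
    return TumorMask(np.asarray(arr, bool), spacing)


def _disk(radius, pad=5):
    n = 2 * (radius + pad) + 1
    rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return _mask((rr - n // 2) ** 2 + (cc - n // 2) ** 2 <= radius**2)


def _ellipse(a, b, deg, n=201):
    rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    dy = -(rr - n // 2)
    dx = cc - n // 2
    th = np.deg2rad(deg)
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)
    return _mask((u / a) ** 2 + (v / b) ** 2 <= 1)


def _star(k, r0=50, amp=0.35, n=161):
    rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    dy = -(rr - n // 2)
    dx = cc - n // 2
    th = np.arctan2(dy, dx)
    rad = np.hypot(dy, dx)
    return _mask(rad <= r0 * (1 + amp * np.cos(k * th)))


class TestBasicFeatures:
    def test_solid_square_10mm(self):
        m = np.zeros((120, 120), bool)
        m[10:110, 10:110] = True  # 100 px = 10 mm
        f = basic_morph_features(_mask(m))
        assert f["MF1"] == pytest.approx(100.0)   # mm^2
        assert f["MF8"] == pytest.approx(1.0)     # extent
        assert f["MF7"] == pytest.approx(1.0, abs=0.02)  # solidity
        assert f["MF6"] == pytest.approx(1.0, abs=0.01)  # convexity
        assert f["MF9"] == 0.0

    def test_disk_form_factor_near_chain_limit(self):
        # The 8-connected chain perimeter of a digital circle exceeds the true
        # circumference by ~5%, so 4*pi*A/P^2 converges to ~0.91, not 1.
        f = basic_morph_features(_disk(40))
        assert 0.88 < f["MF3"] < 0.95
        assert f["MF4"] == pytest.approx(1.0, abs=0.02)  # roundness is unbiased

    def test_star_undulation_counts_lobes(self):
        for k in (3, 5, 7):
            f = basic_morph_features(_star(k))
            assert f["MF9"] == k
            assert f["MF7"] < 1.0  # solidity drops below the convex hull

    def test_star_solidity_matches_hull_deficiency(self):
        from skimage.morphology import convex_hull_image

        m = _star(5)
        f = basic_morph_features(m)
        brute = m.pixels.sum() / convex_hull_image(m.pixels).sum()
        assert f["MF7"] == pytest.approx(brute, rel=1e-9)

    def test_multicomponent_mask_rejected(self):
        m = np.zeros((30, 30), bool)
        m[2:8, 2:8] = True
        m[20:26, 20:26] = True
        with pytest.raises(DataError):
            basic_morph_features(_mask(m))


class TestBestFitEllipse:
    def test_disk_self_fit(self):
        e = ellipse_features(_disk(40))
        assert e["MF11"] == pytest.approx(8.0, rel=0.02)  # 2r = 80 px = 8 mm
        assert e["MF13"] == pytest.approx(1.0, abs=0.02)
        assert e["MF15"] > 0.95

    def test_axis_aligned_two_to_one_ellipse(self):
        e = ellipse_features(_ellipse(60, 30, 0))
        assert e["MF13"] == pytest.approx(2.0, abs=0.05)
        assert min(e["MF16"], 180 - e["MF16"]) < 2.0

    def test_rotated_ellipse_orientation_recovered(self):
        e = ellipse_features(_ellipse(60, 30, 30))
        assert e["MF16"] == pytest.approx(30.0, abs=3.0)

    def test_collinear_region_rejected(self):
        m = np.zeros((20, 20), bool)
        m[10, 2:18] = True
        with pytest.raises(DegenerateShapeError):
            best_fit_ellipse(_mask(m))


class TestNRL:
    def test_disk_has_constant_nrl(self):
        f = nrl_features(_disk(40))
        assert f["MF18"] == pytest.approx(0.0, abs=1e-3)
        assert f["MF17"] == pytest.approx(0.0, abs=0.05)

    def test_ellipse_variance_matches_boundary_recomputation(self):
        m = _ellipse(60, 30, 20)
        boundary = trace_boundary(m)
        centroid = np.argwhere(m.pixels).mean(axis=0)
        radii = np.sqrt(((boundary - centroid) ** 2).sum(axis=1))
        nrl = radii / radii.max()
        assert nrl_features(m)["MF18"] == pytest.approx(nrl.var(), rel=1e-12)

    def test_spiculated_rougher_than_smooth(self):
        smooth = generate_phantom(PhantomParams(
            label="benign", tumor_diameter_mm=12, seed=5))
        spic = generate_phantom(PhantomParams(
            label="malignant", tumor_diameter_mm=12, seed=5,
            contour_irregularity=0.3))
        assert nrl_features(spic.mask)["MF18"] > nrl_features(smooth.mask)["MF18"]

    def test_single_pixel_rejected(self):
        m = np.zeros((9, 9), bool)
        m[4, 4] = True
        with pytest.raises(DegenerateShapeError):
            nrl_features(_mask(m))


class TestInvariances:
    def test_rotation_by_90_degrees(self, malignant_case):
        m = malignant_case.mask
        rot = _mask(np.rot90(m.pixels))
        v = morph_vector(m)
        vr = morph_vector(rot)
        for name in MORPH_FEATURES:
            if name == "MF16":
                delta = abs((vr[name] - v[name]) % 180.0)
                assert min(delta, 180 - delta) == pytest.approx(90.0, abs=1e-6)
            elif name == "MF5":
                # aspect ratio depends on the max-diameter direction only
                assert vr[name] == pytest.approx(v[name], rel=1e-6)
            else:
                assert vr[name] == pytest.approx(v[name], rel=1e-6), name

    def test_dimensionless_features_scale_invariant(self):
        # Same physical tumor rasterized at 0.1 and 0.05 mm spacing.
        params = dict(label="malignant", tumor_diameter_mm=12, seed=21,
                      contour_irregularity=0.25)
        coarse = generate_phantom(PhantomParams(**params))
        fine = generate_phantom(PhantomParams(**params, spacing_mm=(0.05, 0.05)))
        v1, v2 = morph_vector(coarse.mask), morph_vector(fine.mask)
        for name in ("MF3", "MF4", "MF5", "MF6", "MF7", "MF8",
                     "MF13", "MF14", "MF15", "MF17", "MF18"):
            assert v2[name] == pytest.approx(v1[name], rel=0.05), name
        # dimensioned features agree in physical units too
        assert v2["MF1"] == pytest.approx(v1["MF1"], rel=0.05)
        assert v2["MF2"] == pytest.approx(v1["MF2"], rel=0.05)

    def test_vector_complete_and_finite(self, benign_case):
        v = morph_vector(benign_case.mask)
        assert list(v.index) == list(MORPH_FEATURES)
        assert np.isfinite(v.to_numpy(dtype=float)).all()
        assert 0 < v["MF7"] <= 1 and 0 < v["MF8"] <= 1 and 0 < v["MF15"] <= 1
        assert v["MF13"] >= 1 and v["MF18"] >= 0
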