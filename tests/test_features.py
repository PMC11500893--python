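"""The 46 radiomic indices: closed forms, hand enumerations, and invariants."""

import dataclasses

import numpy as np
import pytest

import petpaint.phantom as ph
from petpaint.features import (
    conventional_features,
    extract_features,
    glcm_features,
    glrlm_features,
    glzlm_features,
    histogram_features,
    ngldm_features,
    shape_features,
    suv_peak,
)
from petpaint.preprocessing import VOIMask, discretize_fbn, discretize_fbs
from petpaint.registry import DISCRETIZATION_INDEPENDENT, FEATURE_NAMES, family
from petpaint.scanner import DEFAULT_SETTINGS, acquire
from .conftest import make_glv, make_image, random_glv


def full_voi(shape, voxel_volume_ml=0.001):
    return VOIMask(mask=np.ones(shape, bool), voxel_volume_ml=voxel_volume_ml)


class TestConventional:
    def test_constant_voi(self):
        img = make_image(np.full((4, 4, 4), 2.5))
        f = conventional_features(img, full_voi((4, 4, 4)))
        assert f["SUVmin"] == f["SUVmean"] == f["SUVmax"] == f["SUVpeak"] == 2.5
        assert f["SUVstd"] == 0.0

    def test_tlg_is_mean_times_volume(self):
        rng = np.random.default_rng(1)
        img = make_image(rng.random((5, 5, 5)) * 10, spacing=(2.0, 2.0, 2.0))
        voi = full_voi((5, 5, 5), voxel_volume_ml=0.008)
        f = conventional_features(img, voi)
        assert f["TLG"] == pytest.approx(f["SUVmean"] * f["MATV"], rel=1e-12)
        assert f["MATV"] == pytest.approx(125 * 0.008)

    def test_moments_on_integer_fixture(self):
        vals = np.arange(27, dtype=float).reshape(3, 3, 3)
        img = make_image(vals)
        f = conventional_features(img, full_voi((3, 3, 3)))
        assert f["SUVmin"] == 0.0
        assert f["SUVmax"] == 26.0
        assert f["SUVmean"] == pytest.approx(13.0)
        assert f["SUVstd"] == pytest.approx(np.std(np.arange(27.0)))

    def test_peak_is_sphere_mean_not_max(self):
        vals = np.zeros((9, 9, 9))
        vals[4, 4, 4] = 100.0
        img = make_image(vals, spacing=(4.0, 4.0, 4.0))
        # voxel centres within the 6.2 mm sphere radius at 4 mm pitch: the hot
        # voxel, 6 face neighbours (4.0 mm) and 12 edge neighbours (5.66 mm)
        peak = suv_peak(img, np.ones((9, 9, 9), bool))
        assert peak == pytest.approx(100.0 / 19.0)

    def test_small_voi_peak_warns(self):
        vals = np.ones((3, 3, 3))
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        img = make_image(vals, spacing=(2.0, 2.0, 2.0))
        with pytest.warns(UserWarning, match="beyond the VOI"):
            assert suv_peak(img, mask) == 1.0


class TestShape:
    def test_digital_ball_sphericity_close_to_one(self):
        # marching cubes on a binary ball carries a staircase area excess of
        # a few percent; sphericity stays in (0.88, 1] at radius 10 voxels
        t = ph.generate_sphere(10.0, grid_spacing=1.0)
        voi = VOIMask(mask=t.support, voxel_volume_ml=0.001)
        f = shape_features(voi, (1.0, 1.0, 1.0))
        assert 0.88 <= f["Sphericity"] <= 1.0

    def test_cube_sphericity_closed_form(self):
        # large cube: faces mesh flat, only the edge chamfer perturbs the
        # analytic pi^(1/3) 6^(2/3) / 6 = 0.8060
        mask = np.zeros((32, 32, 32), bool)
        mask[1:31, 1:31, 1:31] = True
        voi = VOIMask(mask=mask, voxel_volume_ml=0.001)
        f = shape_features(voi, (1.0, 1.0, 1.0))
        assert f["Sphericity"] == pytest.approx(np.pi ** (1 / 3) * 6 ** (2 / 3) / 6,
                                                abs=0.03)

    def test_volume_is_count_times_voxel_volume(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[2:4, 2:4, 2:4] = True
        voi = VOIMask(mask=mask, voxel_volume_ml=0.008)
        f = shape_features(voi, (2.0, 2.0, 2.0))
        assert f["Volume_mL"] == pytest.approx(8 * 0.008)

    def test_single_voxel_degenerate_surface(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        voi = VOIMask(mask=mask, voxel_volume_ml=0.001)
        f = shape_features(voi, (1.0, 1.0, 1.0))
        assert np.isfinite(f["Sphericity"]) and f["Sphericity"] > 0


class TestHistogram:
    def test_single_level(self):
        glv = make_glv(np.ones((3, 3, 3), dtype=int))
        with pytest.warns(UserWarning, match="zero-variance"):
            f = histogram_features(glv)
        assert f["Entropy_log2"] == 0.0
        assert f["Energy"] == 1.0
        assert f["Skewness"] == 0.0

    def test_uniform_over_four_levels(self):
        glv = make_glv(np.repeat([1, 2, 3, 4], 2).reshape(2, 2, 2))
        f = histogram_features(glv)
        assert f["Entropy_log2"] == pytest.approx(2.0)
        assert f["Energy"] == pytest.approx(0.25)

    def test_entropy_base_change(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            glv = random_glv(rng)
            f = histogram_features(glv)
            assert f["Entropy_log2"] == pytest.approx(
                f["Entropy_log10"] / np.log10(2.0), rel=1e-12)

    def test_moments_match_hand_computation(self):
        lev = np.array([1, 1, 2, 4], dtype=float)
        glv = make_glv(lev.astype(int).reshape(1, 1, 4))
        f = histogram_features(glv)
        mu, sd = lev.mean(), lev.std()
        assert f["Skewness"] == pytest.approx(((lev - mu) ** 3).mean() / sd**3)
        assert f["Kurtosis"] == pytest.approx(((lev - mu) ** 4).mean() / sd**4)


class TestGLCMFeatures:
    def test_constant_volume_conventions(self):
        glv = make_glv(np.ones((3, 3, 3), dtype=int))
        with pytest.warns(UserWarning, match="correlation"):
            f = glcm_features(glv)
        assert f["Energy"] == 1.0
        assert f["Entropy_log2"] == 0.0
        assert f["Contrast"] == 0.0
        assert f["Homogeneity"] == 1.0
        assert f["Correlation"] == 0.0

    def test_alternating_line_contrast_and_homogeneity(self):
        glv = make_glv(np.array([1, 2, 1, 2]).reshape(1, 1, 4))
        f = glcm_features(glv, directions=[(0, 0, 1)])
        assert f["Contrast"] == pytest.approx(1.0)
        assert f["Homogeneity"] == pytest.approx(0.5)
        assert f["Dissimilarity"] == pytest.approx(1.0)

    def test_indices_match_matrix_algebra_on_random_volumes(self):
        # recompute each index from the probability matrix with explicit loops
        from petpaint.texture import glcm_matrix

        rng = np.random.default_rng(3)
        for _ in range(15):
            glv = random_glv(rng)
            p = glcm_matrix(glv.levels, glv.mask, glv.n_levels)
            f = glcm_features(glv)
            hom = con = dis = ene = ent = 0.0
            for i in range(p.shape[0]):
                for j in range(p.shape[1]):
                    hom += p[i, j] / (1 + abs(i - j))
                    con += p[i, j] * (i - j) ** 2
                    dis += p[i, j] * abs(i - j)
                    ene += p[i, j] ** 2
                    if p[i, j] > 0:
                        ent -= p[i, j] * np.log2(p[i, j])
            assert f["Homogeneity"] == pytest.approx(hom, abs=1e-12)
            assert f["Contrast"] == pytest.approx(con, abs=1e-12)
            assert f["Dissimilarity"] == pytest.approx(dis, abs=1e-12)
            assert f["Energy"] == pytest.approx(ene, abs=1e-12)
            assert f["Entropy_log2"] == pytest.approx(ent, abs=1e-12)


class TestRunAndZoneFeatures:
    def test_single_run_closed_form(self):
        n = 5
        glv = make_glv(np.ones((1, 1, n), dtype=int))
        f = glrlm_features(glv, directions=[(0, 0, 1)])
        assert f["SRE"] == pytest.approx(1 / n**2)
        assert f["LRE"] == pytest.approx(n**2)
        assert f["RP"] == pytest.approx(1 / n)

    def test_fully_alternating_line(self):
        glv = make_glv(np.array([1, 2] * 4).reshape(1, 1, 8))
        f = glrlm_features(glv, directions=[(0, 0, 1)])
        assert f["SRE"] == pytest.approx(1.0)
        assert f["RP"] == pytest.approx(1.0)

    def test_single_zone_closed_form(self):
        glv = make_glv(np.ones((2, 3, 4), dtype=int))
        n = 24
        f = glzlm_features(glv)
        assert f["ZP"] == pytest.approx(1 / n)
        assert f["LZE"] == pytest.approx(n**2)
        assert f["SZE"] == pytest.approx(1 / n**2)

    def test_all_distinct_levels_all_singleton_zones(self):
        glv = make_glv(np.arange(1, 9).reshape(2, 2, 2))
        f = glzlm_features(glv)
        assert f["SZE"] == pytest.approx(1.0)
        assert f["ZP"] == pytest.approx(1.0)


class TestNGLDM:
    def test_constant_volume(self):
        glv = make_glv(np.ones((3, 3, 3), dtype=int))
        f = ngldm_features(glv)
        assert f["Contrast"] == 0.0
        assert f["Coarseness"] == 1e6  # capped inverse of zero difference

    def test_checkerboard_matches_hand_enumeration(self):
        zz, yy, xx = np.indices((3, 3, 3))
        glv = make_glv(((zz + yy + xx) % 2 + 1).astype(int))
        from .test_texture_oracles import oracle_ngldm

        p, s, n = oracle_ngldm(glv.levels, glv.mask, glv.n_levels)
        f = ngldm_features(glv)
        ps = (p * s).sum()
        assert f["Coarseness"] == pytest.approx(1 / ps)
        iv = np.array([1.0, 2.0])
        contrast = ((p[:, None] * p[None, :] * (iv[:, None] - iv[None, :]) ** 2).sum()
                    / (2 * 1)) * s.sum() / n
        assert f["Contrast"] == pytest.approx(contrast)
        busy = ps / np.abs(iv[:, None] * p[:, None] - iv[None, :] * p[None, :]).sum()
        assert f["Busyness"] == pytest.approx(busy)


@pytest.fixture(scope="module")
def rendered():
    t = ph.generate_lesion("L2", seed=0)
    plan = ph.plan_trajectory(t)
    session = ph.build_sessions("GE Discovery IQ")["L2"]
    amap = ph.paint_ground_truth(t, plan, session)
    img = acquire(amap, DEFAULT_SETTINGS["D"], seed=5)
    from petpaint.preprocessing import make_voi

    return img, make_voi(t, img)


class TestExtractAll:

    def test_exactly_46_named_features(self, rendered):
        img, voi = rendered
        f = extract_features(img, voi, "FBS")
        assert tuple(f) == FEATURE_NAMES
        assert len(f) == 46
        assert all(np.isfinite(v) for v in f.values())

    def test_conv_and_shape_identical_across_discretizations(self, rendered):
        img, voi = rendered
        fbs = extract_features(img, voi, "FBS")
        fbn = extract_features(img, voi, "FBN")
        for name in DISCRETIZATION_INDEPENDENT:
            assert fbs[name] == fbn[name]
        assert any(fbs[n] != fbn[n] for n in FEATURE_NAMES if n.startswith("GLCM"))

    def test_deterministic(self, rendered):
        img, voi = rendered
        a = extract_features(img, voi, "FBN")
        b = extract_features(img, voi, "FBN")
        assert a == b

    def test_blur_increases_homogeneity_decreases_contrast(self):
        # stronger smoothing makes neighbouring voxels more alike
        t = ph.generate_lesion("L3", seed=0)
        plan = ph.plan_trajectory(t)
        session = ph.build_sessions("Mediso AnyScan PET/CT")["L3"]
        amap = ph.paint_ground_truth(t, plan, session)
        from petpaint.preprocessing import make_voi

        results = []
        for fwhm in (4.0, 7.0):
            setting = dataclasses.replace(DEFAULT_SETTINGS["C"], psf_fwhm=fwhm,
                                          noise_scale=0.0)
            img = acquire(amap, setting, seed=0)
            f = extract_features(img, make_voi(t, img), "FBS")
            results.append(f)
        assert results[1]["GLCM_Homogeneity"] > results[0]["GLCM_Homogeneity"]
        assert results[1]["GLCM_Contrast"] < results[0]["GLCM_Contrast"]

    def test_family_prefixes(self):
        fams = {family(n) for n in FEATURE_NAMES}
        assert fams == {"CONV", "SHAPE", "HISTO", "GLCM", "GLRLM", "NGLDM", "GLZLM"}
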