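"""Texture features: worked micro-examples, invariants, vector layout."""
import numpy as np
import pytest

from dtiradiomics import (build_glcm, build_gldm, build_glrlm, build_glszm,
                          discretize, extract_feature_vector, extract_map_features,
                          feature_registry, glcm_contrast, glcm_feature_set,
                          glcm_imc1, gldm_feature_set, glrlm_feature_set,
                          glszm_feature_set, histogram_feature_set,
                          roi_from_levels, shape_feature_set)
from dtiradiomics.core import BrainMask
from dtiradiomics.texture import GLCMatrix
from dtiradiomics.transforms import parse_descriptor


class TestDiscretize:
    def test_hand_binning_half_open(self):
        d = discretize(np.array([0.0, 0.5, 1.0]).reshape(3, 1, 1),
                       np.ones((3, 1, 1), bool), Ng=2)
        assert d.levels.ravel().tolist() == [1, 2, 2]

    def test_constant_region_degenerate(self):
        d = discretize(np.full((2, 2, 2), 0.3), np.ones((2, 2, 2), bool), Ng=4)
        assert d.degenerate
        assert set(d.masked_levels()) == {1}

    def test_matches_histogram(self, rng):
        data = rng.random((6, 6, 6))
        mask = rng.random((6, 6, 6)) > 0.3
        Ng = 5
        d = discretize(data, mask, Ng=Ng)
        counts = np.bincount(d.masked_levels(), minlength=Ng + 1)[1:]
        ref, _ = np.histogram(data[mask], bins=Ng,
                              range=(data[mask].min(), data[mask].max()))
        assert counts.tolist() == ref.tolist()

    def test_ng_lower_bound(self):
        with pytest.raises(ValueError):
            discretize(np.ones((2, 2, 2)), np.ones((2, 2, 2), bool), Ng=1)


class TestGLCM:
    def test_row_pair_enumeration(self):
        d = roi_from_levels([1, 1, 2, 2])
        g = build_glcm(d, directions=[(1, 0, 0)])
        # symmetric counts {(1,1):2,(1,2):2,(2,2):2} -> uniform p = 1/3
        expected = np.array([[1 / 3, 1 / 6], [1 / 6, 1 / 3]])
        assert np.allclose(g.p, expected)
        assert glcm_contrast(g) == pytest.approx(1 / 3)

    def test_contrast_off_diagonal(self):
        g = GLCMatrix(np.array([[0.0, 0.5], [0.5, 0.0]]), 2)
        assert glcm_contrast(g) == pytest.approx(1.0)

    def test_contrast_zero_on_diagonal_mass(self):
        g = GLCMatrix(np.array([[0.5, 0.0], [0.0, 0.5]]), 2)
        assert glcm_contrast(g) == 0.0

    def test_single_level_all_mass_at_origin(self):
        d = roi_from_levels(np.ones((3, 3, 3), int))
        g = build_glcm(d)
        assert g.p[0, 0] == 1.0

    def test_imc1_independent_is_zero(self):
        g = GLCMatrix(np.outer([0.3, 0.7], [0.3, 0.7]), 2)
        assert glcm_imc1(g) == pytest.approx(0.0, abs=1e-12)

    def test_imc1_perfectly_dependent(self):
        # term-by-term: HXY = ln2, HXY1 = 2 ln2, max(HX,HY) = ln2 -> -1
        g = GLCMatrix(np.array([[0.5, 0.0], [0.0, 0.5]]), 2)
        assert glcm_imc1(g) == pytest.approx(-1.0, abs=1e-12)

    def test_imc1_single_cell_defined_zero(self):
        g = GLCMatrix(np.array([[1.0]]), 1)
        assert glcm_imc1(g) == 0.0

    def test_symmetry(self, rng):
        d = roi_from_levels(rng.integers(0, 4, size=(5, 5, 5)))
        g = build_glcm(d)
        assert np.allclose(g.p, g.p.T)
        assert g.p.sum() == pytest.approx(1.0)


class TestGLRLM:
    def test_run_enumeration_row(self):
        d = roi_from_levels([1, 1, 2, 2, 2])
        m = build_glrlm(d, directions=[(1, 0, 0)])
        f = glrlm_feature_set(m)
        assert f["LongRunLowGrayLevelEmphasis"] == pytest.approx(3.125)

    def test_constant_single_run(self):
        n = 6
        d = roi_from_levels(np.ones(n, int))
        m = build_glrlm(d, directions=[(1, 0, 0)])
        assert glrlm_feature_set(m)["LongRunEmphasis"] == pytest.approx(n ** 2)

    def test_run_length_conservation(self, rng):
        d = roi_from_levels(rng.integers(0, 4, size=(6, 6, 6)))
        m = build_glrlm(d)
        j = np.arange(1, m.per_direction[0].shape[1] + 1)
        for P in m.per_direction:
            assert (P * j[None, :]).sum() == d.Np


class TestGLSZM:
    def test_two_zone_square(self):
        d = roi_from_levels([[1, 1], [2, 2]])
        z = build_glszm(d)
        f = glszm_feature_set(z)
        assert z.Nz == 2
        assert f["ZoneVariance"] == 0.0
        assert f["SmallAreaLowGrayLevelEmphasis"] == pytest.approx(0.15625)

    def test_zone_size_conservation(self, rng):
        d = roi_from_levels(rng.integers(0, 3, size=(6, 6, 6)))
        z = build_glszm(d)
        j = np.arange(1, z.P.shape[1] + 1)
        assert (z.P * j[None, :]).sum() == d.Np
        assert z.P.sum() == z.Nz


class TestGLDM:
    def test_constant_cube_centre_dependence(self):
        d = roi_from_levels(np.ones((3, 3, 3), int))
        m = build_gldm(d, alpha=0)
        # the centre voxel has all 26 neighbours in-mask and within alpha
        assert m.P.shape[1] == 27
        assert m.P[0, 26] == 1.0
        # corner voxels have 7 in-mask neighbours
        assert m.P[0, 7] == 8.0
        assert m.P.sum() == d.Np

    def test_counts_only_in_mask_neighbours(self):
        lv = np.zeros((3, 3, 1), int)
        lv[1, 1, 0] = 1
        m = build_gldm(roi_from_levels(lv), alpha=0)
        assert m.P[0, 0] == 1.0  # isolated voxel: dependence 0


class TestHistogram:
    def test_kurtosis_even_split(self):
        f = histogram_feature_set(np.array([-1.0, -1.0, 1.0, 1.0]).reshape(4, 1, 1),
                                  np.ones((4, 1, 1), bool))
        assert f["Kurtosis"] == pytest.approx(1.0)

    def test_uniformity_single_bin(self):
        f = histogram_feature_set(np.full((3, 1, 1), 2.0), np.ones((3, 1, 1), bool))
        assert f["Uniformity"] == 1.0

    def test_uniformity_uniform_occupancy(self):
        Ng = 8
        vals = (np.arange(Ng) + 0.5) / Ng
        f = histogram_feature_set(vals.reshape(Ng, 1, 1), np.ones((Ng, 1, 1), bool),
                                  Ng=Ng)
        assert f["Uniformity"] == pytest.approx(1.0 / Ng)

    def test_zero_variance_degenerate_moments(self):
        f = histogram_feature_set(np.full((4, 1, 1), 3.0), np.ones((4, 1, 1), bool))
        assert np.isnan(f["Kurtosis"]) and np.isnan(f["Skewness"])


class TestShape:
    def test_cube_volume_and_extents(self):
        m = np.zeros((14, 14, 14), bool)
        m[2:12, 2:12, 2:12] = True
        f = shape_feature_set(BrainMask(m, spacing=(1, 1, 1)))
        assert f["VoxelVolume"] == pytest.approx(1000.0)
        assert (f["BoundingBoxExtentX"], f["BoundingBoxExtentY"],
                f["BoundingBoxExtentZ"]) == (10.0, 10.0, 10.0)

    def test_elongation_ordering(self):
        x, y, z = np.ogrid[:30, :20, :20]
        ball = (x - 15) ** 2 / 144 + (y - 10) ** 2 / 16 + (z - 10) ** 2 / 16 <= 1
        sph = (x - 15) ** 2 + (y - 10) ** 2 + (z - 10) ** 2 <= 36
        f_ell = shape_feature_set(BrainMask(ball))
        f_sph = shape_feature_set(BrainMask(sph))
        assert f_ell["Elongation"] < f_sph["Elongation"]
        assert f_sph["Elongation"] == pytest.approx(1.0, abs=0.05)


class TestInvariants:
    def test_scale_invariance_of_discretized_features(self, rng):
        data = rng.random((7, 7, 7))
        mask = np.ones((7, 7, 7), bool)
        f1 = {}
        f2 = {}
        for c, d in (("a", discretize(data, mask, Ng=6)),
                     ("b", discretize(data * 37.5, mask, Ng=6))):
            out = {}
            out.update(glcm_feature_set(build_glcm(d)))
            out.update(glrlm_feature_set(build_glrlm(d)))
            out.update(glszm_feature_set(build_glszm(d)))
            out.update(gldm_feature_set(build_gldm(d)))
            (f1 if c == "a" else f2).update(out)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-12), k


class TestExtraction:
    def test_default_lengths(self, small_fa, small_md, small_mask):
        v_fa = extract_map_features(small_fa, small_mask)
        assert len(v_fa) == 2300
        both = extract_feature_vector(small_fa, small_md, small_mask)
        assert len(both) == 4600
        assert not both.index.duplicated().any()
        assert np.all(np.isfinite(both.to_numpy()))

    def test_single_map_block_prefixes(self, small_fa, small_mask):
        v = extract_map_features(small_fa, small_mask)
        assert all(fid.startswith("FA|") for fid in v.index)
        assert "FA|wavelet.LHL|GLCM|Imc1" in v.index

    def test_deterministic(self, small_fa, small_mask):
        manifest = [parse_descriptor("original"), parse_descriptor("wavelet.LLL")]
        a = extract_map_features(small_fa, small_mask, manifest=manifest)
        b = extract_map_features(small_fa, small_mask, manifest=manifest)
        assert a.equals(b)

    def test_empty_manifest_rejected(self, small_fa, small_mask):
        with pytest.raises(ValueError):
            extract_map_features(small_fa, small_mask, manifest=[])

    def test_registry_class_sizes(self):
        reg = feature_registry()
        sizes = {k: len(v) for k, v in reg.items()}
        assert sizes == {"Histogram": 23, "GLCM": 24, "GLRLM": 16,
                         "GLSZM": 16, "GLDM": 13}
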