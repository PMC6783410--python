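"""Texture catalog and extraction: hand examples, brute-force oracles,
conservation laws, and the heterogeneity-contrast monotonicity check."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gliorad.catalog import CATALOG, feature_catalog, catalog_manifest
from gliorad.features import (
    DIRECTIONS_13,
    TextureConfig,
    extract_case_features,
    first_order_features,
    glcm_features,
    glcm_matrix,
    glcm_statistics,
    glrlm_features,
    glrlm_statistics,
    quantize_levels,
    run_list,
    shape_features,
)
from oracles import (
    brute_first_order,
    brute_glcm,
    brute_glcm_stats,
    brute_glrlm_stats,
    brute_runs,
)


def _full_voi(helpers, shape):
    return helpers.voi(np.ones(shape, bool))


class TestCatalog:
    def test_catalog_is_489_unique_stable(self):
        cat = feature_catalog()
        assert len(cat) == 489
        assert len(set(cat)) == 489
        assert cat == feature_catalog()
        assert "T1Gd_core_GLRLMLrge_SD" in cat

    def test_manifest_tags_every_feature(self):
        man = catalog_manifest()
        assert len(man) == 489
        fams = {m["family"] for m in man}
        assert fams == {"Hist", "GLCM", "GLRLM", "Shape"}


class TestQuantize:
    def test_constant_voi_single_bin(self, helpers):
        norm = helpers.norm(np.full((4, 4, 4), 17, dtype=np.int16))
        labels = quantize_levels(norm, _full_voi(helpers, (4, 4, 4)), 32)
        assert set(np.unique(labels)) == {1}

    def test_uniform_full_range_equal_occupancy(self, helpers):
        lv = np.arange(256, dtype=np.int16).reshape(4, 8, 8)
        labels = quantize_levels(helpers.norm(lv), _full_voi(helpers, (4, 8, 8)), 32)
        occ = np.bincount(labels.ravel())[1:]
        assert occ.max() - occ.min() <= 1

    def test_256_bins_is_identity_plus_one(self, helpers):
        lv = np.arange(256, dtype=np.int16).reshape(4, 8, 8)
        labels = quantize_levels(helpers.norm(lv), _full_voi(helpers, (4, 8, 8)), 256)
        assert np.array_equal(labels, lv + 1)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 64))
    def test_bins_always_in_range(self, seed, n_bins):
        from conftest import make_norm, make_voi
        rng = np.random.default_rng(seed)
        lv = rng.integers(0, 256, (5, 5, 5)).astype(np.int16)
        labels = quantize_levels(make_norm(lv), make_voi(np.ones((5, 5, 5), bool)),
                                 n_bins)
        inside = labels[labels > 0]
        assert inside.min() >= 1 and inside.max() <= n_bins


class TestFirstOrder:
    def test_hand_example_1_2_3(self, helpers):
        lv = np.array([1, 2, 3], dtype=np.int16).reshape(3, 1, 1)
        out = first_order_features(helpers.norm(lv), _full_voi(helpers, (3, 1, 1)),
                                   min_voxels=1)
        assert out["Mean"] == pytest.approx(2.0)
        assert out["Range"] == pytest.approx(2.0)
        assert out["Variance"] == pytest.approx(2.0 / 3.0)

    def test_constant_voi_degenerate_stats(self, helpers):
        lv = np.full((3, 3, 3), 9, dtype=np.int16)
        out = first_order_features(helpers.norm(lv), _full_voi(helpers, (3, 3, 3)))
        assert out["Variance"] == 0 and out["Entropy"] == 0 and out["Range"] == 0

    def test_small_voi_returns_missing(self, helpers):
        lv = np.zeros((2, 2, 1), dtype=np.int16)
        out = first_order_features(helpers.norm(lv), _full_voi(helpers, (2, 2, 1)),
                                   min_voxels=8)
        assert all(np.isnan(v) for v in out.values())

    def test_matches_brute_force_oracle(self, helpers):
        rng = np.random.default_rng(7)
        lv = rng.integers(0, 256, (7, 6, 5)).astype(np.int16)
        voi = helpers.voi(rng.uniform(size=(7, 6, 5)) > 0.4)
        out = first_order_features(helpers.norm(lv), voi, min_voxels=1)
        oracle = brute_first_order(lv[voi.mask])
        for k, v in oracle.items():
            assert out[k] == pytest.approx(v, abs=1e-10), k


class TestGLCM:
    def test_slab_example(self):
        labels = np.array([[1, 1], [1, 2]]).reshape(2, 2, 1)
        mat = glcm_matrix(labels, (1, 0, 0), 2)
        assert mat[0, 0] == pytest.approx(0.5)
        assert mat[0, 1] == pytest.approx(0.25)
        stats = glcm_statistics(mat)
        assert stats["Contrast"] == pytest.approx(0.5)
        assert stats["Energy"] == pytest.approx(0.375)
        assert stats["MaxProbability"] == pytest.approx(0.5)

    def test_constant_voi_degenerate(self, helpers):
        labels = np.ones((4, 4, 4), dtype=np.int32)
        out = glcm_features(labels, TextureConfig(n_gray_bins=32))
        assert out["Contrast_Mean"] == 0
        assert out["Energy_Mean"] == 1
        assert out["Entropy_Mean"] == 0
        assert out["Contrast_SD"] == 0

    def test_direction_permutation_invariance(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(1, 6, (6, 6, 6)).astype(np.int32)
        cfg1 = TextureConfig(n_gray_bins=8, directions=DIRECTIONS_13)
        cfg2 = TextureConfig(n_gray_bins=8, directions=tuple(reversed(DIRECTIONS_13)))
        a = glcm_features(labels, cfg1)
        b = glcm_features(labels, cfg2)
        assert a == pytest.approx(b, rel=1e-9, abs=1e-12)

    def test_matrix_sums_to_one_and_symmetric(self):
        rng = np.random.default_rng(2)
        labels = (rng.integers(0, 5, (8, 8, 8))).astype(np.int32)
        for d in DIRECTIONS_13:
            mat = glcm_matrix(labels, d, 4)
            if mat is None:
                continue
            assert mat.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.allclose(mat, mat.T)

    def test_matches_brute_force_on_small_vois(self):
        rng = np.random.default_rng(3)
        for trial in range(3):
            labels = np.where(rng.uniform(size=(5, 5, 4)) > 0.35,
                              rng.integers(1, 5, (5, 5, 4)), 0).astype(np.int32)
            if (labels > 0).sum() > 200 or (labels > 0).sum() == 0:
                continue
            for d in DIRECTIONS_13:
                mine = glcm_matrix(labels, d, 4)
                oracle = brute_glcm(labels, d)
                if mine is None:
                    assert oracle is None
                    continue
                assert np.allclose(mine, oracle, atol=1e-12)
                ostats = brute_glcm_stats(oracle)
                for k, v in glcm_statistics(mine).items():
                    assert v == pytest.approx(ostats[k], abs=1e-8), (k, d)


class TestGLRLM:
    def test_1d_row_example(self):
        labels = np.array([1, 1, 2], dtype=np.int32).reshape(3, 1, 1)
        grays, lengths = run_list(labels, (1, 0, 0))
        assert sorted(zip(grays.tolist(), lengths.tolist())) == [(1, 2), (2, 1)]
        stats = glrlm_statistics(grays, lengths, 3)
        assert stats["RunPct"] == pytest.approx(2.0 / 3.0)
        assert stats["ShortRun"] == pytest.approx(0.625)
        assert stats["Lrge"] == pytest.approx(2.5)

    def test_constant_line_long_run_emphasis(self):
        L = 7
        labels = np.ones((L, 1, 1), dtype=np.int32)
        grays, lengths = run_list(labels, (1, 0, 0))
        stats = glrlm_statistics(grays, lengths, L)
        assert stats["Lrge"] == pytest.approx(L**2)

    def test_run_mass_conservation_every_direction(self):
        rng = np.random.default_rng(4)
        labels = np.where(rng.uniform(size=(7, 7, 7)) > 0.3,
                          rng.integers(1, 6, (7, 7, 7)), 0).astype(np.int32)
        n = (labels > 0).sum()
        for d in DIRECTIONS_13:
            _, lengths = run_list(labels, d)
            assert lengths.sum() == n, d

    def test_matches_brute_force_on_small_vois(self):
        rng = np.random.default_rng(5)
        labels = np.where(rng.uniform(size=(5, 5, 5)) > 0.4,
                          rng.integers(1, 4, (5, 5, 5)), 0).astype(np.int32)
        assert 0 < (labels > 0).sum() <= 200
        n = (labels > 0).sum()
        for d in DIRECTIONS_13:
            grays, lengths = run_list(labels, d)
            mine = sorted(zip(grays.tolist(), lengths.tolist()))
            oracle = sorted(brute_runs(labels, d))
            assert mine == oracle, d
            ostats = brute_glrlm_stats(oracle, n)
            for k, v in glrlm_statistics(grays, lengths, n).items():
                assert v == pytest.approx(ostats[k], abs=1e-8), (k, d)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_conservation_property(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.where(rng.uniform(size=(6, 5, 4)) > rng.uniform(0, 0.9),
                          rng.integers(1, 8, (6, 5, 4)), 0).astype(np.int32)
        n = (labels > 0).sum()
        for d in ((1, 0, 0), (1, -1, 1)):
            _, lengths = run_list(labels, d)
            assert lengths.sum() == n


class TestShape:
    def test_digital_ball_sphericity_near_one(self, helpers):
        r = 10
        x = np.arange(-14, 15)
        xx, yy, zz = np.meshgrid(x, x, x, indexing="ij")
        ball = xx**2 + yy**2 + zz**2 <= r**2
        core = helpers.voi(ball)
        out = shape_features(core, None, (1.0, 1.0, 1.0))
        assert 0.95 <= out["Shape_core_Sphericity"] <= 1.05
        assert out["Shape_core_Volume"] == pytest.approx(4 / 3 * np.pi * r**3,
                                                         rel=0.05)
        assert out["Shape_core_MaxDiameter"] == pytest.approx(2 * r, rel=0.1)

    def test_single_voxel_volume(self, helpers):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        out = shape_features(helpers.voi(mask), None, (1.0, 1.0, 1.0))
        assert out["Shape_core_Volume"] == pytest.approx(1.0)

    def test_empty_edema_flags_only_edema_features(self, helpers):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        core = helpers.voi(mask)
        edema = helpers.voi(np.zeros((8, 8, 8), bool), role="edema")
        out = shape_features(core, edema, (1.0, 1.0, 1.0))
        assert np.isfinite(out["Shape_core_Volume"])
        assert np.isnan(out["Shape_edema_Volume"])
        assert np.isnan(out["Shape_edema_CoreVolumeRatio"])


class TestExtractCase:
    def test_complete_case_has_489_values(self, preprocessed_case):
        vec = extract_case_features(preprocessed_case["series"],
                                    preprocessed_case["core"],
                                    preprocessed_case["edema"])
        assert len(vec) == 489
        assert list(vec.index) == CATALOG
        assert vec.notna().all()

    def test_extraction_is_deterministic(self, preprocessed_case):
        a = extract_case_features(preprocessed_case["series"],
                                  preprocessed_case["core"],
                                  preprocessed_case["edema"])
        b = extract_case_features(preprocessed_case["series"],
                                  preprocessed_case["core"],
                                  preprocessed_case["edema"])
        pd.testing.assert_series_equal(a, b)

    def test_empty_edema_keeps_all_keys(self, preprocessed_case, helpers):
        shape = preprocessed_case["core"].mask.shape
        empty = helpers.voi(np.zeros(shape, bool), role="edema")
        vec = extract_case_features(preprocessed_case["series"],
                                    preprocessed_case["core"], empty)
        assert len(vec) == 489
        edema_tex = [c for c in CATALOG if "_edema_" in c and
                     not c.startswith("Shape")]
        assert vec[edema_tex].isna().all()
        assert np.isnan(vec["Shape_edema_Volume"])
        assert vec[[c for c in CATALOG if "_core_" in c]].notna().all()

    def test_missing_series_flags_its_features_only(self, preprocessed_case):
        series = dict(preprocessed_case["series"])
        series.pop("Gdzscore")
        vec = extract_case_features(series, preprocessed_case["core"],
                                    preprocessed_case["edema"])
        assert len(vec) == 489
        assert vec[[c for c in CATALOG if c.startswith("Gdzscore_")]].isna().all()
        assert vec[[c for c in CATALOG if c.startswith("T1_")]].notna().all()


class TestHeterogeneityMonotonicity:
    def test_contrast_increases_with_planted_heterogeneity(self):
        """Mean GLCM contrast of the enhancing core must rise, on average
        over 20 paired phantom cases, when the planted texture SD rises."""
        from gliorad.synthetic import CohortConfig, generate_case
        from gliorad.preproc import normalize_t1_like
        from gliorad.voi import build_voi_core

        def contrast(het, seed):
            # fixed-width bins on the absolute 0-255 scale: in-VOI min-max
            # re-binning deliberately removes amplitude, so the planted
            # texture SD must be measured against a fixed gray scale
            cfg = CohortConfig(
                n_cases=2, grid_shape=(40, 40, 40), spacing_mm=(2.0, 2.0, 2.0),
                heterogeneity_range=(het, het), seed=seed,
                core_radius_range=(9.0, 12.0), edema_margin_range=(5.0, 7.0),
                center_jitter_mm=3.0)
            case = generate_case(cfg, 0)
            norm = normalize_t1_like(case.t1gd, case.t1gd.voxels != 0)
            labels = np.zeros(norm.shape, np.int32)
            sel = case.core_mask & norm.validity
            labels[sel] = norm.levels[sel] // 8 + 1
            return glcm_features(labels, TextureConfig())["Contrast_Mean"]

        lo = [contrast(5.0, s) for s in range(20)]
        hi = [contrast(25.0, s) for s in range(20)]
        assert np.mean(hi) > np.mean(lo)
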