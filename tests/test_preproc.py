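"""Intensity normalization, derived series, resampling, and NIfTI I/O."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gliorad.preproc import (
    AffineTransform,
    GridSpec,
    GridMismatchError,
    Image3D,
    LoadError,
    compute_gdzscore,
    compute_t2edge,
    load_study,
    normalize_t1_like,
    normalize_t2,
    read_nifti,
    resample_affine,
    resample_mask,
    write_nifti,
)


class TestLoadStudy:
    @pytest.fixture
    def study_dir(self, tmp_path, helpers):
        rng = np.random.default_rng(0)
        shape = (12, 12, 12)
        for name in ("t1", "t2", "t1gd"):
            write_nifti(helpers.image(rng.uniform(1, 100, shape)),
                        tmp_path / f"{name}.nii.gz")
        mask = np.zeros(shape)
        mask[4:8, 4:8, 4:8] = 2.0
        mask[5, 5, 5] = 7.0
        write_nifti(helpers.image(mask), tmp_path / "core.nii.gz")
        write_nifti(helpers.image(mask), tmp_path / "t2les.nii.gz")
        return tmp_path

    def test_bundle_has_five_grids_and_binarized_masks(self, study_dir):
        b = load_study("c1", study_dir / "t1.nii.gz", study_dir / "t2.nii.gz",
                       study_dir / "t1gd.nii.gz", study_dir / "core.nii.gz",
                       study_dir / "t2les.nii.gz")
        assert b.t1.shape == b.t2.shape == b.t1gd.shape == (12, 12, 12)
        assert set(np.unique(b.core_mask)) == {False, True}
        assert b.core_mask.sum() == 64  # the 2s and the 7 all binarize to True

    def test_missing_file_raises(self, study_dir):
        with pytest.raises(LoadError):
            load_study("c1", study_dir / "nope.nii.gz", study_dir / "t2.nii.gz",
                       study_dir / "t1gd.nii.gz", study_dir / "core.nii.gz",
                       study_dir / "t2les.nii.gz")

    def test_mask_grid_mismatch_raises(self, study_dir, tmp_path, helpers):
        write_nifti(helpers.image(np.ones((8, 8, 8))), tmp_path / "small.nii.gz")
        with pytest.raises(LoadError):
            load_study("c1", study_dir / "t1.nii.gz", study_dir / "t2.nii.gz",
                       study_dir / "t1gd.nii.gz", tmp_path / "small.nii.gz",
                       study_dir / "t2les.nii.gz")


class TestNormalizeT1Like:
    def test_top_permille_deleted_and_range_mapped(self, helpers):
        img = helpers.image(np.arange(1000.0).reshape(10, 10, 10))
        norm = normalize_t1_like(img, np.ones((10, 10, 10), bool))
        assert 998.0 <= norm.normalization_params[1] < 999.0
        flat = norm.levels.ravel()
        valid = norm.validity.ravel()
        assert not valid[999]            # the single top-0.1% voxel
        assert valid[:999].all()
        assert flat[0] == 0
        assert flat[998] == 255

    def test_constant_image_maps_to_zero(self, helpers):
        img = helpers.image(np.full((6, 6, 6), 42.0))
        norm = normalize_t1_like(img, np.ones((6, 6, 6), bool))
        assert norm.validity.sum() > 0
        assert np.all(norm.levels[norm.validity] == 0)

    def test_invalid_fraction_bounded_on_continuous_input(self, helpers):
        rng = np.random.default_rng(1)
        img = helpers.image(rng.uniform(0, 1, (40, 40, 40)))
        mask = np.ones((40, 40, 40), bool)
        norm = normalize_t1_like(img, mask)
        invalid_frac = 1.0 - norm.validity.sum() / mask.sum()
        assert invalid_frac <= 0.002

    def test_empty_mask_rejected(self, helpers):
        img = helpers.image(np.ones((4, 4, 4)))
        with pytest.raises(ValueError):
            normalize_t1_like(img, np.zeros((4, 4, 4), bool))


class TestNormalizeT2:
    def test_three_value_map(self, helpers):
        vals = np.array([10.0, 20.0, 30.0] * 9).reshape(3, 3, 3)
        norm = normalize_t2(helpers.image(vals))
        lv = np.unique(norm.levels)
        assert list(lv) == [0, 128, 255]
        assert norm.validity.all()

    def test_constant_maps_to_zero(self, helpers):
        norm = normalize_t2(helpers.image(np.full((4, 4, 4), 5.0)),
                            np.ones((4, 4, 4), bool))
        assert np.all(norm.levels == 0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_levels_in_range_and_max_hits_255(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(-50, 200, (6, 6, 6))
        img = Image3D(vals, np.ones(3), np.eye(4), "T2")
        norm = normalize_t2(img, np.ones((6, 6, 6), bool))
        assert norm.levels.min() >= 0 and norm.levels.max() == 255
        # the in-mask maximum always maps to the top level
        assert norm.levels[np.unravel_index(np.argmax(vals), vals.shape)] == 255

    def test_renormalization_is_near_idempotent(self, helpers):
        rng = np.random.default_rng(2)
        vals = rng.integers(0, 256, (8, 8, 8)).astype(float)
        vals.ravel()[0], vals.ravel()[1] = 0.0, 255.0  # pin the full range
        norm1 = normalize_t2(helpers.image(vals), np.ones((8, 8, 8), bool))
        norm2 = normalize_t2(helpers.image(norm1.levels.astype(float)),
                             np.ones((8, 8, 8), bool))
        assert np.max(np.abs(norm2.levels - norm1.levels)) <= 1


class TestT2Edge:
    def test_constant_region_gives_zero_edges(self, helpers):
        norm = helpers.norm(np.full((8, 8, 8), 100, dtype=np.int16))
        edge = compute_t2edge(norm)
        assert np.all(edge.levels == 0)

    def test_linear_ramp_interior_is_uniform(self, helpers):
        x = np.arange(10)
        vals = np.broadcast_to(x[:, None, None], (10, 10, 10)).astype(np.int16)
        edge = compute_t2edge(helpers.norm(np.ascontiguousarray(vals)))
        interior = edge.levels[edge.validity]
        assert len(np.unique(interior)) == 1

    def test_validity_shrinks_and_levels_bounded(self, preprocessed_case):
        t2 = preprocessed_case["series"]["T2"]
        edge = preprocessed_case["series"]["T2Edge"]
        assert np.all(edge.validity <= t2.validity)
        assert edge.levels.min() >= 0 and edge.levels.max() <= 255

    def test_axis_permutation_leaves_magnitude_unchanged(self, helpers):
        rng = np.random.default_rng(3)
        vals = rng.integers(0, 256, (9, 9, 9)).astype(np.int16)
        edge = compute_t2edge(helpers.norm(vals))
        perm = (2, 0, 1)
        edge_p = compute_t2edge(helpers.norm(np.transpose(vals, perm).copy()))
        assert np.array_equal(edge_p.levels, np.transpose(edge.levels, perm))


class TestGdzscore:
    def test_no_enhancement_gives_zero(self, helpers):
        lv = np.arange(27, dtype=np.int16).reshape(3, 3, 3)
        z = compute_gdzscore(helpers.norm(lv), helpers.norm(lv.copy()))
        assert np.all(z.levels == 0)

    def test_two_point_difference_distribution(self, helpers):
        t1 = helpers.norm(np.zeros((2, 2, 1), dtype=np.int16))
        t1gd = helpers.norm(np.array([[[0], [0]], [[10], [10]]], dtype=np.int16))
        z = compute_gdzscore(t1, t1gd)
        # D = {0,0,10,10} -> z = {-1,-1,1,1} -> levels {0,0,255,255}
        assert sorted(z.levels.ravel().tolist()) == [0, 0, 255, 255]

    def test_grid_mismatch_raises(self, helpers):
        with pytest.raises(GridMismatchError):
            compute_gdzscore(helpers.norm(np.zeros((3, 3, 3), dtype=np.int16)),
                             helpers.norm(np.zeros((4, 4, 4), dtype=np.int16)))


class TestResample:
    def _grid(self, img):
        return GridSpec(img.shape, img.grid_to_world)

    def test_identity_is_exact(self, helpers):
        rng = np.random.default_rng(4)
        img = helpers.image(rng.uniform(0, 255, (10, 10, 10)))
        out = resample_affine(img, AffineTransform.identity(), self._grid(img))
        assert np.allclose(out.voxels, img.voxels)

    def test_integer_translation_of_mask_matches_index_shift(self):
        mask = np.zeros((16, 16, 16), bool)
        mask[5:9, 6:10, 4:8] = True
        xfm = AffineTransform(np.array([
            [1, 0, 0, 3.0], [0, 1, 0, -2.0], [0, 0, 1, 0.0], [0, 0, 0, 1]]))
        target = GridSpec((16, 16, 16), np.eye(4))
        out = resample_mask(mask, np.eye(4), xfm, target)
        oracle = np.roll(mask, (3, -2, 0), axis=(0, 1, 2))
        assert np.array_equal(out, oracle)
        assert out.sum() == mask.sum()

    def test_constant_image_stays_constant_inside(self, helpers):
        img = helpers.image(np.full((12, 12, 12), 7.0))
        xfm = AffineTransform(np.array([
            [1, 0, 0, 0.4], [0, 1, 0, 0.2], [0, 0, 1, -0.3], [0, 0, 0, 1]]))
        out = resample_affine(img, xfm, self._grid(img))
        interior = out.voxels[2:-2, 2:-2, 2:-2]
        assert np.allclose(interior, 7.0)

    def test_roundtrip_within_interpolation_tolerance(self, helpers):
        from scipy.ndimage import gaussian_filter
        rng = np.random.default_rng(5)
        smooth = gaussian_filter(rng.uniform(0, 255, (20, 20, 20)), 2.0)
        img = helpers.image(smooth)
        xfm = AffineTransform(np.array([
            [1, 0, 0, 1.5], [0, 1, 0, -0.5], [0, 0, 1, 0.7], [0, 0, 0, 1]]))
        fwd = resample_affine(img, xfm, self._grid(img))
        back = resample_affine(fwd, xfm.inverse(), self._grid(img))
        inner = (slice(4, -4),) * 3
        assert np.max(np.abs(back.voxels[inner] - img.voxels[inner])) <= 2.0

    def test_unknown_interpolation_rejected(self, helpers):
        img = helpers.image(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            resample_affine(img, AffineTransform.identity(), self._grid(img),
                            interpolation="cubic")

    def test_nifti_roundtrip_exact(self, tmp_path, helpers):
        rng = np.random.default_rng(6)
        img = helpers.image(rng.uniform(-10, 10, (7, 7, 7)))
        p = write_nifti(img, tmp_path / "x.nii.gz")
        back = read_nifti(p)
        assert np.array_equal(back.voxels, img.voxels)
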