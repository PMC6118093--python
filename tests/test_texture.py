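import numpy as np
import pytest

from fetmri.grids import LesionMask, VoxelGrid
from fetmri.phantoms import generate_case
from fetmri.texture import (
    DIRECTIONS_13,
    FEATURE_NAMES,
    GLCM_NAMES,
    GLRLM_NAMES,
    GLZLM_NAMES,
    HISTOGRAM_NAMES,
    NGLDM_NAMES,
    SHAPE_NAMES,
    STATISTICAL_NAMES,
    QuantizedVOI,
    build_glcm,
    build_glrlm,
    build_glzlm,
    build_ngldm,
    conventional_stats,
    extract_all,
    extract_features,
    glcm_features,
    glrlm_features,
    glzlm_features,
    histogram_features,
    ngldm_features,
    quantize,
    shape_features,
)

from conftest import ball_mask, clean_spec, make_random_voi
from oracles import (
    brute_glcm,
    brute_glcm_features,
    brute_glrlm_features,
    brute_glzlm_features,
    brute_ngldm_features,
)


def voi_from_levels(levels):
    levels = np.asarray(levels, dtype=np.int32)
    mask = levels > 0
    return QuantizedVOI(levels=levels, mask=mask, G=int(levels.max()), lower=0, upper=1,
                        degenerate=False)


def grid_and_mask(values, spacing=(1.0, 1.0, 1.0)):
    values = np.asarray(values, dtype=float)
    return VoxelGrid(values, spacing), LesionMask(np.ones(values.shape, dtype=bool), spacing)


class TestQuantize:
    def test_constant_voi_is_degenerate(self):
        grid, mask = grid_and_mask(np.full((3, 3, 3), 5.0))
        q = quantize(grid, mask)
        assert q.degenerate
        assert np.all(q.in_mask_levels == 1)

    def test_hand_computed_binning(self):
        values = np.array([0, 1, 2, 3, 4, 5, 6, 8], dtype=float).reshape(2, 2, 2)
        grid, mask = grid_and_mask(values)
        q = quantize(grid, mask, G=64)
        mean, sd = values.mean(), values.std()
        lower, upper = mean - 3 * sd, mean + 3 * sd
        expected = np.clip(1 + np.floor(64 * (values - lower) / (upper - lower)), 1, 64)
        assert np.array_equal(q.levels[q.mask], expected[mask.support].astype(int))
        assert q.lower == pytest.approx(lower) and q.upper == pytest.approx(upper)

    def test_outliers_clamped_to_extreme_bins(self):
        values = np.ones((3, 3, 3))
        values[0, 0, 0] = 1e6  # way above mean + 3 SD
        values[2, 2, 2] = -1e6
        grid, mask = grid_and_mask(values)
        q = quantize(grid, mask)
        assert q.levels[0, 0, 0] == 64
        assert q.levels[2, 2, 2] == 1

    def test_empty_mask_rejected(self):
        grid = VoxelGrid(np.ones((3, 3, 3)), (1, 1, 1))
        empty = LesionMask(np.zeros((3, 3, 3), dtype=bool), (1, 1, 1))
        with pytest.raises(ValueError):
            quantize(grid, empty)


class TestConventionalStats:
    def test_hand_arithmetic(self):
        values = np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 1, 4)
        grid = VoxelGrid(values, (1.0, 1.0, 1.0))
        mask = LesionMask(np.ones((1, 1, 4), dtype=bool), (1.0, 1.0, 1.0))
        stats = conventional_stats(grid, mask)
        assert stats["Min"] == 1 and stats["Max"] == 4
        assert stats["Mean"] == pytest.approx(2.5)
        assert stats["Volume"] == pytest.approx(0.004)  # 4 mm^3 in mL

    def test_constant_voi_sd_zero(self):
        grid, mask = grid_and_mask(np.full((2, 2, 2), 3.0))
        assert conventional_stats(grid, mask)["SD"] == 0.0

    def test_intensity_scaling_linearity(self, rng):
        values = rng.random((3, 3, 3))
        grid, mask = grid_and_mask(values)
        base = conventional_stats(grid, mask)
        scaled = conventional_stats(grid.with_values(5.0 * values), mask)
        for key in ("Min", "Mean", "Max", "SD"):
            assert scaled[key] == pytest.approx(5.0 * base[key])
        assert scaled["Volume"] == base["Volume"]


class TestHistogram:
    def test_uniform_64_bins_closed_form(self):
        levels = np.arange(1, 65, dtype=np.int32).reshape(4, 4, 4)
        q = QuantizedVOI(levels, np.ones((4, 4, 4), bool), 64, 0, 1, False)
        feats, _ = histogram_features(q)
        assert feats["HISTO_Entropy"] == pytest.approx(6.0)
        assert feats["HISTO_Energy"] == pytest.approx(1 / 64)

    def test_single_bin(self):
        q = QuantizedVOI(np.full((2, 2, 2), 5, np.int32), np.ones((2, 2, 2), bool), 64, 0, 1, False)
        feats, flags = histogram_features(q)
        assert feats["HISTO_Entropy"] == 0.0
        assert feats["HISTO_Energy"] == 1.0
        assert "HISTO_Skewness" in flags and feats["HISTO_Skewness"] == 0.0

    def test_symmetric_two_point_skewness_zero(self):
        levels = np.array([20, 40] * 4, dtype=np.int32).reshape(2, 2, 2)
        q = QuantizedVOI(levels, np.ones((2, 2, 2), bool), 64, 0, 1, False)
        feats, _ = histogram_features(q)
        assert feats["HISTO_Skewness"] == pytest.approx(0.0, abs=1e-12)
        assert feats["HISTO_Kurtosis"] == pytest.approx(1.0)  # two-point distribution


class TestGlcm:
    def test_constant_voi_closed_forms(self):
        q = voi_from_levels(np.ones((3, 3, 3)))
        feats, flags = glcm_features(build_glcm(q))
        assert feats["GLCM_Energy"] == 1.0
        assert feats["GLCM_Entropy"] == 0.0
        assert feats["GLCM_Contrast"] == 0.0
        assert feats["GLCM_Dissimilarity"] == 0.0
        assert feats["GLCM_Homogeneity"] == pytest.approx(1.0)
        assert feats["GLCM_Correlation"] == 0.0 and "GLCM_Correlation" in flags

    def test_checkerboard_contrast_matches_brute_force(self):
        idx = np.indices((4, 4, 4)).sum(axis=0)
        levels = (idx % 2 + 1).astype(np.int32)
        q = voi_from_levels(levels)
        mine, _ = glcm_features(build_glcm(q))
        ref = brute_glcm_features(brute_glcm(q.levels, q.mask, q.G))
        for name in GLCM_NAMES:
            assert mine[name] == pytest.approx(ref[name], abs=1e-10)

    def test_matrix_is_normalized_and_symmetric(self, random_voi_factory):
        for _ in range(20):
            p = build_glcm(random_voi_factory())
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            np.testing.assert_allclose(p, p.T, atol=1e-12)


class TestGlrlm:
    def test_single_voxel(self):
        levels = np.zeros((3, 3, 3), np.int32)
        levels[1, 1, 1] = 4
        feats = glrlm_features(build_glrlm(voi_from_levels(levels)), 1)
        assert feats["SRE"] == 1.0 and feats["LRE"] == 1.0 and feats["RP"] == 1.0

    def test_constant_line_hand_enumerated(self):
        # 1x1x8 line of one grey level embedded in a 3x3x10 grid: the axial
        # direction gives 1 run of length 8; the other 12 directions give 8
        # runs of length 1 each.
        levels = np.zeros((3, 3, 10), np.int32)
        levels[1, 1, 1:9] = 2
        matrix = build_glrlm(voi_from_levels(levels))
        n_r = matrix.sum()
        assert n_r == 1 + 12 * 8
        feats = glrlm_features(matrix, 8)
        assert feats["SRE"] == pytest.approx((96 + 1 / 64) / 97)
        assert feats["LRE"] == pytest.approx((96 + 64) / 97)
        assert feats["RP"] == pytest.approx(97 / (13 * 8))

    def test_random_vois_match_brute_force(self, random_voi_factory):
        for _ in range(15):
            q = random_voi_factory()
            mine = glrlm_features(build_glrlm(q), q.n_voxels)
            ref = brute_glrlm_features(q.levels, q.mask, q.n_voxels)
            for name in GLRLM_NAMES:
                assert mine[name] == pytest.approx(ref[name], abs=1e-10), name


class TestNgldm:
    def test_constant_voi_degenerate(self):
        q = voi_from_levels(np.ones((3, 3, 3)))
        feats, flags = ngldm_features(*build_ngldm(q))
        assert feats["NGLDM_Coarseness"] == pytest.approx(1e6)
        assert feats["NGLDM_Contrast"] == 0.0
        assert "NGLDM_Busyness" in flags

    def test_alternating_cube_hand_computed(self):
        # 2x2x2 checkerboard of levels 1/2: each voxel has 7 in-VOI
        # neighbours, 4 of the other level and 3 of its own.
        idx = np.indices((2, 2, 2)).sum(axis=0)
        q = voi_from_levels((idx % 2 + 1).astype(np.int32))
        p, s, n_contrib = build_ngldm(q)
        assert n_contrib == 8
        assert p[0] == pytest.approx(0.5) and p[1] == pytest.approx(0.5)
        assert s[0] == pytest.approx(16 / 7) and s[1] == pytest.approx(16 / 7)
        feats, _ = ngldm_features(p, s, n_contrib)
        assert feats["NGLDM_Coarseness"] == pytest.approx(1 / (1e-6 + 16 / 7))
        assert feats["NGLDM_Contrast"] == pytest.approx(1 / 7)
        assert feats["NGLDM_Busyness"] == pytest.approx(16 / 7)

    def test_random_vois_match_brute_force(self, random_voi_factory):
        for _ in range(15):
            q = random_voi_factory()
            mine, _ = ngldm_features(*build_ngldm(q))
            ref = brute_ngldm_features(q.levels, q.mask)
            for name in NGLDM_NAMES:
                assert mine[name] == pytest.approx(ref[name], abs=1e-10), name


class TestGlzlm:
    def test_connected_constant_voi_closed_form(self):
        q = voi_from_levels(np.ones((3, 3, 3)))  # one zone of 27
        feats = glzlm_features(build_glzlm(q), 27)
        assert feats["SZE"] == pytest.approx(1 / 27**2)
        assert feats["LZE"] == pytest.approx(27**2)
        assert feats["ZP"] == pytest.approx(1 / 27)

    def test_all_distinct_levels(self):
        levels = np.arange(1, 9, dtype=np.int32).reshape(2, 2, 2)
        feats = glzlm_features(build_glzlm(voi_from_levels(levels)), 8)
        assert feats["SZE"] == 1.0 and feats["LZE"] == 1.0 and feats["ZP"] == 1.0

    def test_random_vois_match_brute_force(self, random_voi_factory):
        for _ in range(15):
            q = random_voi_factory()
            mine = glzlm_features(build_glzlm(q), q.n_voxels)
            ref = brute_glzlm_features(q.levels, q.mask, q.n_voxels)
            for name in GLZLM_NAMES:
                assert mine[name] == pytest.approx(ref[name], abs=1e-10), name


class TestShape:
    def test_cube_sphericity_closed_form(self):
        support = np.zeros((14, 14, 14), dtype=bool)
        support[2:12, 2:12, 2:12] = True
        feats = shape_features(LesionMask(support, (1.0, 1.0, 1.0)))
        expected = (36 * np.pi) ** (1 / 3) / 6  # ~0.806
        assert feats["Sphericity"] == pytest.approx(expected, rel=0.02)

    def test_ball_sphericity_near_one(self):
        # Meshes of digital balls carry a staircase-facet bias that inflates
        # the measured area by a few percent, so the estimate sits slightly
        # below 1 (value frozen from the mesh-surface computation itself).
        feats = shape_features(ball_mask(shape=(25, 25, 25), radius_mm=10.0))
        assert 0.90 <= feats["Sphericity"] <= 1.00

    def test_elongated_box_less_spherical_than_cube(self):
        box = np.zeros((3, 3, 102), dtype=bool)
        box[1, 1, 1:101] = True
        cube_side = round(100 ** (1 / 3))
        cube = np.zeros((8, 8, 8), dtype=bool)
        cube[1 : 1 + cube_side, 1 : 1 + cube_side, 1 : 1 + cube_side] = True
        s_box = shape_features(LesionMask(box, (1, 1, 1)))["Sphericity"]
        s_cube = shape_features(LesionMask(cube, (1, 1, 1)))["Sphericity"]
        assert s_box < s_cube

    def test_compacity_definition(self):
        mask = ball_mask(shape=(25, 25, 25), radius_mm=10.0)
        feats = shape_features(mask)
        # consistency between the two indices through the common V and A
        v = mask.n_voxels * 1.0
        a = (36 * np.pi * v**2) ** (1 / 3) / feats["Sphericity"]
        assert feats["Compacity"] == pytest.approx(v / (np.sqrt(np.pi) * a**1.5), rel=1e-6)


class TestConservationLaws:
    def test_matrix_invariants_on_random_vois(self, random_voi_factory):
        for _ in range(30):
            q = random_voi_factory()
            nv = q.n_voxels
            p = build_glcm(q)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            r = build_glrlm(q)
            lengths = np.arange(1, r.shape[1] + 1)
            assert (r * lengths).sum() == pytest.approx(13 * nv)
            z = build_glzlm(q)
            sizes = np.arange(1, z.shape[1] + 1)
            assert (z * sizes).sum() == pytest.approx(nv)
            pi, _, _ = build_ngldm(q)
            assert pi.sum() == pytest.approx(1.0, abs=1e-12)


class TestInvariances:
    def test_grey_level_inversion_invariance(self, rng):
        for _ in range(10):
            q = make_random_voi(rng, G=8)
            inverted = QuantizedVOI(
                np.where(q.mask, q.G + 1 - q.levels, 0), q.mask, q.G, 0, 1, False
            )
            a_glcm, _ = glcm_features(build_glcm(q))
            b_glcm, _ = glcm_features(build_glcm(inverted))
            for name in ("GLCM_Contrast", "GLCM_Dissimilarity"):
                assert a_glcm[name] == pytest.approx(b_glcm[name], abs=1e-10)
            a_r = glrlm_features(build_glrlm(q), q.n_voxels)
            b_r = glrlm_features(build_glrlm(inverted), q.n_voxels)
            for name in ("SRE", "LRE", "RP"):
                assert a_r[name] == pytest.approx(b_r[name], abs=1e-10)
            a_z = glzlm_features(build_glzlm(q), q.n_voxels)
            b_z = glzlm_features(build_glzlm(inverted), q.n_voxels)
            for name in ("SZE", "LZE", "ZP"):
                assert a_z[name] == pytest.approx(b_z[name], abs=1e-10)

    def test_texture_amp_controls_glcm_and_intensity_heterogeneity(self):
        # Raising the texture amplitude raises the raw intra-VOI intensity SD.
        # Because quantization rescales to mean +/- 3 SD, amplitude itself
        # cancels from the grey levels; what grows with amp is the weight of
        # the spatially *correlated* field relative to white noise, so
        # co-occurrences concentrate: GLCM entropy falls and energy rises.
        stats = {0.05: {"SD": [], "ent": [], "ene": []},
                 0.5: {"SD": [], "ent": [], "ene": []}}
        for amp in stats:
            spec = clean_spec(texture_amp=amp, noise_sd_mri=1.0, seed=31)
            for i in range(8):
                case = generate_case(spec, "injury", f"amp{amp}_{i}")
                feats, _ = extract_features(case.mri, case.mri_mask)
                stats[amp]["SD"].append(feats["SD"])
                stats[amp]["ent"].append(feats["GLCM_Entropy"])
                stats[amp]["ene"].append(feats["GLCM_Energy"])
        assert np.mean(stats[0.5]["SD"]) > np.mean(stats[0.05]["SD"])
        assert np.mean(stats[0.5]["ent"]) < np.mean(stats[0.05]["ent"])
        assert np.mean(stats[0.5]["ene"]) > np.mean(stats[0.05]["ene"])


class TestExtractAll:
    def test_42_features_per_channel_partitioned(self, small_spec):
        case = generate_case(small_spec, "recurrence", "x")
        feats, _, excl = extract_all(case)
        assert not excl
        assert len(feats) == 4 * 42
        for prefix in ("T1_", "T1_LoG_", "T1_DWT3_", "PET_"):
            names = {k.removeprefix(prefix) for k in feats if k.startswith(prefix)}
            names -= {n for n in names if any((prefix + n).startswith(q + "_")
                      for q in ("T1_LoG", "T1_DWT3") if prefix == "T1_")}
        assert len(STATISTICAL_NAMES) == 5
        assert len(HISTOGRAM_NAMES) == 4
        assert len(GLCM_NAMES + GLRLM_NAMES + NGLDM_NAMES + GLZLM_NAMES) == 31
        assert len(SHAPE_NAMES) == 2
        assert set(FEATURE_NAMES) == set(
            STATISTICAL_NAMES + HISTOGRAM_NAMES + GLCM_NAMES + GLRLM_NAMES
            + NGLDM_NAMES + GLZLM_NAMES + SHAPE_NAMES
        )
        pet_names = {k for k in feats if k.startswith("PET_")}
        assert pet_names == {"PET_" + n for n in FEATURE_NAMES}

    def test_filters_on_pet_refused(self, small_spec):
        case = generate_case(small_spec, "injury", "y")
        with pytest.raises(ValueError, match="unfiltered"):
            extract_all(case, channels=("PET_LoG",))

    def test_small_pet_voi_excluded_mri_retained(self, small_spec):
        case = generate_case(small_spec, "injury", "z")
        # supra-threshold PET uptake confined to a 99-voxel pocket
        pet = np.ones(case.pet.shape)
        pocket = np.zeros_like(pet, dtype=bool)
        pocket.flat[
            np.ravel_multi_index(np.nonzero(case.mri_mask.support), pet.shape)[:99]
        ] = True
        pet[pocket] = 2.0
        case = type(case)(
            case_id=case.case_id,
            pet=VoxelGrid(pet, case.pet.spacing_mm, modality="PET"),
            mri=case.mri, mri_mask=case.mri_mask,
            pet_background=1.0, label=case.label,
        )
        feats, _, excl = extract_all(case)
        assert "PET" in excl
        assert not any(k.startswith("PET_") for k in feats)
        assert any(k.startswith("T1_") for k in feats)

    def test_pet_negative_falls_back_to_transferred_mri_mask(self, small_spec):
        case = generate_case(small_spec, "injury", "w")
        pet = np.ones(case.pet.shape)
        pet[case.mri_mask.support] = 1.5  # below TBR 1.6
        case = type(case)(
            case_id=case.case_id,
            pet=VoxelGrid(pet, case.pet.spacing_mm, modality="PET"),
            mri=case.mri, mri_mask=case.mri_mask,
            pet_background=1.0, label=case.label,
        )
        feats, flags, excl = extract_all(case)
        assert "PET" not in excl
        assert flags.get("PET_voi", "").startswith("PET-negative")
        assert feats["PET_Mean"] == pytest.approx(1.5, abs=0.01)


class TestQuantizeProperties:
    from hypothesis import given, settings, strategies as st

    @given(
        st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=8, max_size=27),
        st.sampled_from([8, 16, 64]),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_levels_always_within_bins(self, values, G):
        side = int(np.ceil(len(values) ** (1 / 3)))
        arr = np.zeros(side**3)
        arr[: len(values)] = values
        grid, mask = grid_and_mask(arr.reshape(side, side, side))
        q = quantize(grid, mask, G=G)
        levels = q.in_mask_levels
        assert levels.min() >= 1 and levels.max() <= G
        assert len(levels) == mask.n_voxels
        if q.degenerate:
            assert np.all(levels == 1)
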