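"""Handcrafted feature bank: cardinalities, hand-worked texture oracles,
shape geometry, and habitat aggregation invariances."""

import numpy as np
import pandas as pd
import pytest

from habitatmil.features import (
    _OFFSETS_13,
    _glcm_kernel,
    _glrlm_kernel,
    _runzone_feats_nb,
    GLRLM_NAMES,
    extract_all,
    extract_habitat_features,
    feature_metadata,
    feature_names,
    filter_bank_images,
    first_order_features,
    shape_features,
)
from habitatmil.habitat import HabitatMap
from habitatmil.preprocess import CTVolume, MaskVolume, clip_hu


def test_bank_cardinalities():
    meta = feature_metadata()
    counts = meta["category"].value_counts()
    assert counts["geometry"] == 14
    assert counts["intensity"] == 360
    assert counts["texture"] == 1460
    assert len(meta) == 1834
    assert meta.index.is_unique


def test_extracted_vector_matches_canonical_order(phantom_features):
    assert list(phantom_features.index) == feature_names()
    assert phantom_features.notna().all()


def test_filter_bank_has_twenty_images(phantom_patient, pre_cfg):
    vol = clip_hu(phantom_patient.ct, pre_cfg)
    bank = filter_bank_images(vol.values[:16, :16, :16])
    assert len(bank) == 20
    for img in bank.values():
        assert img.shape == (16, 16, 16)


def test_determinism(phantom_patient, pre_cfg, phantom_features):
    vol = clip_hu(phantom_patient.ct, pre_cfg)
    again = extract_all(vol, phantom_patient.mask, pre_cfg)
    pd.testing.assert_series_equal(phantom_features, again)


class TestShape:
    def test_sphere_sphericity(self, sphere_pair):
        _, mask = sphere_pair
        s = shape_features(mask)
        assert 0.95 <= s["shape_Sphericity"] <= 1.0

    def test_cube_mesh_volume(self):
        arr = np.zeros((14, 14, 14), np.uint8)
        arr[2:12, 2:12, 2:12] = 1  # 10 mm cube at 1 mm spacing
        s = shape_features(MaskVolume(arr))
        assert abs(s["shape_MeshVolume"] - 1000.0) / 1000.0 < 0.05

    def test_shape_ignores_intensity_shift(self, phantom_patient, pre_cfg, phantom_features):
        vol = clip_hu(phantom_patient.ct, pre_cfg)
        shifted = extract_all(CTVolume(np.clip(vol.values + 10, -125, 225),
                                       vol.spacing_mm), phantom_patient.mask, pre_cfg)
        shape_cols = [n for n in phantom_features.index if n.startswith("shape_")]
        pd.testing.assert_series_equal(phantom_features[shape_cols], shifted[shape_cols])
        assert shifted["original_firstorder_Mean"] != phantom_features["original_firstorder_Mean"]

    def test_tiny_mask_rejected(self):
        arr = np.zeros((5, 5, 5), np.uint8)
        arr[2, 2, 2] = 1
        with pytest.raises(ValueError, match="too small"):
            shape_features(MaskVolume(arr))


class TestFirstOrder:
    def test_hand_computed_moments(self):
        vals = np.array([0.0, 0.0, 4.0, 4.0])
        out = first_order_features(vals, np.array([1, 1, 2, 2]))
        names = list(zip(
            ("Energy", "Entropy", "Minimum", "Percentile10", "Percentile90",
             "Maximum", "Mean", "Median", "InterquartileRange", "Range",
             "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
             "RootMeanSquared", "StandardDeviation", "Skewness", "Kurtosis",
             "Variance", "Uniformity"), out))
        d = dict(names)
        assert d["Mean"] == 2.0
        assert d["Variance"] == 4.0
        assert d["Energy"] == 32.0
        assert d["Entropy"] == pytest.approx(1.0)   # two equally filled bins
        assert d["Uniformity"] == pytest.approx(0.5)
        assert len(out) == 18

    def test_constant_roi(self):
        out = first_order_features(np.full(20, 7.0), np.ones(20, dtype=int))
        assert out[16] == 0.0  # variance
        assert out[1] == 0.0   # entropy


class TestTextureOracles:
    def test_glcm_pair_counts_on_toy_grid(self):
        # 2 x 2 single-slice grid: [[1, 2], [1, 3]]
        arr = np.array([[[1], [2]], [[1], [3]]], dtype=np.int64)
        mats = _glcm_kernel(np.ascontiguousarray(arr), 3, _OFFSETS_13)
        along_rows = mats[1]  # offset (0, 1, 0): pairs (1,2) and (1,3)
        expected = np.zeros((3, 3))
        expected[0, 1] = expected[1, 0] = 1
        expected[0, 2] = expected[2, 0] = 1
        np.testing.assert_array_equal(along_rows, expected)
        along_cols = mats[2]  # offset (1, 0, 0): pairs (1,1) and (2,3)
        expected2 = np.zeros((3, 3))
        expected2[0, 0] = 2
        expected2[1, 2] = expected2[2, 1] = 1
        np.testing.assert_array_equal(along_cols, expected2)

    def test_glrlm_runs_on_striped_grid(self):
        # 4 x 4 single-slice grid striped along axis 1: row i is gray i+1
        arr = np.zeros((4, 4, 1), dtype=np.int64)
        for i in range(4):
            arr[i, :, 0] = i + 1
        mats = _glrlm_kernel(np.ascontiguousarray(arr), 4, _OFFSETS_13, 4)
        along = mats[1]   # (0,1,0): one run of length 4 per gray level
        across = mats[2]  # (1,0,0): four runs of length 1 per gray level... per column
        expected_along = np.zeros((4, 4))
        expected_along[:, 3] = 1
        np.testing.assert_array_equal(along, expected_along)
        expected_across = np.zeros((4, 4))
        expected_across[:, 0] = 4
        np.testing.assert_array_equal(across, expected_across)
        # long-run emphasis along stripes exceeds across stripes
        lre = GLRLM_NAMES.index("LongRunEmphasis")
        lre_along = _runzone_feats_nb(mats[1][None], 16, 1)[lre]
        lre_across = _runzone_feats_nb(mats[2][None], 16, 1)[lre]
        assert lre_along > lre_across

    def test_constant_roi_degenerate_glcm(self):
        vol = CTVolume(np.full((8, 8, 8), 50.0))
        arr = np.zeros((8, 8, 8), np.uint8)
        arr[1:7, 1:7, 1:7] = 1
        feats = extract_all(vol, MaskVolume(arr))
        assert feats["original_glcm_JointEntropy"] == 0.0
        assert feats["original_glcm_MaximumProbability"] == 1.0
        assert feats["original_glcm_JointEnergy"] == 1.0
        assert np.isfinite(feats).all()


def test_rotation_invariance_of_direction_averaged_texture(phantom_patient, pre_cfg,
                                                           phantom_features):
    """Rotating the volume 90 degrees in-plane changes direction-averaged
    texture features of the unfiltered image by at most 2%."""
    vol = clip_hu(phantom_patient.ct, pre_cfg)
    rot_vol = CTVolume(np.rot90(vol.values, axes=(1, 2)).copy(), vol.spacing_mm)
    rot_mask = MaskVolume(np.rot90(phantom_patient.mask.values, axes=(1, 2)).copy())
    rot = extract_all(rot_vol, rot_mask, pre_cfg)
    tex = [n for n in phantom_features.index
           if n.startswith("original_") and "firstorder" not in n]
    base = phantom_features[tex]
    denom = base.abs().clip(lower=1e-9)
    rel = (rot[tex] - base).abs() / denom
    assert rel.max() < 0.02, rel.sort_values().tail(3)


class TestHabitatAggregation:
    def test_label_permutation_invariance(self, phantom_patient, phantom_habitat, pre_cfg):
        vol = clip_hu(phantom_patient.ct, pre_cfg)
        base = extract_habitat_features(vol, phantom_habitat, pre_cfg)
        relabel = np.zeros_like(phantom_habitat.values)
        for old, new in ((1, 2), (2, 3), (3, 1)):
            relabel[phantom_habitat.values == old] = new
        permuted_map = HabitatMap(relabel, phantom_habitat.spacing_mm, 3)
        permuted = extract_habitat_features(vol, permuted_map, pre_cfg)
        assert (base - permuted).abs().max() == 0.0

    def test_small_subregions_excluded(self, phantom_patient, pre_cfg):
        vol = clip_hu(phantom_patient.ct, pre_cfg)
        mask = phantom_patient.mask
        coords = np.argwhere(mask.values == 1)
        labels = np.zeros_like(mask.values, dtype=np.int16)
        labels[mask.values == 1] = 1
        tiny = coords[:4]
        labels[tuple(tiny.T)] = 2  # 4-voxel subregion, below the default minimum
        hmap = HabitatMap(labels, mask.spacing_mm, 2)
        agg = extract_habitat_features(vol, hmap, pre_cfg)
        solo_mask = MaskVolume((labels == 1).astype(np.uint8), mask.spacing_mm)
        solo = extract_all(vol, solo_mask, pre_cfg)
        pd.testing.assert_series_equal(agg, solo)

    def test_all_subregions_too_small_raises(self, phantom_patient, pre_cfg):
        vol = clip_hu(phantom_patient.ct, pre_cfg)
        labels = np.zeros(vol.shape, dtype=np.int16)
        labels[10, 10, 10] = 1
        # a single-voxel map is not a valid habitat of the tumor, but the
        # aggregation guard should fire before anything else
        hmap = HabitatMap(labels, vol.spacing_mm, 1)
        with pytest.raises(ValueError, match="minimum voxel count"):
            extract_habitat_features(vol, hmap, pre_cfg)
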