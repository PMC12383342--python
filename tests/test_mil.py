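"""2.5D stacks, per-slice classifiers, and PLH / BoW multi-instance fusion."""

import numpy as np
import pandas as pd
import pytest

from habitatmil.mil import (
    DEFAULT_BACKBONES,
    SLICE_OFFSETS,
    BowModel,
    SlicePredictionMatrix,
    SliceStack,
    TinyConvNet,
    TrainConfig,
    bow_fit,
    build_stack,
    fit_slice_models,
    fuse_mil,
    plh_features,
    predict_matrix,
    select_central_slice,
)
from habitatmil.preprocess import CTVolume, MaskVolume


class TestCentralSlice:
    def test_argmax(self):
        arr = np.zeros((3, 6, 6), np.uint8)
        arr[0, :1, :3] = 1   # area 3
        arr[1, :2, :5] = 1   # area 10
        arr[2, :2, :2] = 1   # area 4
        assert select_central_slice(MaskVolume(arr)) == 1

    def test_tie_breaks_low(self):
        arr = np.zeros((3, 4, 4), np.uint8)
        arr[1, :2, :2] = 1
        arr[2, :2, :2] = 1
        assert select_central_slice(MaskVolume(arr)) == 1

    def test_sphere_equator(self, sphere_pair):
        _, mask = sphere_pair
        assert select_central_slice(mask) == 20

    def test_empty_mask(self):
        with pytest.raises(ValueError):
            select_central_slice(MaskVolume(np.zeros((3, 3, 3), np.uint8)))


class TestBuildStack:
    def _patient(self, seed=0, nz=24):
        rng = np.random.default_rng(seed)
        vol = CTVolume(rng.normal(40, 50, (nz, 40, 40)))
        arr = np.zeros((nz, 40, 40), np.uint8)
        arr[nz // 2 - 5:nz // 2 + 5, 12:30, 10:26] = 1
        return vol, MaskVolume(arr)

    def test_five_slices_in_range(self):
        vol, mask = self._patient()
        stack = build_stack(vol, mask)
        assert stack.slices.shape == (5, 224, 224)
        assert stack.slices.min() >= -1.0 and stack.slices.max() <= 1.0

    def test_minmax_attained_exactly(self):
        vol, mask = self._patient(1)
        stack = build_stack(vol, mask)
        for s in range(5):
            assert stack.slices[s].min() == pytest.approx(-1.0)
            assert stack.slices[s].max() == pytest.approx(1.0)

    def test_constant_slice_maps_to_zero(self):
        vol = CTVolume(np.full((10, 30, 30), 60.0))
        arr = np.zeros((10, 30, 30), np.uint8)
        arr[4:7, 10:20, 10:20] = 1
        stack = build_stack(vol, MaskVolume(arr))
        np.testing.assert_array_equal(stack.slices, 0.0)

    def test_edge_offsets_replaced_by_nearest_slice(self):
        rng = np.random.default_rng(2)
        vol = CTVolume(rng.normal(40, 50, (8, 30, 30)))
        arr = np.zeros((8, 30, 30), np.uint8)
        arr[6:8, 8:22, 8:22] = 1  # central slice near the top edge
        stack = build_stack(vol, MaskVolume(arr))
        central = select_central_slice(MaskVolume(arr))
        assert central + 4 > 7  # offsets overflow
        np.testing.assert_array_equal(stack.slices[3], stack.slices[4])

    def test_translation_consistency(self):
        vol, mask = self._patient(3, nz=30)
        stack = build_stack(vol, mask)
        shifted_vol = CTVolume(np.roll(vol.values, 2, axis=0), vol.spacing_mm)
        shifted_mask = MaskVolume(np.roll(mask.values, 2, axis=0), mask.spacing_mm)
        assert select_central_slice(shifted_mask) == select_central_slice(mask) + 2
        stack2 = build_stack(shifted_vol, shifted_mask)
        np.testing.assert_allclose(stack.slices, stack2.slices)


def _toy_stacks(n=40, seed=0):
    """Seeded stacks where positives carry a bright patch in every slice."""
    rng = np.random.default_rng(seed)
    labels = pd.Series((np.arange(n) % 2), index=[f"P{i}" for i in range(n)])
    stacks = {}
    for i in range(n):
        imgs = rng.normal(0, 0.2, size=(5, 224, 224))
        if labels.iloc[i] == 1:
            imgs[:, 70:150, 70:150] += 0.8
        stacks[f"P{i}"] = SliceStack(patient_id=f"P{i}", slices=np.clip(imgs, -1, 1))
    return stacks, labels


class TestSliceModels:
    def test_fifteen_instances_under_default_registry(self):
        stacks, labels = _toy_stacks(16)
        models = fit_slice_models(stacks, labels, seed=0)
        assert len(models) == 15
        assert {b for b, _ in models} == set(DEFAULT_BACKBONES)
        assert {o for _, o in models} == set(SLICE_OFFSETS)

    def test_unknown_backbone_raises(self):
        stacks, labels = _toy_stacks(8)
        with pytest.raises(KeyError, match="unknown"):
            fit_slice_models(stacks, labels, backbones=("densenet201",))

    def test_separable_data_trains_accurately(self):
        stacks, labels = _toy_stacks(60)
        X = np.stack([s.slices[2] for s in stacks.values()])
        y = labels.to_numpy()
        model = TinyConvNet(8, TrainConfig(seed=0)).fit(X, y)
        acc = ((model.predict_proba(X) >= 0.5) == y).mean()
        assert acc >= 0.95

    def test_seeded_determinism(self):
        stacks, labels = _toy_stacks(16)
        m1 = fit_slice_models(stacks, labels, backbones=("tinycnn-a",), seed=5)
        m2 = fit_slice_models(stacks, labels, backbones=("tinycnn-a",), seed=5)
        p1 = predict_matrix(m1, stacks).probs
        p2 = predict_matrix(m2, stacks).probs
        pd.testing.assert_frame_equal(p1, p2)

    def test_prediction_matrix_complete(self):
        stacks, labels = _toy_stacks(12)
        models = fit_slice_models(stacks, labels, seed=1)
        mat = predict_matrix(models, stacks)
        assert mat.probs.shape == (12, 15)
        assert mat.probs.notna().all().all()
        assert ((mat.probs.values >= 0) & (mat.probs.values <= 1)).all()
        np.testing.assert_array_equal(mat.labels.values, (mat.probs.values >= 0.5))

    def test_single_class_rejected(self):
        stacks, labels = _toy_stacks(8)
        with pytest.raises(ValueError, match="both classes"):
            fit_slice_models(stacks, labels * 0, seed=0)


def _matrix_from_probs(per_patient: dict, backbone="bb") -> SlicePredictionMatrix:
    cols = pd.MultiIndex.from_tuples(
        [(backbone, off) for off in SLICE_OFFSETS], names=["backbone", "offset"]
    )
    return SlicePredictionMatrix(
        pd.DataFrame([v for v in per_patient.values()],
                     index=list(per_patient), columns=cols)
    )


class TestPLH:
    def test_hand_binned_histogram(self):
        mat = _matrix_from_probs({"p1": [0.1, 0.2, 0.9, 0.85, 0.5]})
        out = plh_features(mat)
        hist = out.loc["p1", [f"mil_plh_bb_bin{i}" for i in range(1, 6)]].tolist()
        assert hist == [1, 1, 1, 0, 2]
        assert out.loc["p1", "mil_plh_bb_npos"] == 3

    def test_probability_one_in_top_bin(self):
        mat = _matrix_from_probs({"p1": [1.0] * 5})
        out = plh_features(mat)
        assert out.loc["p1", "mil_plh_bb_bin5"] == 5

    def test_counts_sum_to_five(self):
        rng = np.random.default_rng(0)
        mat = _matrix_from_probs({f"p{i}": rng.random(5) for i in range(7)})
        out = plh_features(mat)
        sums = out[[f"mil_plh_bb_bin{i}" for i in range(1, 6)]].sum(axis=1)
        assert (sums == 5).all()

    def test_invariant_to_slice_order(self):
        probs = [0.1, 0.7, 0.3, 0.9, 0.5]
        a = plh_features(_matrix_from_probs({"p": probs}))
        b = plh_features(_matrix_from_probs({"p": probs[::-1]}))
        pd.testing.assert_frame_equal(a, b)


class TestBoW:
    def test_hand_worked_tfidf(self):
        # doc1 tokens: decile-0 twice, decile-1 once; doc2: decile-1 three times
        mat = _matrix_from_probs({
            "d1": [0.05, 0.05, 0.15, 0.15, 0.15],
            "d2": [0.15, 0.15, 0.15, 0.15, 0.15],
        })
        bow = bow_fit(mat)
        table = bow.transform(mat)
        n, df_a = 2, 1
        idf_a = np.log((1 + n) / (1 + df_a)) + 1
        idf_b = np.log((1 + n) / (1 + 2)) + 1
        raw = np.array([2 * idf_a, 3 * idf_b])
        expected_a = raw[0] / np.linalg.norm(raw)
        assert table.loc["d1", "mil_bow_bb_d0"] == pytest.approx(expected_a)
        assert table.loc["d2", "mil_bow_bb_d0"] == 0.0
        assert table.loc["d1", "mil_bow_bb_d0"] > table.loc["d2", "mil_bow_bb_d0"]

    def test_row_norms_are_one(self):
        rng = np.random.default_rng(1)
        mat = _matrix_from_probs({f"p{i}": rng.random(5) for i in range(9)})
        table = bow_fit(mat).transform(mat)
        norms = np.linalg.norm(table.values, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-10)

    def test_matches_sklearn_tfidf(self):
        from sklearn.feature_extraction.text import TfidfTransformer

        rng = np.random.default_rng(2)
        mat = _matrix_from_probs({f"p{i}": rng.random(5) for i in range(12)})
        bow = bow_fit(mat)
        ours = bow.transform(mat)
        counts = BowModel._tokens(mat).reindex(columns=bow.vocabulary, fill_value=0.0)
        ref = TfidfTransformer(norm="l2", smooth_idf=True).fit_transform(counts.values)
        np.testing.assert_allclose(ours.values, ref.toarray(), atol=1e-12)

    def test_vocabulary_fit_on_training_only(self):
        train = _matrix_from_probs({"a": [0.05] * 5, "b": [0.15] * 5})
        test = _matrix_from_probs({"c": [0.95] * 5})
        bow = bow_fit(train)
        out = bow.transform(test)  # unseen token ignored, row of zeros
        assert (out.loc["c"] == 0).all()


def test_constant_stub_backbone_degenerates_gracefully():
    stacks, labels = _toy_stacks(10)
    models = fit_slice_models(stacks, labels, backbones=("constant",), seed=0)
    mat = predict_matrix(models, stacks)
    plh = plh_features(mat)
    hist_cols = [c for c in plh.columns if "bin" in c]
    assert (plh[hist_cols].sum(axis=1) == 5).all()
    assert (plh[[c for c in hist_cols if c.endswith("bin3")]] == 5).all().all()


def test_fuse_mil_contract():
    rng = np.random.default_rng(3)
    mat = _matrix_from_probs({f"p{i}": rng.random(5) for i in range(6)})
    plh = plh_features(mat)
    bow = bow_fit(mat).transform(mat)
    fused = fuse_mil(plh, bow)
    assert fused.shape[1] == plh.shape[1] + bow.shape[1]
    assert fused.columns.is_unique
    with pytest.raises(ValueError, match="different patients"):
        fuse_mil(plh.iloc[:3], bow)
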