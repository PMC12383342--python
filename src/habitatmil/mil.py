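"""2.5D slice stacks, per-slice classifiers, and multi-instance fusion.

A patient's tumor is represented by five axial slices: the slice with the
largest tumor cross-section plus the slices at +/-2 and +/-4 layers. Each
slice is cropped to the central-slice ROI bounding box (expanded 10% per
side to a square), HU-clipped, min-max normalized to [-1, 1] and resized to
224 x 224 with nearest-neighbor interpolation. Each (backbone, offset) pair
gets its own classifier trained with the patient label as a weak slice
label — with the default three-backbone registry this yields 15 slice-level
models and a 3 x 5 prediction grid per patient.

Slice outputs are fused into patient-level ("bag") features two ways:

* PLH — per backbone, a histogram of its five slice probabilities over
  equal-width bins on [0, 1] plus the count of positive hard labels;
* BoW — each patient is a document of (backbone, probability-decile)
  tokens from its 15 outcomes, encoded with TF-IDF
  (idf = ln((1+N)/(1+df)) + 1, rows L2-normalized, vocabulary fit on
  training patients only).

Backbones live behind a registry. The named ImageNet architectures of the
original transfer-learning setting are optional plug-ins; the default
reference backbone is a small seeded convolutional network (mean-pool to
28 x 28, one 3 x 3 convolution, global average pooling, logistic head)
trained with SGD on sigmoid cross-entropy under a cosine-decay learning
rate — the same trainer contract, at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import CTVolume, MaskVolume, PreprocessConfig

__all__ = [
    "SLICE_OFFSETS",
    "SliceStack",
    "TrainConfig",
    "SliceModel",
    "TinyConvNet",
    "BACKBONE_REGISTRY",
    "DEFAULT_BACKBONES",
    "select_central_slice",
    "build_stack",
    "fit_slice_models",
    "predict_matrix",
    "SlicePredictionMatrix",
    "plh_features",
    "BowModel",
    "bow_fit",
    "fuse_mil",
]

SLICE_OFFSETS = (-4, -2, 0, 2, 4)
TARGET_SIZE = 224


@dataclass(frozen=True)
class SliceStack:
    """Five preprocessed 2D slices in [-1, 1] at offsets -4..+4."""

    patient_id: str
    slices: np.ndarray  # (5, 224, 224)

    def __post_init__(self) -> None:
        if self.slices.shape != (len(SLICE_OFFSETS), TARGET_SIZE, TARGET_SIZE):
            raise ValueError(f"bad stack shape {self.slices.shape}")
        if self.slices.min() < -1.0 - 1e-9 or self.slices.max() > 1.0 + 1e-9:
            raise ValueError("slice values must lie in [-1, 1]")


def select_central_slice(mask: MaskVolume) -> int:
    """Index (axis 0) of the slice with the largest tumor cross-section;
    ties resolve to the lower index."""
    areas = mask.values.sum(axis=(1, 2))
    if areas.sum() == 0:
        raise ValueError("mask is empty")
    return int(np.argmax(areas))


def _nn_resize(img: np.ndarray, size: int) -> np.ndarray:
    src = [np.clip(np.floor((np.arange(size) + 0.5) * s / size).astype(int), 0, s - 1)
           for s in img.shape]
    return img[np.ix_(src[0], src[1])]


def build_stack(
    vol: CTVolume,
    mask: MaskVolume,
    central: int | None = None,
    pre_cfg: PreprocessConfig | None = None,
    patient_id: str = "",
) -> SliceStack:
    """Build the five-slice 2.5D stack for one patient.

    Offsets beyond the volume are replaced by the nearest valid slice. The
    crop window comes from the central-slice ROI only, so all five slices
    share the same spatial frame. A constant slice (degenerate min = max)
    maps to all zeros.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    mask.check_aligned(vol)
    if central is None:
        central = select_central_slice(mask)
    n_slices = vol.shape[0]

    roi = mask.values[central]
    if roi.sum() == 0:
        raise ValueError("central slice holds no tumor")
    rows = np.flatnonzero(roi.any(axis=1))
    cols = np.flatnonzero(roi.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    # expand 10% per side, then grow the shorter side to a square
    mr = max(int(round(0.1 * (r1 - r0))), 1)
    mc = max(int(round(0.1 * (c1 - c0))), 1)
    r0, r1 = r0 - mr, r1 + mr
    c0, c1 = c0 - mc, c1 + mc
    h, w = r1 - r0, c1 - c0
    if h < w:
        pad = w - h
        r0 -= pad // 2
        r1 += pad - pad // 2
    elif w < h:
        pad = h - w
        c0 -= pad // 2
        c1 += pad - pad // 2

    out = np.zeros((len(SLICE_OFFSETS), TARGET_SIZE, TARGET_SIZE))
    for s, off in enumerate(SLICE_OFFSETS):
        z = int(np.clip(central + off, 0, n_slices - 1))
        plane = vol.values[z]
        crop = np.full((r1 - r0, c1 - c0), pre_cfg.clip_lo_hu)
        rr0, rr1 = max(r0, 0), min(r1, plane.shape[0])
        cc0, cc1 = max(c0, 0), min(c1, plane.shape[1])
        crop[rr0 - r0:rr1 - r0, cc0 - c0:cc1 - c0] = plane[rr0:rr1, cc0:cc1]
        crop = np.clip(crop, pre_cfg.clip_lo_hu, pre_cfg.clip_hi_hu)
        lo, hi = crop.min(), crop.max()
        if hi > lo:
            crop = 2.0 * (crop - lo) / (hi - lo) - 1.0
        else:
            crop = np.zeros_like(crop)
        out[s] = _nn_resize(crop, TARGET_SIZE)
    return SliceStack(patient_id=patient_id, slices=out)


@dataclass(frozen=True)
class TrainConfig:
    """SGD + sigmoid cross-entropy + cosine-decay trainer settings."""

    epochs: int = 30
    learning_rate: float = 0.1
    batch_size: int = 32
    seed: int = 0


class SliceModel:
    """Interface for a binary per-slice classifier."""

    backbone_id: str = "abstract"

    def fit(self, images: np.ndarray, labels: np.ndarray) -> "SliceModel":
        raise NotImplementedError

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class TinyConvNet(SliceModel):
    """Reference convolutional backbone trainable on a CPU in seconds.

    Architecture: 8x8 mean pooling (224 -> 28), one 3x3 convolution with
    ``n_filters`` channels and ReLU, global average pooling, and a logistic
    output. Trained end-to-end with mini-batch SGD on sigmoid cross-entropy
    with a cosine-decay learning rate. All randomness is seeded.
    """

    def __init__(self, n_filters: int = 8, config: TrainConfig | None = None,
                 backbone_id: str = "tinycnn", conv_lr_scale: float = 784.0):
        self.n_filters = n_filters
        self.config = config or TrainConfig()
        self.backbone_id = backbone_id
        self.conv_lr_scale = conv_lr_scale
        self._fitted = False

    @staticmethod
    def _pool(images: np.ndarray) -> np.ndarray:
        n = images.shape[0]
        p = images.reshape(n, 28, 8, 28, 8).mean(axis=(2, 4))
        return p

    @staticmethod
    def _im2col(pooled: np.ndarray) -> np.ndarray:
        n = pooled.shape[0]
        padded = np.pad(pooled, ((0, 0), (1, 1), (1, 1)))
        cols = np.empty((n, 28 * 28, 9))
        k = 0
        for di in range(3):
            for dj in range(3):
                cols[:, :, k] = padded[:, di:di + 28, dj:dj + 28].reshape(n, -1)
                k += 1
        return cols

    def fit(self, images: np.ndarray, labels: np.ndarray) -> "TinyConvNet":
        y = np.asarray(labels, dtype=np.float64)
        if np.unique(y).size < 2:
            raise ValueError("need both classes to train")
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        F = self.n_filters
        self.W = rng.normal(0.0, np.sqrt(2.0 / 9.0), size=(9, F))
        self.b = np.zeros(F)
        self.v = rng.normal(0.0, np.sqrt(1.0 / F), size=F)
        self.c = 0.0

        cols = self._im2col(self._pool(images))
        n = cols.shape[0]
        total_steps = cfg.epochs * max(n // cfg.batch_size, 1)
        step = 0
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb, yb = cols[idx], y[idx]
                lr = cfg.learning_rate * 0.5 * (1.0 + np.cos(np.pi * step / total_steps))
                step += 1

                z = xb @ self.W + self.b           # (m, 784, F)
                a = np.maximum(z, 0.0)
                g = a.mean(axis=1)                 # (m, F)
                logit = g @ self.v + self.c
                p = 1.0 / (1.0 + np.exp(-logit))

                dlogit = (p - yb) / len(idx)
                dv = g.T @ dlogit
                dc = dlogit.sum()
                dg = np.outer(dlogit, self.v)
                # global average pooling scales conv gradients by 1/positions;
                # compensate with a per-layer learning-rate scale so the conv
                # filters train at the same speed as the head
                da = dg[:, None, :] / z.shape[1] * self.conv_lr_scale
                dz = da * (z > 0)
                dW = np.einsum("npk,npf->kf", xb, dz)
                db = dz.sum(axis=(0, 1))

                self.W -= lr * dW
                self.b -= lr * db
                self.v -= lr * dv
                self.c -= lr * dc
        self._fitted = True
        return self

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("model is not fitted")
        cols = self._im2col(self._pool(images))
        a = np.maximum(cols @ self.W + self.b, 0.0)
        logit = a.mean(axis=1) @ self.v + self.c
        return 1.0 / (1.0 + np.exp(-logit))


class ConstantModel(SliceModel):
    """Degenerate stub emitting a fixed probability (substitutability tests)."""

    def __init__(self, p: float = 0.5, backbone_id: str = "constant"):
        self.p = p
        self.backbone_id = backbone_id

    def fit(self, images, labels):
        return self

    def predict_proba(self, images):
        return np.full(images.shape[0], self.p)


BACKBONE_REGISTRY: dict[str, callable] = {
    "tinycnn-a": lambda seed: TinyConvNet(8, TrainConfig(seed=seed), "tinycnn-a"),
    "tinycnn-b": lambda seed: TinyConvNet(12, TrainConfig(seed=seed + 1000), "tinycnn-b"),
    "tinycnn-c": lambda seed: TinyConvNet(16, TrainConfig(seed=seed + 2000), "tinycnn-c"),
    "constant": lambda seed: ConstantModel(),
}
DEFAULT_BACKBONES = ("tinycnn-a", "tinycnn-b", "tinycnn-c")


@dataclass
class SlicePredictionMatrix:
    """Per-patient backbone x slice grid of probabilities.

    ``probs`` has a (backbone, offset) MultiIndex on columns; hard labels are
    1[prob >= 0.5].
    """

    probs: pd.DataFrame

    @property
    def labels(self) -> pd.DataFrame:
        return (self.probs >= 0.5).astype(int)

    @property
    def backbones(self) -> list[str]:
        return list(self.probs.columns.get_level_values(0).unique())


def fit_slice_models(
    stacks: dict[str, SliceStack],
    labels: pd.Series,
    backbones: tuple[str, ...] = DEFAULT_BACKBONES,
    seed: int = 0,
) -> dict[tuple[str, int], SliceModel]:
    """Train one model per (backbone, slice offset) under weak patient labels.

    With the default three-backbone registry this returns 15 fitted models.
    """
    unknown = [b for b in backbones if b not in BACKBONE_REGISTRY]
    if unknown:
        raise KeyError(f"unknown backbones {unknown}; registered: {sorted(BACKBONE_REGISTRY)}")
    ids = list(stacks.keys())
    y = labels.loc[ids].to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("need both classes among patients")
    models: dict[tuple[str, int], SliceModel] = {}
    for b_i, backbone in enumerate(backbones):
        for s_i, offset in enumerate(SLICE_OFFSETS):
            X = np.stack([stacks[pid].slices[s_i] for pid in ids])
            model = BACKBONE_REGISTRY[backbone](seed + 17 * b_i + 101 * s_i)
            models[(backbone, offset)] = model.fit(X, y)
    return models


def predict_matrix(
    models: dict[tuple[str, int], SliceModel], stacks: dict[str, SliceStack]
) -> SlicePredictionMatrix:
    ids = list(stacks.keys())
    cols = {}
    for (backbone, offset), model in models.items():
        s_i = SLICE_OFFSETS.index(offset)
        X = np.stack([stacks[pid].slices[s_i] for pid in ids])
        cols[(backbone, offset)] = model.predict_proba(X)
    probs = pd.DataFrame(cols, index=ids)
    probs.columns = pd.MultiIndex.from_tuples(probs.columns, names=["backbone", "offset"])
    return SlicePredictionMatrix(probs.sort_index(axis=1))


def plh_features(matrix: SlicePredictionMatrix, bins: int = 5) -> pd.DataFrame:
    """Predict-likelihood-histogram bag features.

    Per backbone: a histogram of its five slice probabilities over ``bins``
    equal-width bins on [0, 1] (half-open, closed at the top) plus the count
    of positive hard labels; concatenated across backbones.
    """
    out = {}
    for backbone in matrix.backbones:
        p = matrix.probs[backbone].to_numpy()
        idx = np.minimum((p * bins).astype(int), bins - 1)
        hist = np.stack([np.bincount(row, minlength=bins) for row in idx])
        for b in range(bins):
            out[f"mil_plh_{backbone}_bin{b + 1}"] = hist[:, b]
        out[f"mil_plh_{backbone}_npos"] = (p >= 0.5).sum(axis=1)
    return pd.DataFrame(out, index=matrix.probs.index).astype(float)


@dataclass
class BowModel:
    """TF-IDF encoder over (backbone, probability-decile) tokens.

    Vocabulary and document frequencies are fit on training patients only;
    idf = ln((1+N)/(1+df)) + 1 and rows are L2-normalized.
    """

    vocabulary: list[tuple[str, int]]
    idf: np.ndarray

    @staticmethod
    def _tokens(matrix: SlicePredictionMatrix) -> pd.DataFrame:
        probs = matrix.probs
        deciles = np.minimum((probs.to_numpy() * 10).astype(int), 9)
        backbone_of_col = probs.columns.get_level_values(0)
        rows = []
        for r in range(probs.shape[0]):
            counts: dict[tuple[str, int], int] = {}
            for c in range(probs.shape[1]):
                tok = (backbone_of_col[c], int(deciles[r, c]))
                counts[tok] = counts.get(tok, 0) + 1
            rows.append(counts)
        return pd.DataFrame(rows, index=probs.index).fillna(0.0)

    def transform(self, matrix: SlicePredictionMatrix) -> pd.DataFrame:
        tf = self._tokens(matrix).reindex(columns=self.vocabulary, fill_value=0.0)
        weighted = tf.to_numpy() * self.idf[None, :]
        norms = np.linalg.norm(weighted, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        weighted = weighted / norms
        cols = [f"mil_bow_{b}_d{d}" for b, d in self.vocabulary]
        return pd.DataFrame(weighted, index=matrix.probs.index, columns=cols)


def bow_fit(matrix: SlicePredictionMatrix) -> BowModel:
    """Fit the BoW vocabulary and idf weights on a training corpus."""
    tf = BowModel._tokens(matrix)
    if tf.shape[0] < 2:
        raise ValueError("BoW needs at least two training patients")
    vocab = sorted(tf.columns)
    df = (tf[vocab].to_numpy() > 0).sum(axis=0)
    n_docs = tf.shape[0]
    idf = np.log((1.0 + n_docs) / (1.0 + df)) + 1.0
    return BowModel(vocabulary=vocab, idf=idf)


def fuse_mil(plh: pd.DataFrame, bow: pd.DataFrame) -> pd.DataFrame:
    """Column-wise concatenation of PLH and BoW bag features."""
    if not plh.index.equals(bow.index):
        raise ValueError("PLH and BoW tables cover different patients")
    fused = pd.concat([plh, bow], axis=1)
    if fused.columns.duplicated().any():
        raise ValueError("duplicate feature names after namespacing")
    fused.attrs["provenance"] = "MIL"
    return fused
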