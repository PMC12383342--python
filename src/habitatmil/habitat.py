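"""Tumor habitat delineation: local voxel features + per-patient K-means.

Each tumor voxel is described by the 19 first-order statistics of its
3x3x3 in-mask neighborhood; K-means (default k=3) on these standardized
vectors partitions the tumor into habitats — subregions of coherent local
intensity/texture such as necrotic cores or enhancing rims. Clustering is
per patient: cluster identities are not comparable across patients, which is
exactly why downstream habitat features are averaged over subregions.

Cluster labels are renumbered by ascending mean of the neighborhood-mean
channel (darkest habitat = 1) so maps are reproducible even though K-means
label order is arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from .preprocess import CTVolume, MaskVolume, PreprocessConfig, discretize

__all__ = [
    "HabitatConfig",
    "VoxelFeatureMap",
    "HabitatMap",
    "LOCAL_FEATURE_NAMES",
    "local_voxel_features",
    "cluster_habitats",
    "habitat_masks",
    "delineate_habitats",
]

#: the 19 neighborhood first-order statistics, in output channel order
LOCAL_FEATURE_NAMES = (
    "energy", "total_energy", "entropy", "minimum", "percentile10",
    "percentile90", "maximum", "mean", "median", "interquartile_range",
    "range", "mean_absolute_deviation", "robust_mean_absolute_deviation",
    "root_mean_squared", "standard_deviation", "skewness", "kurtosis",
    "variance", "uniformity",
)


@dataclass(frozen=True)
class HabitatConfig:
    window_edge: int = 3
    k: int = 3
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.window_edge < 3 or self.window_edge % 2 == 0:
            raise ValueError("window_edge must be odd and >= 3")
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass(frozen=True)
class VoxelFeatureMap:
    """Per-voxel feature vectors over the mask (n_voxels x 19)."""

    coords: np.ndarray        # (n, 3) voxel indices
    values: np.ndarray        # (n, 19), NaN rows flagged invalid
    valid: np.ndarray         # (n,) bool; False where neighborhood had < 2 voxels
    channel_names: tuple[str, ...]
    grid_shape: tuple[int, int, int]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class HabitatMap:
    """Integer label grid: 0 outside the tumor, 1..k inside."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    k: int

    def __post_init__(self) -> None:
        labels = np.unique(self.values[self.values > 0])
        if labels.size and (labels.min() < 1 or labels.max() > self.k):
            raise ValueError(f"habitat labels must lie in 1..{self.k}")

    @property
    def labels_present(self) -> np.ndarray:
        return np.unique(self.values[self.values > 0])


@njit(cache=True)
def _percentile(sorted_buf, n, q):
    # linear-interpolation percentile, matching numpy's default
    pos = q / 100.0 * (n - 1)
    lo = int(np.floor(pos))
    hi = lo + 1 if lo + 1 < n else lo
    frac = pos - lo
    return sorted_buf[lo] * (1.0 - frac) + sorted_buf[hi] * frac


@njit(cache=True)
def _local_stats_kernel(vol, binned, mask, coords, radius, voxel_volume, out, valid):
    n = coords.shape[0]
    buf = np.empty(343, dtype=np.float64)   # supports window_edge up to 7
    ibuf = np.empty(343, dtype=np.int64)
    for idx in range(n):
        x, y, z = coords[idx, 0], coords[idx, 1], coords[idx, 2]
        m = 0
        for dx in range(-radius, radius + 1):
            xx = x + dx
            if xx < 0 or xx >= vol.shape[0]:
                continue
            for dy in range(-radius, radius + 1):
                yy = y + dy
                if yy < 0 or yy >= vol.shape[1]:
                    continue
                for dz in range(-radius, radius + 1):
                    zz = z + dz
                    if zz < 0 or zz >= vol.shape[2]:
                        continue
                    if mask[xx, yy, zz] == 1:
                        buf[m] = vol[xx, yy, zz]
                        ibuf[m] = binned[xx, yy, zz]
                        m += 1
        if m < 2:
            valid[idx] = False
            for c in range(19):
                out[idx, c] = np.nan
            continue
        valid[idx] = True
        vals = np.sort(buf[:m])
        mean = 0.0
        energy = 0.0
        for i in range(m):
            mean += vals[i]
            energy += vals[i] * vals[i]
        mean /= m
        var = 0.0
        m3 = 0.0
        m4 = 0.0
        mad = 0.0
        for i in range(m):
            d = vals[i] - mean
            var += d * d
            m3 += d * d * d
            m4 += d * d * d * d
            mad += abs(d)
        var /= m
        m3 /= m
        m4 /= m
        mad /= m
        sd = np.sqrt(var)
        skew = m3 / (sd * sd * sd) if sd > 0 else 0.0
        kurt = m4 / (var * var) if var > 0 else 0.0
        p10 = _percentile(vals, m, 10.0)
        p25 = _percentile(vals, m, 25.0)
        p50 = _percentile(vals, m, 50.0)
        p75 = _percentile(vals, m, 75.0)
        p90 = _percentile(vals, m, 90.0)
        # robust MAD: values within [p10, p90], deviation from their own mean
        rn = 0
        rsum = 0.0
        for i in range(m):
            if p10 <= vals[i] <= p90:
                rsum += vals[i]
                rn += 1
        rmad = 0.0
        if rn > 0:
            rmean = rsum / rn
            for i in range(m):
                if p10 <= vals[i] <= p90:
                    rmad += abs(vals[i] - rmean)
            rmad /= rn
        # discrete entropy / uniformity over the binned neighborhood values
        ivals = np.sort(ibuf[:m])
        entropy = 0.0
        uniformity = 0.0
        i = 0
        while i < m:
            j = i
            while j < m and ivals[j] == ivals[i]:
                j += 1
            p = (j - i) / m
            entropy -= p * np.log2(p)
            uniformity += p * p
            i = j
        out[idx, 0] = energy
        out[idx, 1] = energy * voxel_volume
        out[idx, 2] = entropy
        out[idx, 3] = vals[0]
        out[idx, 4] = p10
        out[idx, 5] = p90
        out[idx, 6] = vals[m - 1]
        out[idx, 7] = mean
        out[idx, 8] = p50
        out[idx, 9] = p75 - p25
        out[idx, 10] = vals[m - 1] - vals[0]
        out[idx, 11] = mad
        out[idx, 12] = rmad
        out[idx, 13] = np.sqrt(energy / m)
        out[idx, 14] = sd
        out[idx, 15] = skew
        out[idx, 16] = kurt
        out[idx, 17] = var
        out[idx, 18] = uniformity


def local_voxel_features(
    vol: CTVolume,
    mask: MaskVolume,
    cfg: HabitatConfig | None = None,
    pre_cfg: PreprocessConfig | None = None,
) -> VoxelFeatureMap:
    """The 19 first-order statistics of each voxel's in-mask neighborhood.

    The window (default 3x3x3) is restricted to in-mask voxels so habitat
    boundaries are not blurred by background. Entropy and uniformity are
    computed on the fixed-bin-width discretized values for consistency with
    the global discretization. Voxels whose neighborhood holds fewer than two
    in-mask voxels are flagged invalid and later assigned to the nearest
    cluster.
    """
    cfg = cfg or HabitatConfig()
    pre_cfg = pre_cfg or PreprocessConfig()
    mask.check_aligned(vol)
    coords = np.argwhere(mask.values == 1)
    if coords.shape[0] == 0:
        raise ValueError("mask is empty")
    binned, _ = discretize(vol, mask, pre_cfg)
    out = np.empty((coords.shape[0], 19), dtype=np.float64)
    valid = np.empty(coords.shape[0], dtype=np.bool_)
    _local_stats_kernel(
        vol.values, binned, mask.values, coords.astype(np.int64),
        cfg.window_edge // 2, vol.voxel_volume_mm3, out, valid,
    )
    return VoxelFeatureMap(coords, out, valid, LOCAL_FEATURE_NAMES, vol.shape)


def cluster_habitats(
    features: VoxelFeatureMap,
    cfg: HabitatConfig | None = None,
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> HabitatMap:
    """K-means partition of the tumor into ``k`` habitats.

    Channels are z-scored (population SD) when ``cfg.standardize`` is set;
    k-means++ initialization is seeded for reproducibility, and final labels
    are ordered by ascending cluster mean of the neighborhood-mean channel.
    """
    cfg = cfg or HabitatConfig()
    X = features.values[features.valid]
    coords_valid = features.coords[features.valid]
    if X.shape[0] < cfg.k:
        raise ValueError(f"need at least k={cfg.k} voxels with valid features")
    if np.unique(X, axis=0).shape[0] < cfg.k:
        raise ValueError("fewer distinct feature vectors than clusters")

    if cfg.standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X - mu) / sd
    else:
        Xs = X

    km = KMeans(n_clusters=cfg.k, init="k-means++", n_init=10, random_state=cfg.seed)
    raw = km.fit_predict(Xs)

    mean_channel = features.channel_names.index("mean")
    order = np.argsort(
        [X[raw == c, mean_channel].mean() if (raw == c).any() else np.inf
         for c in range(cfg.k)]
    )
    relabel = np.empty(cfg.k, dtype=np.int64)
    relabel[order] = np.arange(1, cfg.k + 1)
    labels = relabel[raw]

    grid = np.zeros(features.grid_shape, dtype=np.int16)
    grid[tuple(coords_valid.T)] = labels

    # invalid voxels inherit the label of the nearest labeled voxel
    if (~features.valid).any():
        tree = cKDTree(coords_valid)
        coords_bad = features.coords[~features.valid]
        _, nearest = tree.query(coords_bad)
        grid[tuple(coords_bad.T)] = labels[nearest]

    return HabitatMap(grid, spacing_mm, cfg.k)


def habitat_masks(h: HabitatMap) -> list[MaskVolume]:
    """One binary mask per habitat label; masks partition the tumor exactly."""
    return [
        MaskVolume((h.values == lbl).astype(np.uint8), h.spacing_mm)
        for lbl in range(1, h.k + 1)
    ]


def delineate_habitats(
    vol: CTVolume,
    mask: MaskVolume,
    cfg: HabitatConfig | None = None,
    pre_cfg: PreprocessConfig | None = None,
) -> HabitatMap:
    """Convenience: local features + clustering in one call."""
    feats = local_voxel_features(vol, mask, cfg, pre_cfg)
    return cluster_habitats(feats, cfg, vol.spacing_mm)
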