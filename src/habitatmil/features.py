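"""Handcrafted radiomic feature bank: 14 geometry + 360 intensity + 1460 texture.

The bank follows the standard radiomics taxonomy. A fixed filter bank of 20
derived images (original, 8 stationary-wavelet sub-bands, Laplacian-of-
Gaussian at sigma 1..6 mm, square, square-root, logarithm, exponential and
gradient-magnitude) feeds 18 first-order statistics and 73 texture-matrix
statistics per image; 3D shape is computed once from the mask, since
intensity filters cannot change geometry. Totals: 14 + 20*18 + 20*73 = 1834.

Texture matrices (GLCM, GLRLM, GLSZM, GLDM, NGTDM) are built by numba
kernels on the ROI bounding box; GLCM and GLRLM features are computed per
direction over the 13 unique 3D offsets and averaged, which makes them
invariant to axis-aligned rotations. Gray levels use the fixed 5-HU bin
width on the original image and a fixed 32-bin min-max quantization on
derived images whose range is no longer in HU.

Two extraction modes mirror the study design: the whole-tumor ROI
("intra") and the subregion-mean over a habitat map ("habitat"), where the
feature-wise arithmetic mean over subregions removes the arbitrariness of
cluster label order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pywt
from numba import njit
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

from .habitat import HabitatMap, habitat_masks
from .preprocess import CTVolume, MaskVolume, PreprocessConfig

__all__ = [
    "FILTER_NAMES",
    "SHAPE_NAMES",
    "FIRST_ORDER_NAMES",
    "TEXTURE_NAMES",
    "filter_bank_images",
    "shape_features",
    "first_order_features",
    "texture_features",
    "extract_all",
    "extract_multi",
    "extract_habitat_features",
    "subregion_mean",
    "feature_names",
    "feature_metadata",
    "cohort_feature_table",
]

DERIVED_BIN_COUNT = 32
LOG_SIGMAS_MM = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)

_WAVELET_KEYS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
FILTER_NAMES = (
    ("original",)
    + tuple(f"wavelet-{k}" for k in _WAVELET_KEYS)
    + tuple(f"log-sigma-{int(s)}mm" for s in LOG_SIGMAS_MM)
    + ("square", "squareroot", "logarithm", "exponential", "gradient")
)

SHAPE_NAMES = (
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Maximum3DDiameter", "Maximum2DDiameterSlice",
    "Maximum2DDiameterRow", "Maximum2DDiameterColumn", "MajorAxisLength",
    "MinorAxisLength", "LeastAxisLength", "Elongation", "Flatness",
)

#: the standard 19 first-order statistics minus TotalEnergy (a voxel-count
#: scaled duplicate of Energy), giving 18 per derived image
FIRST_ORDER_NAMES = (
    "Energy", "Entropy", "Minimum", "Percentile10", "Percentile90", "Maximum",
    "Mean", "Median", "InterquartileRange", "Range", "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation", "RootMeanSquared", "StandardDeviation",
    "Skewness", "Kurtosis", "Variance", "Uniformity",
)

# GLCM: 24 standard measures minus the two that are deterministic functions
# of others (SumAverage = 2*JointAverage; Dissimilarity = DifferenceAverage)
GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumEntropy", "SumSquares",
)
GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)
GLSZM_NAMES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)
GLDM_NAMES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)
NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")
TEXTURE_NAMES = {
    "glcm": GLCM_NAMES, "glrlm": GLRLM_NAMES, "glszm": GLSZM_NAMES,
    "gldm": GLDM_NAMES, "ngtdm": NGTDM_NAMES,
}

_OFFSETS_13 = np.array(
    [
        (0, 0, 1), (0, 1, 0), (1, 0, 0),
        (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ],
    dtype=np.int64,
)
_OFFSETS_26 = np.array(
    [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
     if (dx, dy, dz) != (0, 0, 0)],
    dtype=np.int64,
)

_EPS = np.spacing(1.0)


# ---------------------------------------------------------------------------
# Filter bank
# ---------------------------------------------------------------------------

def filter_bank_images(
    values: np.ndarray,
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    clip_lo: float = -125.0,
) -> dict[str, np.ndarray]:
    """The 20 derived images of the filter bank, all on the input grid.

    ``values`` is assumed HU-clipped, so ``values - clip_lo`` is non-negative
    and the monotone transforms (square root, logarithm, ...) are defined.
    """
    out: dict[str, np.ndarray] = {"original": values}

    # stationary wavelet sub-bands (coif1, level 1); pad axes to even length
    pads = [(0, s % 2) for s in values.shape]
    padded = np.pad(values, pads, mode="edge")
    coeffs = pywt.swtn(padded, "coif1", level=1)[0]
    sl = tuple(slice(0, s) for s in values.shape)
    for key in _WAVELET_KEYS:
        pywt_key = key.replace("L", "a").replace("H", "d")
        out[f"wavelet-{key}"] = coeffs[pywt_key][sl]

    # scale-normalized Laplacian of Gaussian (sigma in mm)
    for sigma in LOG_SIGMAS_MM:
        sig_vox = [sigma / s for s in spacing_mm]
        out[f"log-sigma-{int(sigma)}mm"] = sigma ** 2 * ndimage.gaussian_laplace(
            values, sig_vox, truncate=2.0
        )

    shifted = values - clip_lo
    out["square"] = shifted ** 2
    out["squareroot"] = np.sqrt(shifted)
    out["logarithm"] = np.log1p(shifted)
    out["exponential"] = np.exp(shifted / 100.0)
    grads = np.gradient(values, *spacing_mm)
    out["gradient"] = np.sqrt(sum(g ** 2 for g in grads))
    return out


def _bin_region(region_values: np.ndarray, is_original: bool, cfg: PreprocessConfig):
    """Gray-level quantization of ROI values -> (bin indices 1..ng, ng)."""
    if is_original:
        idx = np.floor((region_values - cfg.clip_lo_hu) / cfg.bin_width_hu).astype(np.int64) + 1
        return np.clip(idx, 1, cfg.bin_count), cfg.bin_count
    lo, hi = float(region_values.min()), float(region_values.max())
    if hi <= lo:
        return np.ones(region_values.shape, dtype=np.int64), 1
    width = (hi - lo) / DERIVED_BIN_COUNT
    idx = np.floor((region_values - lo) / width).astype(np.int64) + 1
    return np.clip(idx, 1, DERIVED_BIN_COUNT), DERIVED_BIN_COUNT


# ---------------------------------------------------------------------------
# Shape (14)
# ---------------------------------------------------------------------------

def _max_pairwise(points: np.ndarray) -> float:
    if points.shape[0] < 2:
        return 0.0
    if points.shape[0] > 10:
        try:
            points = points[ConvexHull(points, qhull_options="QJ").vertices]
        except Exception:
            pass
    return float(pdist(points).max())


def shape_features(mask: MaskVolume) -> pd.Series:
    """The 14 standard 3D shape descriptors of a binary ROI."""
    arr = mask.values.astype(bool)
    n_vox = int(arr.sum())
    if n_vox < 8:
        raise ValueError(f"mask too small for shape analysis ({n_vox} voxels)")
    spacing = np.asarray(mask.spacing_mm)

    # light smoothing before meshing removes the voxel staircase, which
    # otherwise inflates the surface-area estimate by ~8%
    padded = ndimage.gaussian_filter(np.pad(arr.astype(np.float64), 2), 0.6)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    tri = verts[faces]
    mesh_volume = float(abs(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)
    surface_area = float(measure.mesh_surface_area(verts, faces))
    voxel_volume = n_vox * float(np.prod(spacing))
    sphericity = (36.0 * np.pi * mesh_volume ** 2) ** (1.0 / 3.0) / surface_area

    boundary = arr & ~ndimage.binary_erosion(arr)
    bcoords = np.argwhere(boundary) * spacing
    max3d = _max_pairwise(bcoords)
    bidx = np.argwhere(boundary)
    max2d = []
    for axis in range(3):
        keep = [a for a in range(3) if a != axis]
        best = 0.0
        for level in np.unique(bidx[:, axis]):
            pts = bidx[bidx[:, axis] == level][:, keep] * spacing[keep]
            if pts.shape[0] >= 2:
                best = max(best, _max_pairwise(pts))
        max2d.append(best)

    coords = np.argwhere(arr) * spacing
    cov = np.cov(coords.T)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0

    vals = [
        mesh_volume, voxel_volume, surface_area, surface_area / mesh_volume,
        sphericity, max3d, max2d[0], max2d[1], max2d[2],
        major, minor, least, elongation, flatness,
    ]
    return pd.Series(vals, index=[f"shape_{n}" for n in SHAPE_NAMES])


# ---------------------------------------------------------------------------
# First order (18 per derived image)
# ---------------------------------------------------------------------------

def first_order_features(region_values: np.ndarray, binned: np.ndarray) -> np.ndarray:
    """18 first-order statistics of ROI voxel values.

    Entropy and Uniformity are computed on the quantized gray levels; all
    moments are population moments and Kurtosis is non-excess.
    """
    x = np.asarray(region_values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty ROI")
    n = x.size
    mean = x.mean()
    var = x.var()
    sd = np.sqrt(var)
    energy = float((x ** 2).sum())
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    skew = float(((x - mean) ** 3).mean() / sd ** 3) if sd > 0 else 0.0
    kurt = float(((x - mean) ** 4).mean() / var ** 2) if var > 0 else 0.0
    counts = np.bincount(binned.ravel())[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p ** 2).sum())
    return np.array([
        energy, entropy, float(x.min()), p10, p90, float(x.max()), mean, p50,
        p75 - p25, float(x.max() - x.min()),
        float(np.abs(x - mean).mean()), rmad, float(np.sqrt(energy / n)),
        float(sd), skew, kurt, float(var), uniformity,
    ])


# ---------------------------------------------------------------------------
# Texture matrices (numba kernels on the ROI bounding box; 0 = outside ROI)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _glcm_kernel(arr, ng, offsets):
    out = np.zeros((offsets.shape[0], ng, ng), dtype=np.float64)
    nx, ny, nz = arr.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                i = arr[x, y, z]
                if i == 0:
                    continue
                for d in range(offsets.shape[0]):
                    xx = x + offsets[d, 0]
                    yy = y + offsets[d, 1]
                    zz = z + offsets[d, 2]
                    if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz:
                        j = arr[xx, yy, zz]
                        if j != 0:
                            out[d, i - 1, j - 1] += 1.0
                            out[d, j - 1, i - 1] += 1.0
    return out


@njit(cache=True)
def _glrlm_kernel(arr, ng, offsets, max_run):
    out = np.zeros((offsets.shape[0], ng, max_run), dtype=np.float64)
    nx, ny, nz = arr.shape
    for d in range(offsets.shape[0]):
        dx, dy, dz = offsets[d, 0], offsets[d, 1], offsets[d, 2]
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    g = arr[x, y, z]
                    if g == 0:
                        continue
                    px, py, pz = x - dx, y - dy, z - dz
                    if 0 <= px < nx and 0 <= py < ny and 0 <= pz < nz and arr[px, py, pz] == g:
                        continue  # not a run start
                    run = 1
                    cx, cy, cz = x + dx, y + dy, z + dz
                    while 0 <= cx < nx and 0 <= cy < ny and 0 <= cz < nz and arr[cx, cy, cz] == g:
                        run += 1
                        cx += dx
                        cy += dy
                        cz += dz
                    out[d, g - 1, run - 1] += 1.0
    return out


@njit(cache=True)
def _glszm_kernel(arr, offsets26):
    nx, ny, nz = arr.shape
    visited = np.zeros(arr.shape, dtype=np.uint8)
    n = nx * ny * nz
    stack = np.empty((n, 3), dtype=np.int64)
    zone_gray = np.empty(n, dtype=np.int64)
    zone_size = np.empty(n, dtype=np.int64)
    nz_count = 0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                g = arr[x, y, z]
                if g == 0 or visited[x, y, z] == 1:
                    continue
                top = 0
                stack[top, 0], stack[top, 1], stack[top, 2] = x, y, z
                top += 1
                visited[x, y, z] = 1
                size = 0
                while top > 0:
                    top -= 1
                    cx, cy, cz = stack[top, 0], stack[top, 1], stack[top, 2]
                    size += 1
                    for k in range(offsets26.shape[0]):
                        xx = cx + offsets26[k, 0]
                        yy = cy + offsets26[k, 1]
                        zz = cz + offsets26[k, 2]
                        if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz:
                            if visited[xx, yy, zz] == 0 and arr[xx, yy, zz] == g:
                                visited[xx, yy, zz] = 1
                                stack[top, 0], stack[top, 1], stack[top, 2] = xx, yy, zz
                                top += 1
                zone_gray[nz_count] = g
                zone_size[nz_count] = size
                nz_count += 1
    return zone_gray[:nz_count], zone_size[:nz_count]


@njit(cache=True)
def _gldm_kernel(arr, ng, offsets26):
    # dependence = 1 + number of 26-neighbors in the ROI with the same gray level
    out = np.zeros((ng, 28), dtype=np.float64)
    nx, ny, nz = arr.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                g = arr[x, y, z]
                if g == 0:
                    continue
                dep = 1
                for k in range(offsets26.shape[0]):
                    xx = x + offsets26[k, 0]
                    yy = y + offsets26[k, 1]
                    zz = z + offsets26[k, 2]
                    if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz:
                        if arr[xx, yy, zz] == g:
                            dep += 1
                out[g - 1, dep - 1] += 1.0
    return out


@njit(cache=True)
def _ngtdm_kernel(arr, ng, offsets26):
    s = np.zeros(ng, dtype=np.float64)
    cnt = np.zeros(ng, dtype=np.float64)
    nx, ny, nz = arr.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                g = arr[x, y, z]
                if g == 0:
                    continue
                total = 0.0
                m = 0
                for k in range(offsets26.shape[0]):
                    xx = x + offsets26[k, 0]
                    yy = y + offsets26[k, 1]
                    zz = z + offsets26[k, 2]
                    if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz:
                        if arr[xx, yy, zz] != 0:
                            total += arr[xx, yy, zz]
                            m += 1
                if m > 0:
                    s[g - 1] += abs(g - total / m)
                cnt[g - 1] += 1.0
    return s, cnt


# ---------------------------------------------------------------------------
# Texture features from the matrices
# ---------------------------------------------------------------------------

@njit(cache=True)
def _glcm_feats_nb(mats, g_lo, ng_norm):
    """22 GLCM features averaged over the direction stack (numba).

    ``mats`` is (D, span, span) over gray values g_lo .. g_lo+span-1.
    """
    D, span = mats.shape[0], mats.shape[1]
    acc = np.zeros(22)
    n_used = 0
    px = np.empty(span)
    p_diff = np.empty(span)
    p_sum = np.empty(2 * span - 1)
    log2 = np.log(2.0)
    for d in range(D):
        total = 0.0
        for i in range(span):
            for j in range(span):
                total += mats[d, i, j]
        if total <= 0.0:
            continue
        n_used += 1
        for i in range(span):
            s = 0.0
            for j in range(span):
                s += mats[d, i, j]
            px[i] = s / total
        mu = 0.0
        for i in range(span):
            mu += (g_lo + i) * px[i]
        sigma2 = 0.0
        hx = 0.0
        for i in range(span):
            sigma2 += (g_lo + i - mu) ** 2 * px[i]
            if px[i] > 0:
                hx -= px[i] * np.log(px[i]) / log2
        for k in range(span):
            p_diff[k] = 0.0
        for k in range(2 * span - 1):
            p_sum[k] = 0.0
        autocorr = 0.0
        contrast = 0.0
        ct2 = 0.0
        ct3 = 0.0
        ct4 = 0.0
        joint_energy = 0.0
        joint_entropy = 0.0
        idm = 0.0
        idmn = 0.0
        id_ = 0.0
        idn = 0.0
        inv_var = 0.0
        max_prob = 0.0
        sum_sq = 0.0
        hxy1 = 0.0
        hxy2 = 0.0
        for i in range(span):
            iv = float(g_lo + i)
            for j in range(span):
                jv = float(g_lo + j)
                q = px[i] * px[j]
                if q > 0:
                    lq = np.log(q) / log2
                    hxy2 -= q * lq
                p = mats[d, i, j] / total
                if p == 0.0 and q == 0.0:
                    continue
                diff = iv - jv
                adiff = abs(diff)
                if p > 0.0:
                    autocorr += iv * jv * p
                    contrast += diff * diff * p
                    csh = iv + jv - 2.0 * mu
                    ct2 += csh * csh * p
                    ct3 += csh * csh * csh * p
                    ct4 += csh * csh * csh * csh * p
                    joint_energy += p * p
                    lp = np.log(p) / log2
                    joint_entropy -= p * lp
                    if q > 0:
                        hxy1 -= p * (np.log(q) / log2)
                    idm += p / (1.0 + diff * diff)
                    idmn += p / (1.0 + (diff / ng_norm) ** 2)
                    id_ += p / (1.0 + adiff)
                    idn += p / (1.0 + adiff / ng_norm)
                    if adiff > 0:
                        inv_var += p / (adiff * adiff)
                    if p > max_prob:
                        max_prob = p
                    sum_sq += (iv - mu) ** 2 * p
                    p_diff[int(adiff)] += p
                    p_sum[i + j] += p
        diff_avg = 0.0
        for k in range(span):
            diff_avg += k * p_diff[k]
        diff_ent = 0.0
        diff_var = 0.0
        for k in range(span):
            if p_diff[k] > 0:
                diff_ent -= p_diff[k] * np.log(p_diff[k]) / log2
            diff_var += (k - diff_avg) ** 2 * p_diff[k]
        sum_ent = 0.0
        for k in range(2 * span - 1):
            if p_sum[k] > 0:
                sum_ent -= p_sum[k] * np.log(p_sum[k]) / log2
        if sigma2 > 0:
            correlation = (autocorr - mu * mu) / sigma2
        else:
            correlation = 1.0
        if hx > 0:
            imc1 = (joint_entropy - hxy1) / hx
        else:
            imc1 = 0.0
        arg = 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy))
        if arg < 0.0:
            arg = 0.0
        imc2 = np.sqrt(arg)
        acc[0] += autocorr
        acc[1] += mu
        acc[2] += ct4
        acc[3] += ct3
        acc[4] += ct2
        acc[5] += contrast
        acc[6] += correlation
        acc[7] += diff_avg
        acc[8] += diff_ent
        acc[9] += diff_var
        acc[10] += joint_energy
        acc[11] += joint_entropy
        acc[12] += imc1
        acc[13] += imc2
        acc[14] += idm
        acc[15] += idmn
        acc[16] += id_
        acc[17] += idn
        acc[18] += inv_var
        acc[19] += max_prob
        acc[20] += sum_ent
        acc[21] += sum_sq
    return acc / n_used


@njit(cache=True)
def _runzone_feats_nb(mats, n_vox, g_lo):
    """16 run-length/size-zone features averaged over the stack (numba)."""
    D, span, nl = mats.shape[0], mats.shape[1], mats.shape[2]
    acc = np.zeros(16)
    n_used = 0
    log2 = np.log(2.0)
    for d in range(D):
        nr = 0.0
        for i in range(span):
            for j in range(nl):
                nr += mats[d, i, j]
        if nr <= 0.0:
            continue
        n_used += 1
        mu_i = 0.0
        mu_j = 0.0
        for i in range(span):
            for j in range(nl):
                p = mats[d, i, j] / nr
                mu_i += (g_lo + i) * p
                mu_j += (j + 1) * p
        sre = 0.0
        lre = 0.0
        gln = 0.0
        rln = 0.0
        glv = 0.0
        rv = 0.0
        re = 0.0
        lgl = 0.0
        hgl = 0.0
        srl = 0.0
        srh = 0.0
        lrl = 0.0
        lrh = 0.0
        for i in range(span):
            iv = float(g_lo + i)
            i2 = iv * iv
            row = 0.0
            for j in range(nl):
                P = mats[d, i, j]
                row += P
                if P == 0.0:
                    continue
                jv = float(j + 1)
                j2 = jv * jv
                p = P / nr
                sre += P / j2
                lre += P * j2
                glv += (iv - mu_i) ** 2 * p
                rv += (jv - mu_j) ** 2 * p
                re -= p * np.log(p) / log2
                lgl += P / i2
                hgl += P * i2
                srl += P / (i2 * j2)
                srh += P * i2 / j2
                lrl += P * j2 / i2
                lrh += P * i2 * j2
            gln += row * row
        for j in range(nl):
            col = 0.0
            for i in range(span):
                col += mats[d, i, j]
            rln += col * col
        acc[0] += sre / nr
        acc[1] += lre / nr
        acc[2] += gln / nr
        acc[3] += gln / (nr * nr)
        acc[4] += rln / nr
        acc[5] += rln / (nr * nr)
        acc[6] += nr / n_vox
        acc[7] += glv
        acc[8] += rv
        acc[9] += re
        acc[10] += lgl / nr
        acc[11] += hgl / nr
        acc[12] += srl / nr
        acc[13] += srh / nr
        acc[14] += lrl / nr
        acc[15] += lrh / nr
    return acc / n_used


_GLCM_CACHE: dict[tuple, dict] = {}


def _glcm_cache(g_lo: int, span: int, ng_norm: int) -> dict:
    """Index machinery for a co-occurrence matrix over gray values
    ``g_lo .. g_lo+span-1`` with normalization constant ``ng_norm`` (the
    total number of quantized levels)."""
    key = (g_lo, span, ng_norm)
    if key not in _GLCM_CACHE:
        i = np.arange(g_lo, g_lo + span, dtype=np.float64)
        ii, jj = np.meshgrid(i, i, indexing="ij")
        absdiff = np.abs(ii - jj)
        _GLCM_CACHE[key] = dict(
            i=i, ii=ii, jj=jj, absdiff=absdiff,
            diff_idx=absdiff.astype(np.int64).ravel(),
            sum_idx=(ii + jj).astype(np.int64).ravel() - 2 * g_lo,
            w_idm=1.0 / (1.0 + (ii - jj) ** 2),
            w_idmn=1.0 / (1.0 + ((ii - jj) / ng_norm) ** 2),
            w_id=1.0 / (1.0 + absdiff),
            w_idn=1.0 / (1.0 + absdiff / ng_norm),
            w_inv=np.where(absdiff > 0, 1.0 / np.maximum(absdiff, 1) ** 2, 0.0),
        )
    return _GLCM_CACHE[key]


def _xlog2(p: np.ndarray) -> np.ndarray:
    # p * log2(p) with the 0 log 0 := 0 convention
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _glcm_features_all(mats: np.ndarray, g_lo: int, ng_norm: int) -> np.ndarray:
    """GLCM features for a (D, span, span) stack over gray values starting at
    ``g_lo``, averaged over directions."""
    totals = mats.sum(axis=(1, 2))
    keep = totals > 0
    p = mats[keep] / totals[keep, None, None]
    d, span = p.shape[0], p.shape[1]
    c = _glcm_cache(g_lo, span, ng_norm)
    i, ii, jj = c["i"], c["ii"], c["jj"]

    px = p.sum(axis=2)                             # (d, span); symmetric
    mu = (i * px).sum(axis=1)
    sigma2 = (((i[None, :] - mu[:, None]) ** 2) * px).sum(axis=1)

    flat = p.reshape(d, -1)
    p_diff = np.zeros((d, span))
    p_sum = np.zeros((d, 2 * span - 1))
    for k in range(d):
        p_diff[k] = np.bincount(c["diff_idx"], weights=flat[k], minlength=span)
        p_sum[k] = np.bincount(c["sum_idx"], weights=flat[k], minlength=2 * span - 1)

    k_diff = np.arange(span, dtype=np.float64)
    joint_entropy = -_xlog2(p).sum(axis=(1, 2))
    diff_avg = (k_diff * p_diff).sum(axis=1)
    diff_ent = -_xlog2(p_diff).sum(axis=1)
    diff_var = (((k_diff[None, :] - diff_avg[:, None]) ** 2) * p_diff).sum(axis=1)
    sum_ent = -_xlog2(p_sum).sum(axis=1)

    autocorr = (ii * jj * p).sum(axis=(1, 2))
    contrast = (((ii - jj) ** 2) * p).sum(axis=(1, 2))
    correlation = np.where(sigma2 > 0, (autocorr - mu * mu) / np.maximum(sigma2, _EPS), 1.0)
    cshift = ii[None] + jj[None] - 2 * mu[:, None, None]
    cluster_tend = (cshift ** 2 * p).sum(axis=(1, 2))
    cluster_shade = (cshift ** 3 * p).sum(axis=(1, 2))
    cluster_prom = (cshift ** 4 * p).sum(axis=(1, 2))

    hx = -_xlog2(px).sum(axis=1)
    pxpy = np.einsum("di,dj->dij", px, px)
    log_pxpy = np.zeros_like(pxpy)
    nz = pxpy > 0
    log_pxpy[nz] = np.log2(pxpy[nz])
    hxy1 = -(p * log_pxpy).sum(axis=(1, 2))
    hxy2 = -(pxpy * log_pxpy).sum(axis=(1, 2))
    imc1 = np.where(hx > 0, (joint_entropy - hxy1) / np.maximum(hx, _EPS), 0.0)
    imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)), 0.0, None))

    idm = (p * c["w_idm"]).sum(axis=(1, 2))
    idmn = (p * c["w_idmn"]).sum(axis=(1, 2))
    id_ = (p * c["w_id"]).sum(axis=(1, 2))
    idn = (p * c["w_idn"]).sum(axis=(1, 2))
    inv_var = (p * c["w_inv"]).sum(axis=(1, 2))
    max_prob = p.max(axis=(1, 2))
    joint_energy = (p ** 2).sum(axis=(1, 2))
    sum_squares = (((ii[None] - mu[:, None, None]) ** 2) * p).sum(axis=(1, 2))

    per_dir = np.stack([
        autocorr, mu, cluster_prom, cluster_shade, cluster_tend, contrast,
        correlation, diff_avg, diff_ent, diff_var, joint_energy,
        joint_entropy, imc1, imc2, idm, idmn, id_, idn, inv_var, max_prob,
        sum_ent, sum_squares,
    ])
    return per_dir.mean(axis=1)


def _run_zone_features_all(mats: np.ndarray, n_vox: int, g_lo: int = 1) -> np.ndarray:
    """Shared 16-feature set for run-length / size-zone matrix stacks.

    ``mats`` has shape (D, span, nl) over gray values starting at ``g_lo``;
    features are computed per direction and averaged (D = 1 for the
    direction-free size-zone matrix).
    """
    totals = mats.sum(axis=(1, 2))
    keep = totals > 0
    P = mats[keep]
    nr = totals[keep][:, None, None]
    span, nl = P.shape[1], P.shape[2]
    i2 = (np.arange(g_lo, g_lo + span, dtype=np.float64) ** 2)[None, :, None]
    j2 = (np.arange(1, nl + 1, dtype=np.float64) ** 2)[None, None, :]
    p = P / nr
    gl_marg = P.sum(axis=2)
    len_marg = P.sum(axis=1)
    nr1 = nr[:, :, 0].ravel()
    mu_i = (np.sqrt(i2[0, :, 0])[None, :] * p.sum(axis=2)).sum(axis=1)
    mu_j = (np.sqrt(j2[0, 0, :])[None, :] * p.sum(axis=1)).sum(axis=1)
    per_dir = np.stack([
        (P / j2).sum(axis=(1, 2)) / nr1,
        (P * j2).sum(axis=(1, 2)) / nr1,
        (gl_marg ** 2).sum(axis=1) / nr1,
        (gl_marg ** 2).sum(axis=1) / nr1 ** 2,
        (len_marg ** 2).sum(axis=1) / nr1,
        (len_marg ** 2).sum(axis=1) / nr1 ** 2,
        nr1 / n_vox,
        (((np.sqrt(i2) - mu_i[:, None, None]) ** 2) * p).sum(axis=(1, 2)),
        (((np.sqrt(j2) - mu_j[:, None, None]) ** 2) * p).sum(axis=(1, 2)),
        -_xlog2(p).sum(axis=(1, 2)),
        (P / i2).sum(axis=(1, 2)) / nr1,
        (P * i2).sum(axis=(1, 2)) / nr1,
        (P / (i2 * j2)).sum(axis=(1, 2)) / nr1,
        (P * i2 / j2).sum(axis=(1, 2)) / nr1,
        (P * j2 / i2).sum(axis=(1, 2)) / nr1,
        (P * i2 * j2).sum(axis=(1, 2)) / nr1,
    ])
    return per_dir.mean(axis=1)


def _run_zone_features(P: np.ndarray, n_vox: int) -> np.ndarray:
    """16-feature set of a single run-length or size-zone matrix."""
    if P.sum() == 0:
        return np.full(16, np.nan)
    return _run_zone_features_all(P[None], n_vox)


def _gldm_features(P: np.ndarray, n_vox: int, g_lo: int = 1) -> np.ndarray:
    nz_total = P.sum()
    span, nd = P.shape
    i = np.arange(g_lo, g_lo + span, dtype=np.float64)[:, None]
    j = np.arange(1, nd + 1, dtype=np.float64)[None, :]
    p = P / nz_total
    gl_marg = P.sum(axis=1)
    dep_marg = P.sum(axis=0)
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    nz = p > 0
    return np.array([
        float((P / j ** 2).sum() / nz_total),
        float((P * j ** 2).sum() / nz_total),
        float((gl_marg ** 2).sum() / nz_total),
        float((dep_marg ** 2).sum() / nz_total),
        float((dep_marg ** 2).sum() / nz_total ** 2),
        float(((i - mu_i) ** 2 * p).sum()),
        float(((j - mu_j) ** 2 * p).sum()),
        float(-(p[nz] * np.log2(p[nz])).sum()),
        float((P / i ** 2).sum() / nz_total),
        float((P * i ** 2).sum() / nz_total),
        float((P / (i ** 2 * j ** 2)).sum() / nz_total),
        float((P * i ** 2 / j ** 2).sum() / nz_total),
        float((P * j ** 2 / i ** 2).sum() / nz_total),
        float((P * i ** 2 * j ** 2).sum() / nz_total),
    ])


def _ngtdm_features(s: np.ndarray, cnt: np.ndarray, g_lo: int = 1) -> np.ndarray:
    n = cnt.sum()
    present = cnt > 0
    ngp = int(present.sum())
    p = cnt / n
    i = np.arange(g_lo, g_lo + s.size, dtype=np.float64)

    coarseness = 1.0 / max(float((p * s).sum()), _EPS)
    coarseness = min(coarseness, 1e6)
    if ngp > 1:
        pi = p[present]
        ii = i[present]
        diff2 = (ii[:, None] - ii[None, :]) ** 2
        contrast = (
            float((pi[:, None] * pi[None, :] * diff2).sum()) / (ngp * (ngp - 1))
        ) * float(s.sum()) / n
        denom = np.abs(ii[:, None] * pi[:, None] - ii[None, :] * pi[None, :]).sum()
        busyness = float((p * s).sum()) / denom if denom > 0 else 0.0
        num_c = (
            np.abs(ii[:, None] - ii[None, :])
            * (pi[:, None] * s[present][:, None] + pi[None, :] * s[present][None, :])
            / (pi[:, None] + pi[None, :])
        ).sum()
        complexity = float(num_c) / n
        num_s = ((pi[:, None] + pi[None, :]) * diff2).sum()
        strength = float(num_s) / max(float(s.sum()), _EPS)
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    return np.array([coarseness, contrast, busyness, complexity, strength])


def texture_features(binned_bbox: np.ndarray, ng: int) -> np.ndarray:
    """The 73 texture statistics of a quantized ROI bounding box.

    ``binned_bbox`` holds gray levels 1..ng inside the ROI and 0 outside.
    GLCM/GLRLM are averaged over the 13 unique 3D directions; GLSZM, GLDM and
    NGTDM are direction-free. Degenerate single-level regions yield the
    defined limits (joint entropy 0, maximum probability 1, ...) rather than
    errors.
    """
    arr = np.ascontiguousarray(binned_bbox.astype(np.int64))
    n_vox = int((arr > 0).sum())
    if n_vox == 0:
        raise ValueError("empty ROI")

    # crop to the occupied gray range; features that depend on absolute gray
    # values receive the offset, those on gray *differences* are unaffected
    roi_levels = arr[arr > 0]
    g_lo, g_hi = int(roi_levels.min()), int(roi_levels.max())
    span = g_hi - g_lo + 1
    shifted = np.where(arr > 0, arr - g_lo + 1, 0)

    glcm_mats = _glcm_kernel(shifted, span, _OFFSETS_13)
    if glcm_mats.sum() == 0:
        # scattered voxels with no neighboring pairs: fall back to self-pairs,
        # which yields the defined degenerate limits instead of NaNs
        levels, counts = np.unique(shifted[shifted > 0], return_counts=True)
        fallback = np.zeros((1, span, span))
        fallback[0, levels - 1, levels - 1] = counts
        glcm_mats = fallback
    glcm = _glcm_feats_nb(glcm_mats, g_lo, float(ng))

    max_run = int(max(arr.shape))
    glrlm_mats = _glrlm_kernel(shifted, span, _OFFSETS_13, max_run)
    glrlm = _runzone_feats_nb(glrlm_mats, n_vox, g_lo)

    zg, zs = _glszm_kernel(shifted, _OFFSETS_26)
    P_sz = np.zeros((span, int(zs.max())), dtype=np.float64)
    np.add.at(P_sz, (zg - 1, zs - 1), 1.0)
    glszm = _runzone_feats_nb(P_sz[None], n_vox, g_lo)

    gldm = _gldm_features(_gldm_kernel(shifted, span, _OFFSETS_26), n_vox, g_lo)
    s, cnt = _ngtdm_kernel(shifted, span, _OFFSETS_26)
    ngtdm = _ngtdm_features(s, cnt, g_lo)
    return np.concatenate([glcm, glrlm, glszm, gldm, ngtdm])


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def feature_names() -> list[str]:
    """Canonical ordering of the 1834 feature names."""
    names = [f"shape_{n}" for n in SHAPE_NAMES]
    for filt in FILTER_NAMES:
        names += [f"{filt}_firstorder_{n}" for n in FIRST_ORDER_NAMES]
    for filt in FILTER_NAMES:
        for fam, fam_names in TEXTURE_NAMES.items():
            names += [f"{filt}_{fam}_{n}" for n in fam_names]
    return names


def feature_metadata() -> pd.DataFrame:
    """Per-feature metadata: category, source filter image, texture family."""
    rows = []
    for n in SHAPE_NAMES:
        rows.append((f"shape_{n}", "geometry", "original", ""))
    for filt in FILTER_NAMES:
        for n in FIRST_ORDER_NAMES:
            rows.append((f"{filt}_firstorder_{n}", "intensity", filt, ""))
    for filt in FILTER_NAMES:
        for fam, fam_names in TEXTURE_NAMES.items():
            for n in fam_names:
                rows.append((f"{filt}_{fam}_{n}", "texture", filt, fam))
    return pd.DataFrame(
        rows, columns=["name", "category", "filter", "family"]
    ).set_index("name")


def _bbox_slices(mask_arr: np.ndarray, pad: int, shape) -> tuple[slice, ...]:
    idx = np.argwhere(mask_arr)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + pad, shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def extract_multi(
    vol: CTVolume,
    masks: dict[str, MaskVolume],
    pre_cfg: PreprocessConfig | None = None,
) -> dict[str, pd.Series]:
    """Extract the full 1834-feature bank for several ROIs of one volume.

    Filter images are computed once on the padded union bounding box and
    shared across regions, which is what makes whole-tumor plus per-habitat
    extraction affordable.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    if not masks:
        raise ValueError("no masks given")
    union = np.zeros(vol.shape, dtype=bool)
    for m in masks.values():
        m.check_aligned(vol)
        union |= m.values.astype(bool)
    if not union.any():
        raise ValueError("all masks are empty")

    pad = int(np.ceil(2.0 * max(LOG_SIGMAS_MM) / min(vol.spacing_mm)))
    sl = _bbox_slices(union, pad, vol.shape)
    crop = vol.values[sl]
    bank = filter_bank_images(crop, vol.spacing_mm, pre_cfg.clip_lo_hu)

    out: dict[str, pd.Series] = {}
    for region, m in masks.items():
        mcrop = m.values[sl].astype(bool)
        if not mcrop.any():
            raise ValueError(f"mask '{region}' is empty")
        shape_part = shape_features(m)
        fo_vals, tex_vals = [], []
        msl = _bbox_slices(mcrop, 1, mcrop.shape)
        for filt in FILTER_NAMES:
            img = bank[filt]
            region_values = img[mcrop]
            binned_flat, ng = _bin_region(region_values, filt == "original", pre_cfg)
            fo_vals.append(first_order_features(region_values, binned_flat))
            full = np.zeros(mcrop.shape, dtype=np.int64)
            full[mcrop] = binned_flat
            tex_vals.append(texture_features(full[msl], ng))
        fo_idx = [f"{f}_firstorder_{n}" for f in FILTER_NAMES for n in FIRST_ORDER_NAMES]
        tex_idx = [
            f"{f}_{fam}_{n}"
            for f in FILTER_NAMES
            for fam, fam_names in TEXTURE_NAMES.items()
            for n in fam_names
        ]
        series = pd.concat([
            shape_part,
            pd.Series(np.concatenate(fo_vals), index=fo_idx),
            pd.Series(np.concatenate(tex_vals), index=tex_idx),
        ])
        out[region] = series
    return out


def extract_all(
    vol: CTVolume, mask: MaskVolume, pre_cfg: PreprocessConfig | None = None
) -> pd.Series:
    """Whole-ROI ("intra") extraction of the 1834-feature bank."""
    return extract_multi(vol, {"roi": mask}, pre_cfg)["roi"]


def extract_habitat_features(
    vol: CTVolume,
    habitat: HabitatMap,
    pre_cfg: PreprocessConfig | None = None,
    min_voxels: int = 10,
) -> pd.Series:
    """Subregion-mean ("habitat") extraction.

    The 1834-feature bank is extracted from each habitat subregion and the
    feature-wise arithmetic mean across subregions is returned, which is
    invariant to the arbitrary ordering of cluster labels. Subregions smaller
    than ``min_voxels`` are excluded from the mean.
    """
    region_masks = {
        f"habitat{i + 1}": m
        for i, m in enumerate(habitat_masks(habitat))
        if m.voxel_count >= min_voxels
    }
    if not region_masks:
        raise ValueError("no habitat subregion reaches the minimum voxel count")
    per_region = extract_multi(vol, region_masks, pre_cfg)
    return subregion_mean(list(per_region.values()))


def subregion_mean(vectors: list[pd.Series]) -> pd.Series:
    """Feature-wise arithmetic mean over subregion vectors.

    Addends are summed in sorted-value order per feature, so the result is
    bit-identical under any permutation of subregion labels.
    """
    stacked = np.sort(np.column_stack([v.to_numpy() for v in vectors]), axis=1)
    return pd.Series(stacked.mean(axis=1), index=vectors[0].index)


def cohort_feature_table(rows: dict[str, pd.Series], provenance: str) -> pd.DataFrame:
    """Stack per-patient feature vectors into a patients x features table."""
    table = pd.DataFrame(rows).T
    table.index.name = "patient_id"
    table.attrs["provenance"] = provenance
    if table.isna().any().any():
        bad = table.columns[table.isna().any()].tolist()[:5]
        raise ValueError(f"feature table contains missing values, e.g. {bad}")
    return table
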