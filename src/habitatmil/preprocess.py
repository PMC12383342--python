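"""Volume containers, I/O, and CT intensity preprocessing.

The pipeline operates on contrast-enhanced thoracic CT volumes paired with
binary tumor masks. Before any feature extraction, volumes are

1. clipped to a fixed Hounsfield window (default [-125, 225] HU) so that
   extreme values (air, bone, metal) do not dominate intensity statistics,
2. resampled to isotropic voxels (default 1 x 1 x 1 mm) so that texture
   offsets and shape measurements are comparable across scanners, and
3. discretized with a fixed bin *width* (default 5 HU -> 70 bins over the
   clip window), i.e. absolute rather than relative quantization, so a gray
   level means the same HU interval for every patient.

Arrays are indexed ``[axis0, axis1, axis2]`` with ``axis 0`` the axial
(slice) axis; ``spacing_mm`` is aligned with the array axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "CTVolume",
    "MaskVolume",
    "PreprocessConfig",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "clip_hu",
    "resample_isotropic",
    "discretize",
    "preprocess_pair",
]

HU_MIN = -1024.0
HU_MAX = 3071.0


@dataclass(frozen=True)
class CTVolume:
    """A 3D scalar CT grid in Hounsfield units with explicit geometry."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"CT volume must be 3D, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("CT volume contains non-finite values")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass(frozen=True)
class MaskVolume:
    """A binary ROI grid on the same geometry as its paired :class:`CTVolume`."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"mask values must be binary {{0,1}}, found {uniq[:10]}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        object.__setattr__(self, "values", arr.astype(np.uint8))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def check_aligned(self, other: "CTVolume | MaskVolume") -> None:
        if self.shape != other.shape or not np.allclose(self.spacing_mm, other.spacing_mm):
            raise ValueError(
                "image/mask grids are not aligned: "
                f"{self.shape}@{self.spacing_mm} vs {other.shape}@{other.spacing_mm}"
            )


@dataclass(frozen=True)
class PreprocessConfig:
    """Clip window, bin width and target spacing for CT standardization.

    ``(clip_hi_hu - clip_lo_hu)`` must be divisible by ``bin_width_hu`` so bin
    edges tile the window exactly; the defaults give 350 HU / 5 HU = 70 bins.
    """

    clip_lo_hu: float = -125.0
    clip_hi_hu: float = 225.0
    bin_width_hu: float = 5.0
    target_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.clip_lo_hu >= self.clip_hi_hu:
            raise ValueError("clip_lo_hu must be < clip_hi_hu")
        if self.bin_width_hu <= 0:
            raise ValueError("bin_width_hu must be positive")
        width = self.clip_hi_hu - self.clip_lo_hu
        n = width / self.bin_width_hu
        if abs(n - round(n)) > 1e-9:
            raise ValueError("clip window must be divisible by bin width")
        if any(s <= 0 for s in self.target_spacing_mm):
            raise ValueError("target spacing must be positive")

    @property
    def bin_count(self) -> int:
        return int(round((self.clip_hi_hu - self.clip_lo_hu) / self.bin_width_hu))


# ---------------------------------------------------------------------------
# I/O (NIfTI / NRRD via SimpleITK; spacing reversed to match array axis order)
# ---------------------------------------------------------------------------

def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple]:
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    return arr, spacing, origin


def _to_sitk(arr: np.ndarray, spacing: tuple, origin: tuple) -> sitk.Image:
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(reversed(spacing)))
    img.SetOrigin(tuple(reversed(origin)))
    return img


def read_volume(path: str | Path) -> CTVolume:
    """Read a CT volume from a NIfTI (.nii/.nii.gz) or NRRD file."""
    arr, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    return CTVolume(arr.astype(np.float64), spacing, origin)


def read_mask(path: str | Path) -> MaskVolume:
    """Read a binary mask; any non-{0,1} content raises a validation error."""
    arr, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    return MaskVolume(arr, spacing, origin)


def write_volume(vol: CTVolume, path: str | Path) -> None:
    sitk.WriteImage(_to_sitk(vol.values.astype(np.float32), vol.spacing_mm, vol.origin), str(path))


def write_mask(mask: MaskVolume, path: str | Path) -> None:
    sitk.WriteImage(_to_sitk(mask.values.astype(np.uint8), mask.spacing_mm, mask.origin), str(path))


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------

def clip_hu(vol: CTVolume, cfg: PreprocessConfig | None = None) -> CTVolume:
    """Clamp intensities into the configured HU window (idempotent)."""
    cfg = cfg or PreprocessConfig()
    return replace(vol, values=np.clip(vol.values, cfg.clip_lo_hu, cfg.clip_hi_hu))


def _resample(img: sitk.Image, target_rev: tuple, interp) -> sitk.Image:
    in_spacing = np.array(img.GetSpacing())
    in_size = np.array(img.GetSize())
    out_spacing = np.array(target_rev, dtype=float)
    out_size = np.round(in_size * in_spacing / out_spacing).astype(int)
    out_size = np.maximum(out_size, 1)
    rs = sitk.ResampleImageFilter()
    rs.SetOutputSpacing(tuple(out_spacing))
    rs.SetSize([int(s) for s in out_size])
    rs.SetOutputOrigin(img.GetOrigin())
    rs.SetOutputDirection(img.GetDirection())
    rs.SetInterpolator(interp)
    rs.SetDefaultPixelValue(0)
    return rs.Execute(img)


def resample_isotropic(
    vol: CTVolume, mask: MaskVolume, cfg: PreprocessConfig | None = None
) -> tuple[CTVolume, MaskVolume]:
    """Resample image (linear) and mask (nearest-neighbor) onto the target grid.

    Linear interpolation for intensities and nearest-neighbor for the mask keep
    the mask binary while avoiding ringing on the image.
    """
    cfg = cfg or PreprocessConfig()
    mask.check_aligned(vol)
    target_rev = tuple(reversed(cfg.target_spacing_mm))

    vimg = _to_sitk(vol.values, vol.spacing_mm, vol.origin)
    mimg = _to_sitk(mask.values.astype(np.uint8), mask.spacing_mm, mask.origin)
    v_out = _resample(vimg, target_rev, sitk.sitkLinear)
    m_out = _resample(mimg, target_rev, sitk.sitkNearestNeighbor)

    varr, vspc, vorg = _from_sitk(v_out)
    marr, mspc, morg = _from_sitk(m_out)
    return CTVolume(varr, vspc, vorg), MaskVolume(marr, mspc, morg)


def discretize(
    vol: CTVolume, mask: MaskVolume, cfg: PreprocessConfig | None = None
) -> tuple[np.ndarray, int]:
    """Fixed-bin-width discretization of the ROI.

    Bin index of a voxel with value ``x`` is ``floor((x - clip_lo)/width) + 1``,
    capped at ``bin_count`` so the top edge falls into the last bin (half-open
    bins, closed at the top). Returns an integer grid (0 outside the mask,
    1..bin_count inside) and the bin count.
    """
    cfg = cfg or PreprocessConfig()
    mask.check_aligned(vol)
    n_bins = cfg.bin_count
    idx = np.floor((vol.values - cfg.clip_lo_hu) / cfg.bin_width_hu).astype(np.int64) + 1
    idx = np.clip(idx, 1, n_bins)
    idx[mask.values == 0] = 0
    return idx, n_bins


def preprocess_pair(
    vol: CTVolume, mask: MaskVolume, cfg: PreprocessConfig | None = None
) -> tuple[CTVolume, MaskVolume]:
    """Clip then resample an image/mask pair (the standard entry point)."""
    cfg = cfg or PreprocessConfig()
    vol, mask = resample_isotropic(vol, mask, cfg)
    return clip_hu(vol, cfg), mask
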