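"""Synthetic CT cohorts with planted habitat structure and a known label model.

No public imaging cohort exists for the post-neoadjuvant esophageal LNM
problem, so every downstream stage is exercised on phantoms generated here.
Each patient is an ellipsoidal tumor embedded in a smooth soft-tissue
background, partitioned into ``n_subregions_true`` compartments that mimic
the biology habitat imaging responds to:

* an eccentric low-HU core (necrosis analog),
* intermediate periphery (viable tumor), and
* a high-HU rim (contrast-enhancing margin).

Per-compartment intensities are Gaussian random fields with
compartment-specific mean, SD and correlation length, so both first-order
and texture features carry recoverable signal. The binary LNM label is drawn
from a logistic model over known latent variables (core volume fraction, rim
mean HU, rim HU heterogeneity, MLNSD, age, treatment), which makes parameter
recovery and directional model comparisons testable. The rim-heterogeneity
latent is deliberately a *within-compartment* signal: whole-tumor statistics
are nearly blind to it (between-compartment contrast dominates the pooled
variance) while subregion-mean statistics see it directly.

Rater variability is emulated by :func:`perturb_mask`, which jitters the mask
boundary by thresholding the signed distance plus a smooth noise field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq

from .preprocess import CTVolume, MaskVolume, write_mask, write_volume

__all__ = [
    "SubregionParams",
    "CohortConfig",
    "ClinicalRecord",
    "SyntheticPatient",
    "generate_cohort",
    "compartment_phantom",
    "perturb_mask",
    "clinical_table",
    "latent_table",
    "write_cohort",
    "CLINICAL_COLUMNS",
]

HU_FLOOR, HU_CEIL = -1024.0, 3071.0


@dataclass(frozen=True)
class SubregionParams:
    """Mean HU, HU standard deviation and texture correlation length (voxels)."""

    mean_hu: float
    sd_hu: float
    corr_len: float


#: core -> periphery -> rim; 70-HU steps against a within-compartment SD of
#: at most 22.5 HU (the rim heterogeneity latent's upper end) keep compartments
#: separable by > 3 SD, the margin habitat clustering needs. Compartments also
#: differ in dispersion (smooth necrotic core, heterogeneous enhancing rim),
#: so local-texture channels carry compartment signal as well.
DEFAULT_SUBREGIONS = (
    SubregionParams(10.0, 4.0, 1.2),
    SubregionParams(80.0, 10.0, 1.5),
    SubregionParams(150.0, 15.0, 1.0),
)

#: log-odds coefficients on standardized latents. The imaging signal lives
#: predominantly in subregion contrasts: the *shape* of the necrotic core
#: (elongation) — internal geometry that whole-tumor statistics cannot
#: express because the outer surface and the pooled intensity histogram are
#: unchanged — plus within-rim heterogeneity, with milder whole-tumor
#: visible effects (core volume fraction, rim enhancement level).
DEFAULT_EFFECTS = {
    "core_frac": 0.5,
    "rim_mean_hu": 0.5,
    "core_sd": 1.6,
    "mlnsd": 0.8,
    "age": -0.5,
    "treatment": -0.6,
}

#: generative standardization constants (mean, sd) for each latent
_LATENT_SCALE = {
    "core_frac": (0.19, 0.0635),
    "rim_mean_hu": (150.0, 15.0),
    "core_sd": (9.0, 3.46),
    "mlnsd": (8.0, 3.0),
    "age": (60.0, 8.0),
    "treatment": (0.5, 0.5),
}

CLINICAL_COLUMNS = [
    "age", "sex", "smoking", "drinking", "cT", "cN", "treatment",
    "TMD_mm", "MLNSD_mm", "enhancement", "MLNF", "MLNEV", "MLNN",
]


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 100
    prevalence: float = 0.3
    volume_shape: tuple[int, int, int] = (32, 48, 48)
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_subregions_true: int = 3
    subregion_params: tuple[SubregionParams, ...] = DEFAULT_SUBREGIONS
    effect_vector: dict = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    tumor_radius_range: tuple[float, float] = (6.0, 9.0)
    axial_ratio: float = 0.8
    pv_mix_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if any(s < 1 for s in self.volume_shape):
            raise ValueError("volume_shape must be positive")
        if self.n_subregions_true < 1:
            raise ValueError("n_subregions_true must be >= 1")
        if len(self.subregion_params) != self.n_subregions_true:
            # pad/derive radial bands between core and rim params
            base = list(self.subregion_params)
            if len(base) < 2:
                raise ValueError("need at least core and rim subregion params")
            lo, hi = base[0], base[-1]
            k = self.n_subregions_true
            params = tuple(
                SubregionParams(
                    lo.mean_hu + (hi.mean_hu - lo.mean_hu) * i / max(k - 1, 1),
                    lo.sd_hu + (hi.sd_hu - lo.sd_hu) * i / max(k - 1, 1),
                    lo.corr_len + (hi.corr_len - lo.corr_len) * i / max(k - 1, 1),
                )
                for i in range(k)
            )
            object.__setattr__(self, "subregion_params", params)


@dataclass(frozen=True)
class ClinicalRecord:
    """Clinicoradiological covariates mirroring the field's standard table."""

    age: float
    sex: int
    smoking: int
    drinking: int
    cT: int
    cN: int
    treatment: str  # "NACT" or "NACRT"
    TMD_mm: float
    MLNSD_mm: float
    enhancement: int
    MLNF: int
    MLNEV: int
    MLNN: int

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.MLNSD_mm < 0:
            raise ValueError("MLNSD_mm must be >= 0")
        if self.treatment not in ("NACT", "NACRT"):
            raise ValueError("treatment must be NACT or NACRT")


@dataclass(frozen=True)
class SyntheticPatient:
    patient_id: str
    ct: CTVolume
    mask: MaskVolume
    true_habitat: np.ndarray  # int grid, 0 outside mask, 1..k inside
    clinical: ClinicalRecord
    label: int
    latents: dict

    def __post_init__(self) -> None:
        inside = self.true_habitat > 0
        if not np.array_equal(inside, self.mask.values.astype(bool)):
            raise ValueError("true_habitat must be nonzero exactly on the mask")


def _grf(rng: np.random.Generator, shape, corr_len: float) -> np.ndarray:
    """Unit-SD Gaussian random field with the given correlation length."""
    noise = rng.standard_normal(shape)
    if corr_len > 0:
        noise = ndimage.gaussian_filter(noise, corr_len)
    sd = noise.std()
    return noise / sd if sd > 0 else noise


def _standardize_latents(lat: dict) -> dict:
    return {k: (lat[k] - _LATENT_SCALE[k][0]) / _LATENT_SCALE[k][1] for k in _LATENT_SCALE}


def _solve_intercept(scores: np.ndarray, prevalence: float) -> float:
    """Intercept making mean sigmoid(b0 + score) equal the target prevalence."""

    def gap(b0):
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + scores)))) - prevalence)

    return brentq(gap, -30.0, 30.0, xtol=1e-10)


def generate_cohort(config: CohortConfig) -> list[SyntheticPatient]:
    """Generate a deterministic synthetic cohort from ``config``.

    The same config (including seed) yields a bit-identical cohort. Labels are
    drawn from a logistic model over standardized latents with coefficients
    ``config.effect_vector``; the intercept is solved so the expected label
    rate equals ``config.prevalence``.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.volume_shape)
    k = config.n_subregions_true
    r_lo, r_hi = config.tumor_radius_range
    if 2 * r_hi + 4 > min(shape[1], shape[2]) or 2 * r_hi * config.axial_ratio + 4 > shape[0]:
        raise ValueError(
            f"volume_shape {shape} too small for tumors of radius up to {r_hi} voxels"
        )

    grids = np.indices(shape).astype(np.float64)
    raw: list[dict] = []

    for i in range(config.n_patients):
        radii_plane = rng.uniform(r_lo, r_hi, size=2)
        radius_ax = rng.uniform(r_lo, r_hi) * config.axial_ratio
        radii = np.array([radius_ax, radii_plane[0], radii_plane[1]])
        center = np.array(shape) / 2.0 + rng.uniform(-1.5, 1.5, size=3)

        rho = np.sqrt(sum(((grids[a] - center[a]) / radii[a]) ** 2 for a in range(3)))
        mask_arr = (rho <= 1.0).astype(np.uint8)

        # latent image variables: a small, variably heterogeneous necrotic
        # core (its texture is the dominant label signal and is volume-diluted
        # ~10:1 in whole-tumor statistics) plus rim enhancement latents
        core_frac = rng.uniform(0.08, 0.30)
        core_sd = rng.uniform(3.0, 15.0)
        core_elong = rng.uniform(1.0, 2.0)
        elong_axis = int(rng.integers(0, 3))
        rim_inner = rng.uniform(0.70, 0.85)
        rim_params = config.subregion_params[-1]
        rim_mu = rng.normal(rim_params.mean_hu, 15.0)
        rim_sd = rim_params.sd_hu
        periph_mu = rng.normal(config.subregion_params[min(1, k - 1)].mean_hu, 10.0)

        # compartments: eccentric core + radial bands + rim shell
        habitat = np.zeros(shape, dtype=np.int16)
        if k == 1:
            habitat[mask_arr == 1] = 1
        else:
            core_scale = core_frac ** (1.0 / 3.0)
            core_center = center + rng.uniform(-1.5, 1.5, size=3)
            # volume-preserving anisotropy: the core stretches along one axis
            # (internal geometry invisible to whole-tumor shape statistics)
            stretch = np.full(3, core_elong ** (-1.0 / 3.0))
            stretch[elong_axis] = core_elong ** (2.0 / 3.0)
            rho_core = np.sqrt(
                sum(((grids[a] - core_center[a]) / (radii[a] * core_scale * stretch[a])) ** 2
                    for a in range(3))
            )
            # radial band edges between core surface and the rim shell
            habitat[mask_arr == 1] = 0
            inside = mask_arr == 1
            band = np.full(shape, -1, dtype=np.int16)
            if k > 2:
                edges = np.linspace(0.0, rim_inner, k - 1)
                band_idx = np.clip(
                    np.searchsorted(edges[1:], rho, side="right") + 1, 1, k - 1
                )
            else:
                band_idx = np.ones(shape, dtype=np.int64)
            band[inside] = band_idx[inside]
            band[inside & (rho >= rim_inner)] = k  # rim shell
            band[inside & (rho_core <= 1.0) & (rho < rim_inner)] = 1  # eccentric core
            if k > 2:
                band[inside & (rho_core > 1.0) & (band == 1)] = 2
            habitat = np.where(inside, band, 0).astype(np.int16)

        # intensities: background + per-compartment Gaussian random fields,
        # mixed with partial-volume-like smooth transitions at internal
        # interfaces (labels stay crisp; only intensities blend)
        ct = 40.0 + 20.0 * _grf(rng, shape, 3.0)
        inside = habitat > 0
        fields, weights = [], []
        for lbl in range(1, k + 1):
            params = config.subregion_params[lbl - 1]
            mu, sd = params.mean_hu, params.sd_hu
            if lbl == k and k > 1:
                mu, sd = rim_mu, rim_sd
            elif lbl == 1 and k > 1:
                sd = core_sd
            elif lbl == 2 and k == 3:
                mu = periph_mu
            if not (habitat == lbl).any():
                continue
            fields.append(mu + sd * _grf(rng, shape, params.corr_len))
            if config.pv_mix_sigma > 0:
                dist = ndimage.distance_transform_edt(habitat != lbl)
                weights.append(np.exp(-((dist / config.pv_mix_sigma) ** 2)))
            else:
                weights.append((habitat == lbl).astype(np.float64))
        W = np.stack(weights)
        F = np.stack(fields)
        wsum = W.sum(axis=0)
        wsum[wsum == 0] = 1.0
        mix = (W * F).sum(axis=0) / wsum
        ct[inside] = mix[inside]
        ct = np.clip(ct, HU_FLOOR, HU_CEIL)

        # clinicoradiological covariates
        age = float(np.clip(rng.normal(60.0, 8.0), 30.0, 85.0))
        treatment = "NACRT" if rng.random() < 0.5 else "NACT"
        mlnsd = float(np.clip(rng.normal(8.0, 3.0), 1.0, 25.0))
        clinical = ClinicalRecord(
            age=age,
            sex=int(rng.random() < 0.85),
            smoking=int(rng.random() < 0.6),
            drinking=int(rng.random() < 0.5),
            cT=int(rng.choice([2, 3, 4], p=[0.2, 0.6, 0.2])),
            cN=int(rng.choice([0, 1, 2], p=[0.3, 0.5, 0.2])),
            treatment=treatment,
            TMD_mm=float(np.clip(rng.normal(40.0, 10.0), 10.0, 80.0)),
            MLNSD_mm=mlnsd,
            enhancement=int(rng.random() < 0.5),
            MLNF=int(rng.random() < 0.3),
            MLNEV=int(rng.random() < 0.3),
            MLNN=int(rng.random() < 0.3),
        )

        actual_core_frac = (
            float((habitat == 1).sum()) / max(int(mask_arr.sum()), 1) if k > 1 else 0.3
        )
        latents = {
            "core_frac": actual_core_frac,
            "rim_mean_hu": rim_mu,
            "periphery_hu": periph_mu,
            "core_sd": core_sd,
            "core_elong": core_elong,
            "rim_inner": rim_inner,
            "mlnsd": mlnsd,
            "age": age,
            "treatment": 1.0 if treatment == "NACRT" else 0.0,
        }
        raw.append(
            dict(ct=ct, mask=mask_arr, habitat=habitat, clinical=clinical, latents=latents)
        )

    # labels: logistic model with intercept solved for the target prevalence
    effects = config.effect_vector
    scores = np.array(
        [
            sum(effects.get(name, 0.0) * z for name, z in _standardize_latents(p["latents"]).items())
            for p in raw
        ]
    )
    b0 = _solve_intercept(scores, config.prevalence)
    probs = 1.0 / (1.0 + np.exp(-(b0 + scores)))
    labels = (rng.random(config.n_patients) < probs).astype(int)

    spacing = config.voxel_spacing_mm
    cohort = []
    for i, p in enumerate(raw):
        lat = dict(p["latents"])
        lat["lnm_probability"] = float(probs[i])
        cohort.append(
            SyntheticPatient(
                patient_id=f"P{i:04d}",
                ct=CTVolume(p["ct"], spacing),
                mask=MaskVolume(p["mask"], spacing),
                true_habitat=p["habitat"],
                clinical=p["clinical"],
                label=int(labels[i]),
                latents=lat,
            )
        )
    return cohort


def compartment_phantom(
    seed: int = 0,
    slab_thickness: int = 18,
    width: int = 28,
    means_hu: tuple[float, float, float] = (10.0, 80.0, 150.0),
    sds_hu: tuple[float, float, float] = (3.0, 10.0, 25.0),
    corr_len: tuple[float, float, float] = (0.8, 0.8, 0.8),
) -> tuple[CTVolume, MaskVolume, np.ndarray]:
    """Calibration phantom with three planted slab compartments.

    A box ROI stacked from three thick slabs, each a Gaussian random field
    with its own mean HU and SD — the canonical QA-style geometry for
    validating subregion recovery: compartment interiors are large relative
    to the local-feature window, and compartments are separable in both
    intensity and local-texture channels (the intensity gaps exceed 3x the
    largest within-compartment SD). Correlation lengths are kept short and
    equal by default: fields with ranges comparable to the 3-voxel window
    make neighborhood statistics track local field realizations rather than
    compartment identity. Returns ``(ct, mask, true_labels)``.
    """
    shape = (3 * slab_thickness, width, width)
    rng = np.random.default_rng(seed)
    mask = np.zeros(shape, np.uint8)
    mask[:, 2:-2, 2:-2] = 1
    truth = np.zeros(shape, np.int16)
    ct = 40.0 + 20.0 * rng.standard_normal(shape)
    for i in range(3):
        sl = slice(i * slab_thickness, (i + 1) * slab_thickness)
        field_ = _grf(rng, shape, corr_len[i])
        ct[sl] = means_hu[i] + sds_hu[i] * field_[sl]
        truth[sl][mask[sl] == 1] = i + 1
    return CTVolume(np.clip(ct, HU_FLOOR, HU_CEIL)), MaskVolume(mask), truth


def perturb_mask(mask: MaskVolume, magnitude: float, seed: int = 0) -> MaskVolume:
    """Morphologically jitter a mask boundary to emulate a second rater.

    Thresholds ``signed_distance + magnitude * smooth_noise`` at zero: with
    ``magnitude=0`` the output is identical to the input; expected Dice with
    the input decreases as ``magnitude`` grows.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    arr = mask.values.astype(bool)
    if not arr.any():
        raise ValueError("cannot perturb an empty mask")
    if magnitude == 0:
        return MaskVolume(mask.values.copy(), mask.spacing_mm, mask.origin)

    d_in = ndimage.distance_transform_edt(arr)
    d_out = ndimage.distance_transform_edt(~arr)
    signed = d_out - d_in  # negative inside, positive outside
    rng = np.random.default_rng(seed)
    field_ = signed + magnitude * _grf(rng, arr.shape, 2.0)
    out = field_ < 0
    if not out.any():
        out = field_ <= field_.min()  # keep at least the deepest voxel
    return MaskVolume(out.astype(np.uint8), mask.spacing_mm, mask.origin)


def clinical_table(cohort: list[SyntheticPatient]) -> pd.DataFrame:
    """Cohort clinical covariates (one row per patient) plus the LNM label."""
    rows = []
    for p in cohort:
        c = p.clinical
        rows.append(
            dict(
                patient_id=p.patient_id,
                age=c.age, sex=c.sex, smoking=c.smoking, drinking=c.drinking,
                cT=c.cT, cN=c.cN, treatment=c.treatment, TMD_mm=c.TMD_mm,
                MLNSD_mm=c.MLNSD_mm, enhancement=c.enhancement, MLNF=c.MLNF,
                MLNEV=c.MLNEV, MLNN=c.MLNN, label=p.label,
            )
        )
    return pd.DataFrame(rows).set_index("patient_id")


def latent_table(cohort: list[SyntheticPatient]) -> pd.DataFrame:
    """Ground-truth generative latents, standardized as the label model saw them."""
    rows = []
    for p in cohort:
        z = _standardize_latents(p.latents)
        z["label"] = p.label
        rows.append(z)
    return pd.DataFrame(rows, index=[p.patient_id for p in cohort])


def write_cohort(cohort: list[SyntheticPatient], out_dir: str | Path) -> None:
    """Persist a cohort: NIfTI volumes/masks/habitats, clinical CSV, JSON truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p in cohort:
        write_volume(p.ct, out / f"{p.patient_id}_ct.nii.gz")
        write_mask(p.mask, out / f"{p.patient_id}_mask.nii.gz")
        hab = CTVolume(p.true_habitat.astype(np.float64), p.mask.spacing_mm)
        write_volume(hab, out / f"{p.patient_id}_habitat.nii.gz")
    clinical_table(cohort).to_csv(out / "clinical.csv")
    truth = {
        p.patient_id: {"label": p.label, "latents": p.latents} for p in cohort
    }
    truth["_column_dictionary"] = {
        "age": "age in years", "sex": "1=male", "smoking": "smoking history 0/1",
        "drinking": "drinking history 0/1", "cT": "clinical T stage",
        "cN": "clinical N stage", "treatment": "NACT or NACRT",
        "TMD_mm": "tumor maximum diameter (mm)",
        "MLNSD_mm": "maximum lymph node short diameter (mm)",
        "enhancement": "enhancement pattern 0/1",
        "MLNF": "lymph node fusion 0/1", "MLNEV": "extracapsular invasion 0/1",
        "MLNN": "lymph node necrosis 0/1", "label": "LNM at surgery 0/1",
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
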