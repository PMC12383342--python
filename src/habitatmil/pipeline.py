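"""End-to-end study orchestration on a cohort.

Wires the stages together the way the study design prescribes: preprocess
-> habitat delineation -> handcrafted features (whole tumor and
subregion-mean) -> 2.5D/MIL features -> per-chain selection cascades
(the whole-tumor chain includes the ICC robustness stage against a
rater-perturbed second segmentation; the habitat and MIL chains skip it)
-> signature models -> clinicoradiological screen -> fusion nomogram ->
evaluation. All fitting decisions (selection statistics, z-score moments,
thresholds, vocabularies) are made on the training split only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation as ev
from .features import cohort_feature_table, extract_multi, subregion_mean
from .habitat import HabitatConfig, delineate_habitats, habitat_masks
from .mil import (
    DEFAULT_BACKBONES,
    bow_fit,
    build_stack,
    fit_slice_models,
    fuse_mil,
    plh_features,
    predict_matrix,
)
from .preprocess import PreprocessConfig, clip_hu
from .selection import SelectionConfig, run_selection_cascade, zscore_fit_apply
from .signatures import (
    build_nomogram,
    fit_signature,
    multivariate_fit,
    univariate_screen,
)
from .synthetic import SyntheticPatient, clinical_table, perturb_mask

__all__ = ["StudyConfig", "StudyResult", "compute_radiomic_tables", "run_study"]

NOMOGRAM_CLINICAL = ["age", "treatment", "MLNSD_mm"]


@dataclass(frozen=True)
class StudyConfig:
    test_fraction: float = 0.3
    algorithm: str = "logistic"
    backbones: tuple[str, ...] = DEFAULT_BACKBONES
    icc_raters: int = 30          # patients re-segmented for the robustness stage
    lasso_grid_size: int = 30
    seed: int = 0


def _split(labels: np.ndarray, test_fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    idx = np.arange(len(labels))
    test_idx: list[int] = []
    for cls in (0, 1):
        cls_idx = idx[labels == cls]
        n_test = max(int(round(test_fraction * len(cls_idx))), 1)
        test_idx.extend(rng.permutation(cls_idx)[:n_test])
    test_mask = np.zeros(len(labels), dtype=bool)
    test_mask[test_idx] = True
    return ~test_mask, test_mask


def compute_radiomic_tables(
    cohort: list[SyntheticPatient],
    pre_cfg: PreprocessConfig | None = None,
    hab_cfg: HabitatConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Whole-tumor (Intra) and subregion-mean (Habitat) feature tables.

    The filter bank is computed once per patient and shared between the
    whole-ROI and per-habitat extractions.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    hab_cfg = hab_cfg or HabitatConfig()
    intra_rows, habitat_rows, habitat_maps = {}, {}, {}
    for p in cohort:
        vol = clip_hu(p.ct, pre_cfg)
        hmap = delineate_habitats(vol, p.mask, hab_cfg, pre_cfg)
        habitat_maps[p.patient_id] = hmap
        regions = {"intra": p.mask}
        for i, m in enumerate(habitat_masks(hmap)):
            if m.voxel_count >= 10:
                regions[f"habitat{i + 1}"] = m
        per_region = extract_multi(vol, regions, pre_cfg)
        intra_rows[p.patient_id] = per_region["intra"]
        hab_series = [v for k, v in per_region.items() if k.startswith("habitat")]
        habitat_rows[p.patient_id] = subregion_mean(hab_series)
    intra = cohort_feature_table(intra_rows, "Intra")
    habitat = cohort_feature_table(habitat_rows, "Habitat")
    return intra, habitat, habitat_maps


def _mil_tables(
    cohort: list[SyntheticPatient],
    labels: pd.Series,
    train_ids: list[str],
    cfg: StudyConfig,
    pre_cfg: PreprocessConfig,
) -> pd.DataFrame:
    stacks = {
        p.patient_id: build_stack(clip_hu(p.ct, pre_cfg), p.mask, pre_cfg=pre_cfg,
                                  patient_id=p.patient_id)
        for p in cohort
    }
    train_stacks = {pid: stacks[pid] for pid in train_ids}
    models = fit_slice_models(train_stacks, labels, cfg.backbones, seed=cfg.seed)
    matrix_all = predict_matrix(models, stacks)
    matrix_train = predict_matrix(models, train_stacks)
    bow = bow_fit(matrix_train)
    return fuse_mil(plh_features(matrix_all), bow.transform(matrix_all))


def _chain_select(
    train: pd.DataFrame,
    y_train: np.ndarray,
    sel_cfg: SelectionConfig,
    icc_tables=None,
):
    report = run_selection_cascade(train, y_train, sel_cfg, icc_tables=icc_tables)
    selected = report.selected
    if not selected:
        # degenerate safeguard: no nonzero LASSO coefficient; fall back to the
        # strongest t-test survivors so downstream consumers stay defined
        pvals = report.p_values.sort_values()
        selected = pvals.index[: min(5, len(pvals))].tolist()
        warnings.warn("empty LASSO selection; falling back to top t-test features")
    return report, selected


@dataclass
class StudyResult:
    train_ids: list[str]
    test_ids: list[str]
    labels: pd.Series
    scores: dict[str, pd.Series]           # signature -> per-patient probability
    aucs: dict[str, dict[str, float]]      # signature -> {train, test}
    cv_aucs: dict[str, float]
    selection_reports: dict[str, object]
    clinical_fit: dict = field(default_factory=dict)
    nomogram: object = None

    def auc_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.aucs).T[["train", "test"]]


def run_study(cohort: list[SyntheticPatient], cfg: StudyConfig | None = None) -> StudyResult:
    """Run the full pipeline on a cohort and evaluate every signature."""
    cfg = cfg or StudyConfig()
    pre_cfg = PreprocessConfig()
    hab_cfg = HabitatConfig(seed=cfg.seed)
    sel_cfg = SelectionConfig(
        seed=cfg.seed,
        lasso_lambda_grid=tuple(np.logspace(-4, 0, cfg.lasso_grid_size)),
    )

    clin = clinical_table(cohort)
    labels = clin["label"]
    y = labels.to_numpy()
    tr_mask, te_mask = _split(y, cfg.test_fraction, cfg.seed)
    ids = np.array([p.patient_id for p in cohort])
    train_ids, test_ids = ids[tr_mask].tolist(), ids[te_mask].tolist()
    y_tr = labels.loc[train_ids].to_numpy()

    # --- handcrafted tables -------------------------------------------------
    intra, habitat, _ = compute_radiomic_tables(cohort, pre_cfg, hab_cfg)

    # rater-perturbed duplicate segmentations for the ICC stage (Intra chain)
    icc_ids = train_ids[: min(cfg.icc_raters, len(train_ids))]
    retest_rows = {}
    by_id = {p.patient_id: p for p in cohort}
    for k, pid in enumerate(icc_ids):
        p = by_id[pid]
        m2 = perturb_mask(p.mask, magnitude=1.0, seed=cfg.seed + 7919 * (k + 1))
        vol = clip_hu(p.ct, pre_cfg)
        retest_rows[pid] = extract_multi(vol, {"roi": m2}, pre_cfg)["roi"]
    retest = cohort_feature_table(retest_rows, "Intra-retest")

    # --- MIL features -------------------------------------------------------
    mil_table = _mil_tables(cohort, labels, train_ids, cfg, pre_cfg)

    # --- per-chain selection + signatures ----------------------------------
    chains = {
        "Intra_Rad": (intra, (intra.loc[icc_ids], retest)),
        "Habitat_Rad": (habitat, None),
        "MIL_Rad": (mil_table, None),
    }
    scores: dict[str, pd.Series] = {}
    cv_aucs: dict[str, float] = {}
    reports: dict[str, object] = {}
    for name, (table, icc_pair) in chains.items():
        tr_tab = table.loc[train_ids]
        report, selected = _chain_select(tr_tab, y_tr, sel_cfg, icc_tables=icc_pair)
        reports[name] = report
        z_tr, z_all = zscore_fit_apply(tr_tab[selected], table[selected])
        sig = fit_signature(z_tr, y_tr, cfg.algorithm, seed=cfg.seed)
        cv_aucs[name] = sig.cv_auc
        scores[name] = pd.Series(sig.predict_proba(z_all), index=table.index)

    # --- clinicoradiological signature --------------------------------------
    clin_X = clin.drop(columns=["label"])
    uni, advancing = univariate_screen(clin_X.loc[train_ids], y_tr)
    multi, retained = multivariate_fit(clin_X.loc[train_ids], y_tr, advancing)
    if not retained:
        retained = NOMOGRAM_CLINICAL
    from .signatures import _encode  # numeric coding shared with the fits

    clin_enc = _encode(clin_X)[retained]
    sig_clin = fit_signature(clin_enc.loc[train_ids], y_tr, cfg.algorithm, seed=cfg.seed)
    cv_aucs["Clinic"] = sig_clin.cv_auc
    scores["Clinic"] = pd.Series(sig_clin.predict_proba(clin_enc), index=clin_enc.index)

    # --- fusion nomogram -----------------------------------------------------
    nomo_inputs = _encode(clin_X)[NOMOGRAM_CLINICAL].copy()
    nomo_inputs["Habitat_Rad"] = scores["Habitat_Rad"]
    nomo_inputs["MIL_Rad"] = scores["MIL_Rad"]
    nomogram = build_nomogram(nomo_inputs.loc[train_ids], y_tr)
    scores["Nomogram"] = nomo_inputs.apply(nomogram.probability, axis=1)

    aucs = {}
    for name, s in scores.items():
        aucs[name] = {
            "train": ev.roc_auc(s.loc[train_ids], labels.loc[train_ids]).auc,
            "test": ev.roc_auc(s.loc[test_ids], labels.loc[test_ids]).auc,
        }
    # nomogram CV AUC (logistic on the five inputs under the same folds)
    from .signatures import signature_cv_auc

    cv_aucs["Nomogram"] = signature_cv_auc(
        nomo_inputs.loc[train_ids], y_tr, "logistic", seed=cfg.seed
    )

    return StudyResult(
        train_ids=train_ids,
        test_ids=test_ids,
        labels=labels,
        scores=scores,
        aucs=aucs,
        cv_aucs=cv_aucs,
        selection_reports=reports,
        clinical_fit={"univariate": uni, "multivariate": multi, "retained": retained},
        nomogram=nomogram,
    )
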