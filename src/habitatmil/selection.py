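"""Feature-selection cascade: ICC filter -> Z-score -> t-test -> correlation
pruning -> LASSO with 10-fold cross-validation.

The cascade mirrors standard radiomics practice: first discard features that
are not robust to segmentation variability (ICC(2,1) >= 0.85 between two
raters or two sittings), standardize on the training cohort, keep features
whose class means differ (Welch t-test, p < 0.05), break up redundant blocks
(greedy deletion while any Pearson |r| > 0.9), and finally fit an
L1-penalized linear regression of the binary label with the penalty chosen
by minimum mean 10-fold cross-validated squared error. Survivors are
strictly nested from stage to stage.

The habitat and MIL chains skip the ICC stage: their inputs are produced by
unsupervised clustering / model fusion, not by a rater's contour.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

__all__ = [
    "SelectionConfig",
    "SelectionReport",
    "icc_2_1",
    "icc_filter",
    "zscore_fit_apply",
    "ttest_filter",
    "correlation_prune",
    "lasso_select",
    "run_selection_cascade",
]


@dataclass(frozen=True)
class SelectionConfig:
    icc_threshold: float = 0.85
    ttest_alpha: float = 0.05
    corr_threshold: float = 0.9
    lasso_folds: int = 10
    lasso_lambda_grid: tuple[float, ...] = tuple(np.logspace(-4, 0, 50))
    seed: int = 0

    def __post_init__(self) -> None:
        for v in (self.icc_threshold, self.ttest_alpha, self.corr_threshold):
            if not (0.0 < v < 1.0):
                raise ValueError("thresholds must lie in (0, 1)")
        if self.lasso_folds < 2:
            raise ValueError("lasso_folds must be >= 2")
        if len(self.lasso_lambda_grid) == 0:
            raise ValueError("empty lambda grid")


@dataclass
class SelectionReport:
    """Per-stage survivors and diagnostics; stages are strictly nested."""

    stages: dict[str, list[str]] = field(default_factory=dict)
    icc_values: pd.Series | None = None
    p_values: pd.Series | None = None
    chosen_lambda: float | None = None
    coefficients: pd.Series | None = None

    def record(self, stage: str, names: list[str]) -> None:
        if self.stages:
            prev = set(list(self.stages.values())[-1])
            if not set(names) <= prev:
                raise ValueError(f"stage '{stage}' is not nested in the previous stage")
        self.stages[stage] = list(names)

    @property
    def selected(self) -> list[str]:
        return list(self.stages.values())[-1] if self.stages else []

    def to_json(self, path: str | Path) -> None:
        payload = {
            "stages": self.stages,
            "chosen_lambda": self.chosen_lambda,
            "coefficients": None
            if self.coefficients is None
            else self.coefficients.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def icc_2_1(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized ICC(2,1): two-way random effects, absolute agreement,
    single measurement, for two raters.

    ``a``/``b`` are (n_subjects, n_features) measurements by each rater.
    Returns one ICC per feature (NaN where the feature has zero variance).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    n = a.shape[0]
    k = 2
    data = np.stack([a, b], axis=1)          # (n, k, f)
    mean_subj = data.mean(axis=1)             # (n, f)
    mean_rater = data.mean(axis=0)            # (k, f)
    grand = data.mean(axis=(0, 1))            # (f,)

    ss_subj = k * ((mean_subj - grand) ** 2).sum(axis=0)
    ss_rater = n * ((mean_rater - grand) ** 2).sum(axis=0)
    ss_total = ((data - grand) ** 2).sum(axis=(0, 1))
    ss_err = ss_total - ss_subj - ss_rater

    msr = ss_subj / (n - 1)
    msc = ss_rater / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = (msr - mse) / denom
    icc[~np.isfinite(icc)] = np.nan
    return icc


def icc_filter(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    cfg: SelectionConfig | None = None,
) -> tuple[list[str], pd.Series]:
    """Keep features with ICC(2,1) >= threshold between two segmentations.

    The threshold is inclusive; zero-variance features (undefined ICC) are
    dropped.
    """
    cfg = cfg or SelectionConfig()
    if not table_a.columns.equals(table_b.columns) or not table_a.index.equals(table_b.index):
        raise ValueError("the two tables must share patients and features")
    icc = pd.Series(icc_2_1(table_a.values, table_b.values), index=table_a.columns)
    keep = icc.index[icc >= cfg.icc_threshold].tolist()
    return keep, icc


def zscore_fit_apply(
    train: pd.DataFrame, *others: pd.DataFrame
) -> tuple[pd.DataFrame, ...]:
    """Z-score with training statistics (population SD); zero-SD columns are
    dropped from every table."""
    if train.empty:
        raise ValueError("training table is empty")
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    keep = sd.index[sd > 0]
    out = [((t[keep] - mu[keep]) / sd[keep]) for t in (train, *others)]
    return tuple(out)


def ttest_filter(
    table: pd.DataFrame,
    labels: np.ndarray,
    cfg: SelectionConfig | None = None,
) -> tuple[list[str], pd.Series]:
    """Two-sided Welch t-test per feature; keep p strictly below alpha."""
    cfg = cfg or SelectionConfig()
    labels = np.asarray(labels)
    g0 = table.values[labels == 0]
    g1 = table.values[labels == 1]
    if g0.shape[0] < 2 or g1.shape[0] < 2:
        raise ValueError("each class needs at least two samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(g0, g1, axis=0, equal_var=False)
    pvals = pd.Series(p, index=table.columns).fillna(1.0)
    keep = pvals.index[pvals < cfg.ttest_alpha].tolist()
    return keep, pvals


def correlation_prune(
    table: pd.DataFrame, cfg: SelectionConfig | None = None
) -> list[str]:
    """Greedy redundancy pruning on pairwise Pearson correlation.

    While any pair exceeds the threshold, delete the feature with the most
    over-threshold partners (ties: larger mean |r| over its partners, then
    lexicographically larger name). Terminates when no pair exceeds the
    threshold.
    """
    cfg = cfg or SelectionConfig()
    cols = list(table.columns)
    if len(cols) < 2:
        return cols
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.abs(np.corrcoef(table.values.T))
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 0.0)
    adj = r > cfg.corr_threshold
    alive = np.ones(len(cols), dtype=bool)

    while True:
        counts = (adj & alive[None, :] & alive[:, None]).sum(axis=1)
        counts[~alive] = 0
        if counts.max() == 0:
            break
        cand = np.flatnonzero(counts == counts.max())
        if cand.size > 1:
            mean_r = np.array([
                r[c][adj[c] & alive].mean() if (adj[c] & alive).any() else 0.0
                for c in cand
            ])
            cand = cand[mean_r == mean_r.max()]
            if cand.size > 1:
                cand = np.array([max(cand, key=lambda c: cols[c])])
        alive[cand[0]] = False

    return [c for c, a in zip(cols, alive) if a]


def lasso_select(
    table: pd.DataFrame,
    labels: np.ndarray,
    cfg: SelectionConfig | None = None,
) -> tuple[list[str], pd.Series, float]:
    """LASSO (squared-error loss on the 0/1 label) with CV-chosen penalty.

    For each lambda on the grid, the mean squared error over ``lasso_folds``
    cross-validation folds is computed; the lambda with the smallest mean MSE
    is chosen and the model refit on all rows. Features with nonzero
    coefficients are selected.
    """
    cfg = cfg or SelectionConfig()
    y = np.asarray(labels, dtype=np.float64)
    X = table.values
    grid = np.sort(np.asarray(cfg.lasso_lambda_grid))[::-1]

    kf = KFold(n_splits=cfg.lasso_folds, shuffle=True, random_state=cfg.seed)
    mse = np.zeros((len(grid), cfg.lasso_folds))
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        for f, (tr, va) in enumerate(kf.split(X)):
            model = Lasso(alpha=grid[0], max_iter=5000, warm_start=True)
            for i, lam in enumerate(grid):
                model.set_params(alpha=lam)
                model.fit(X[tr], y[tr])
                mse[i, f] = float(((model.predict(X[va]) - y[va]) ** 2).mean())
        best = int(np.argmin(mse.mean(axis=1)))
        lam_star = float(grid[best])

        final = Lasso(alpha=lam_star, max_iter=20000).fit(X, y)
    coefs = pd.Series(final.coef_, index=table.columns)
    selected = coefs.index[coefs != 0].tolist()
    return selected, coefs[selected], lam_star


def run_selection_cascade(
    train: pd.DataFrame,
    labels: np.ndarray,
    cfg: SelectionConfig | None = None,
    icc_tables: tuple[pd.DataFrame, pd.DataFrame] | None = None,
) -> SelectionReport:
    """Run the full cascade on a training table.

    ``icc_tables`` are paired feature tables from two segmentations of a
    (usually smaller) robustness subset; when given, the ICC stage filters
    the training table's features by their agreement on that subset. Passing
    ``None`` skips the ICC stage (the habitat and MIL chains). All statistics
    are computed on the training cohort only; test tables are transformed
    downstream with the same fitted statistics.
    """
    cfg = cfg or SelectionConfig()
    report = SelectionReport()
    report.record("input", list(train.columns))
    current = train

    if icc_tables is not None:
        a, b = icc_tables
        keep, icc = icc_filter(a[current.columns], b[current.columns], cfg)
        report.icc_values = icc
        report.record("icc", keep)
        current = current[keep]

    (current,) = zscore_fit_apply(current)
    report.record("zscore", list(current.columns))

    keep, pvals = ttest_filter(current, labels, cfg)
    report.p_values = pvals
    report.record("ttest", keep)
    current = current[keep]

    if current.shape[1] == 0:
        report.record("correlation", [])
        report.record("lasso", [])
        report.coefficients = pd.Series(dtype=float)
        return report

    keep = correlation_prune(current, cfg)
    report.record("correlation", keep)
    current = current[keep]

    selected, coefs, lam = lasso_select(current, labels, cfg)
    report.record("lasso", selected)
    report.coefficients = coefs
    report.chosen_lambda = lam
    return report
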