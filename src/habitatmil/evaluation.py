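"""Model evaluation: ROC/AUC with DeLong variance and tests, threshold
metrics with bootstrap intervals, calibration (bootstrap bands +
Hosmer-Lemeshow), and decision-curve analysis.

The AUC is the Mann-Whitney statistic with midranks for ties; its variance
and the covariance between two correlated AUCs come from the DeLong
structural components, giving a Wald interval and the nonparametric paired
test for AUC differences. Net benefit at threshold probability t is
``TP/n - FP/n * t/(1-t)``; treat-all is ``pi - (1-pi) * t/(1-t)`` and
treat-none is identically zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROCResult",
    "ThresholdMetrics",
    "CalibrationResult",
    "DecisionCurve",
    "roc_auc",
    "auc_brute_force",
    "delong_test",
    "threshold_metrics",
    "hosmer_lemeshow",
    "calibration_curve",
    "decision_curve",
]


def _check_classes(labels: np.ndarray) -> None:
    u = np.unique(labels)
    if not (u.size == 2 and set(u) <= {0, 1}):
        raise ValueError("labels must contain both classes coded 0/1")


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """AUC plus the DeLong structural components (V10 per positive, V01 per
    negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return float(auc), v10, v01


@dataclass
class ROCResult:
    auc: float
    variance: float
    ci95: tuple[float, float]
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_auc(scores, labels, ci_method: str = "wald") -> ROCResult:
    """AUC with DeLong variance and a 95% interval (clipped to [0, 1]).

    ``ci_method`` is "wald" (default) or "logit" for the logit-transformed
    interval, which respects the [0, 1] bounds at extreme AUCs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_classes(labels)
    auc, v10, v01 = _delong_components(scores, labels)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    se = np.sqrt(var)
    if ci_method == "logit" and 0 < auc < 1 and se > 0:
        logit = np.log(auc / (1 - auc))
        se_l = se / (auc * (1 - auc))
        lo = 1 / (1 + np.exp(-(logit - 1.96 * se_l)))
        hi = 1 / (1 + np.exp(-(logit + 1.96 * se_l)))
    else:
        lo, hi = auc - 1.96 * se, auc + 1.96 * se
    ci = (float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1)))

    from sklearn.metrics import roc_curve as _skl_roc

    fpr, tpr, thr = _skl_roc(labels, scores)
    return ROCResult(auc, float(var), ci, fpr, tpr, thr)


def auc_brute_force(scores, labels) -> float:
    """Pairwise-enumeration AUC oracle: concordant pairs + half ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_classes(labels)
    pos = scores[labels == 1][:, None]
    neg = scores[labels == 0][None, :]
    return float(((pos > neg).sum() + 0.5 * (pos == neg).sum()) / (pos.size * neg.size))


def delong_test(scores_1, scores_2, labels) -> tuple[float, float]:
    """Two-sided DeLong test for the difference of two correlated AUCs.

    Scores must be paired on identical patients. Zero variance of the
    difference (e.g. comparing a model with itself) yields p = 1 with a
    warning.
    """
    s1 = np.asarray(scores_1, dtype=float)
    s2 = np.asarray(scores_2, dtype=float)
    labels = np.asarray(labels).astype(int)
    if s1.shape != s2.shape or s1.shape[0] != labels.shape[0]:
        raise ValueError("scores must be paired on the same patients")
    _check_classes(labels)
    a1, v10_1, v01_1 = _delong_components(s1, labels)
    a2, v10_2, v01_2 = _delong_components(s2, labels)
    m, n = len(v10_1), len(v01_1)
    d10 = v10_1 - v10_2
    d01 = v01_1 - v01_2
    var = (np.var(d10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(d01, ddof=1) / n if n > 1 else 0.0
    )
    if var <= 0:
        warnings.warn("zero variance of the AUC difference (identical models?)")
        return 0.0, 1.0
    z = (a1 - a2) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class ThresholdMetrics:
    threshold: float
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float  # NaN when no positive predictions
    npv: float  # NaN when no negative predictions
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)


def _confusion_metrics(y: np.ndarray, pred: np.ndarray) -> dict[str, float]:
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return {
        "accuracy": (tp + tn) / len(y),
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
        "ppv": tp / (tp + fp) if tp + fp else np.nan,
        "npv": tn / (tn + fn) if tn + fn else np.nan,
    }


def threshold_metrics(
    scores, labels, threshold: float, n_boot: int = 2000, seed: int = 0
) -> ThresholdMetrics:
    """Confusion-matrix metrics at a threshold with stratified-bootstrap
    percentile intervals. Undefined PPV/NPV are reported as NaN, not zero."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    _check_classes(y)
    point = _confusion_metrics(y, (scores >= threshold).astype(int))

    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    boots: dict[str, list[float]] = {k: [] for k in point}
    for _ in range(n_boot):
        idx = np.concatenate([
            rng.choice(idx_pos, idx_pos.size, replace=True),
            rng.choice(idx_neg, idx_neg.size, replace=True),
        ])
        bm = _confusion_metrics(y[idx], (scores[idx] >= threshold).astype(int))
        for k, v in bm.items():
            boots[k].append(v)
    ci = {
        k: tuple(np.nanpercentile(v, [2.5, 97.5]).tolist()) for k, v in boots.items()
    }
    return ThresholdMetrics(threshold, point["accuracy"], point["sensitivity"],
                            point["specificity"], point["ppv"], point["npv"], ci)


def hosmer_lemeshow(
    probs, labels, groups: int = 10
) -> tuple[float, int, float]:
    """Hosmer-Lemeshow goodness-of-fit test on deciles of predicted risk.

    Returns (chi-square, df, p) with df = groups - 2; ties are kept in one
    group, and groups collapsing to fewer bins reduce df with a warning.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(y) < 5 * groups:
        raise ValueError(f"need at least {5 * groups} observations for {groups} groups")
    bins = pd.qcut(probs, groups, duplicates="drop")
    g = bins.categories.size
    if g < groups:
        warnings.warn(f"tied probabilities reduced groups from {groups} to {g}")
    chi2 = 0.0
    frame = pd.DataFrame({"p": probs, "y": y, "bin": bins})
    for _, grp in frame.groupby("bin", observed=True):
        n_g = len(grp)
        if n_g == 0:
            continue
        o = grp["y"].sum()
        e = grp["p"].sum()
        denom = e * (1.0 - e / n_g)
        if denom <= 0:
            denom = np.finfo(float).tiny
        chi2 += (o - e) ** 2 / denom
    df = g - 2
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return float(chi2), int(df), p


@dataclass
class CalibrationResult:
    mean_predicted: np.ndarray
    observed: np.ndarray
    band_lo: np.ndarray
    band_hi: np.ndarray
    hl_chi2: float
    hl_df: int
    hl_p: float


def calibration_curve(
    probs, labels, n_bins: int = 10, n_boot: int = 1000, seed: int = 0
) -> CalibrationResult:
    """Binned observed-vs-predicted curve with percentile bootstrap bands.

    Bins are quantiles of predicted risk (fixed across bootstrap resamples);
    resampling is stratified by class. The Hosmer-Lemeshow statistic on the
    same grouping is attached.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(y) < 20:
        raise ValueError("need at least 20 observations")
    edges = np.unique(np.quantile(probs, np.linspace(0, 1, n_bins + 1)))
    if edges.size < 3:
        edges = np.array([probs.min() - 1e-9, np.median(probs), probs.max() + 1e-9])
    which = np.clip(np.searchsorted(edges, probs, side="right") - 1, 0, edges.size - 2)

    def curve(p, yy, w):
        mp, ob = [], []
        for b in range(edges.size - 1):
            sel = w == b
            if sel.any():
                mp.append(p[sel].mean())
                ob.append(yy[sel].mean())
            else:
                mp.append(np.nan)
                ob.append(np.nan)
        return np.array(mp), np.array(ob)

    mean_pred, observed = curve(probs, y, which)

    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    boot = np.full((n_boot, edges.size - 1), np.nan)
    for i in range(n_boot):
        idx = np.concatenate([
            rng.choice(idx_pos, idx_pos.size, replace=True),
            rng.choice(idx_neg, idx_neg.size, replace=True),
        ])
        _, ob = curve(probs[idx], y[idx], which[idx])
        boot[i] = ob
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lo = np.nanpercentile(boot, 2.5, axis=0)
        hi = np.nanpercentile(boot, 97.5, axis=0)

    try:
        chi2, df, p = hosmer_lemeshow(probs, y)
    except ValueError:
        chi2, df, p = np.nan, 0, np.nan
    return CalibrationResult(mean_pred, observed, lo, hi, chi2, df, p)


@dataclass
class DecisionCurve:
    thresholds: np.ndarray
    net_benefit_model: np.ndarray
    net_benefit_all: np.ndarray
    net_benefit_none: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "model": self.net_benefit_model,
            "treat_all": self.net_benefit_all,
            "treat_none": self.net_benefit_none,
        })


def plot_evaluation(
    roc: ROCResult,
    calibration: CalibrationResult,
    dca: DecisionCurve,
    path,
) -> None:
    """Render ROC, calibration and decision curves to one SVG/PNG panel."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (a, b, c) = plt.subplots(1, 3, figsize=(12, 3.6))
    a.plot(roc.fpr, roc.tpr, lw=1.5,
           label=f"AUC {roc.auc:.3f} ({roc.ci95[0]:.3f}-{roc.ci95[1]:.3f})")
    a.plot([0, 1], [0, 1], "k--", lw=0.7)
    a.set_xlabel("1 - specificity")
    a.set_ylabel("sensitivity")
    a.legend(fontsize=8)

    ok = np.isfinite(calibration.mean_predicted)
    b.plot([0, 1], [0, 1], "k--", lw=0.7)
    b.fill_between(calibration.mean_predicted[ok], calibration.band_lo[ok],
                   calibration.band_hi[ok], alpha=0.25)
    b.plot(calibration.mean_predicted[ok], calibration.observed[ok], "o-", ms=3)
    b.set_xlabel("predicted probability")
    b.set_ylabel("observed frequency")
    b.set_title(f"Hosmer-Lemeshow p = {calibration.hl_p:.3f}", fontsize=9)

    c.plot(dca.thresholds, dca.net_benefit_model, label="model")
    c.plot(dca.thresholds, dca.net_benefit_all, label="treat all")
    c.plot(dca.thresholds, dca.net_benefit_none, label="treat none")
    c.set_ylim(bottom=-0.1)
    c.set_xlabel("threshold probability")
    c.set_ylabel("net benefit")
    c.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def decision_curve(probs, labels, thresholds=None) -> DecisionCurve:
    """Decision-curve analysis: net benefit of acting on the model versus
    treat-all and treat-none across threshold probabilities."""
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(int)
    if thresholds is None:
        thresholds = np.linspace(0.01, 0.99, 99)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(y)
    pi = y.mean()
    odds = thresholds / (1.0 - thresholds)
    nb_model = np.empty_like(thresholds)
    for i, t in enumerate(thresholds):
        pred = probs >= t
        tp = float((pred & (y == 1)).sum())
        fp = float((pred & (y == 0)).sum())
        nb_model[i] = tp / n - fp / n * odds[i]
    nb_all = pi - (1.0 - pi) * odds
    return DecisionCurve(thresholds, nb_model, nb_all, np.zeros_like(thresholds))
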