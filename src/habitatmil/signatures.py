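"""Clinicoradiological signature, machine-learning signatures, and the
fusion nomogram.

Clinicoradiological modeling follows the classical two-step screen: one
logistic fit per candidate variable (univariate), with variables at
p < 0.05 advancing to a joint (multivariate) fit whose p < 0.05 survivors
are the independent predictors. Odds ratios are exp(coefficient) with Wald
95% intervals.

Radiomic/MIL signatures are fitted by a configurable model zoo (logistic
regression, SVM, random forest, extra trees, two gradient-boosted-tree
variants, and an MLP) with grid search over seeded stratified 5-fold CV
maximizing mean AUC; the classification threshold is Youden's J on the
training ROC, frozen for the test set.

The nomogram re-parameterizes a logistic model over {age, treatment, MLNSD,
Habitat_Rad score, MIL_Rad score} into 0-100 point scales per variable; the
probability implied by total points equals the underlying logistic
probability exactly (the point scale is a re-parameterization, not an
approximation).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "LogisticFitResult",
    "univariate_screen",
    "multivariate_fit",
    "SignatureModel",
    "ZOO_ALGORITHMS",
    "train_signature",
    "fit_signature",
    "Nomogram",
    "build_nomogram",
    "apply_nomogram",
]


@dataclass(frozen=True)
class LogisticFitResult:
    """Coefficient, odds ratio and Wald interval for one model term."""

    variable: str
    coefficient: float
    std_error: float
    p_value: float
    flagged_separation: bool = False

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.coefficient))

    @property
    def ci95(self) -> tuple[float, float]:
        lo = np.exp(self.coefficient - 1.96 * self.std_error)
        hi = np.exp(self.coefficient + 1.96 * self.std_error)
        return float(lo), float(hi)


def _encode(clinical: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix: treatment is coded NACRT=1, NACT=0."""
    X = clinical.copy()
    if "treatment" in X.columns and X["treatment"].dtype == object:
        X["treatment"] = (X["treatment"] == "NACRT").astype(float)
    return X.astype(float)


def _logit_fit(X: pd.DataFrame, y: np.ndarray) -> tuple[sm.Logit, bool]:
    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    flagged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", True) or np.any(
                np.abs(res.params) > 50
            ):
                raise RuntimeError("separation suspected")
        except Exception:
            # complete/quasi-separation: fall back to a ridge-penalized fit
            flagged = True
            res = model.fit_regularized(alpha=1.0, L1_wt=0.0, disp=0, maxiter=500)
    return res, flagged


def univariate_screen(
    clinical: pd.DataFrame, labels: np.ndarray, alpha: float = 0.05
) -> tuple[dict[str, LogisticFitResult], list[str]]:
    """One single-variable logistic fit per candidate.

    Returns per-variable results and the names advancing (p < alpha) to the
    multivariate fit.
    """
    y = np.asarray(labels, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("need both classes")
    X = _encode(clinical)
    results: dict[str, LogisticFitResult] = {}
    advancing = []
    for col in X.columns:
        res, flagged = _logit_fit(X[[col]], y)
        se = float(res.bse[col]) if np.isfinite(res.bse[col]) else np.inf
        p = float(res.pvalues[col]) if np.isfinite(res.pvalues[col]) else 1.0
        results[col] = LogisticFitResult(col, float(res.params[col]), se, p, flagged)
        if p < alpha:
            advancing.append(col)
    return results, advancing


def multivariate_fit(
    clinical: pd.DataFrame,
    labels: np.ndarray,
    variables: list[str],
    alpha: float = 0.05,
) -> tuple[dict[str, LogisticFitResult], list[str]]:
    """Joint logistic fit of the screened variables.

    Returns per-variable results and the retained set (p < alpha in the joint
    model). An empty ``variables`` list yields an empty retained set.
    """
    if not variables:
        return {}, []
    y = np.asarray(labels, dtype=float)
    X = _encode(clinical)[variables]
    cond = np.linalg.cond(np.corrcoef(X.values.T)) if X.shape[1] > 1 else 1.0
    if cond > 1e6:
        warnings.warn("severe collinearity among multivariate candidates")
    res, flagged = _logit_fit(X, y)
    results = {
        col: LogisticFitResult(
            col, float(res.params[col]),
            float(res.bse[col]) if np.isfinite(res.bse[col]) else np.inf,
            float(res.pvalues[col]) if np.isfinite(res.pvalues[col]) else 1.0,
            flagged,
        )
        for col in variables
    }
    retained = [v for v in variables if results[v].p_value < alpha]
    return results, retained


# ---------------------------------------------------------------------------
# Model zoo
# ---------------------------------------------------------------------------

def _zoo(seed: int) -> dict[str, tuple[object, dict]]:
    """Algorithm -> (estimator, hyperparameter grid). Grids are kept small:
    the contract is seeded grid search, not an exhaustive sweep."""
    from lightgbm import LGBMClassifier
    from xgboost import XGBClassifier

    return {
        "logistic": (
            Pipeline([("scale", StandardScaler()),
                      ("clf", LogisticRegression(max_iter=2000, random_state=seed))]),
            {"clf__C": [0.1, 1.0, 10.0]},
        ),
        "svm": (
            Pipeline([("scale", StandardScaler()),
                      ("clf", SVC(probability=True, random_state=seed))]),
            {"clf__C": [0.5, 2.0]},
        ),
        "random_forest": (
            RandomForestClassifier(random_state=seed, n_estimators=100),
            {"max_depth": [3, None]},
        ),
        "extra_trees": (
            ExtraTreesClassifier(random_state=seed, n_estimators=100),
            {"max_depth": [3, None]},
        ),
        "xgboost": (
            XGBClassifier(random_state=seed, n_estimators=50, verbosity=0,
                          eval_metric="logloss"),
            {"max_depth": [2, 3]},
        ),
        "lightgbm": (
            LGBMClassifier(random_state=seed, n_estimators=50, verbose=-1),
            {"num_leaves": [7, 15]},
        ),
        "mlp": (
            Pipeline([("scale", StandardScaler()),
                      ("clf", MLPClassifier(hidden_layer_sizes=(16,), max_iter=1000,
                                            random_state=seed))]),
            {"clf__alpha": [1e-3, 1e-1]},
        ),
    }


ZOO_ALGORITHMS = (
    "logistic", "svm", "random_forest", "extra_trees", "xgboost", "lightgbm", "mlp",
)


@dataclass
class SignatureModel:
    """A fitted scoring object mapping a feature table to probabilities."""

    algorithm: str
    feature_names: list[str]
    estimator: object
    threshold: float
    cv_auc: float
    cv_results: dict = field(default_factory=dict)

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.feature_names].to_numpy()
        return self.estimator.predict_proba(X)[:, 1]

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(table) >= self.threshold).astype(int)


def _youden_threshold(y: np.ndarray, scores: np.ndarray) -> float:
    fpr, tpr, thr = roc_curve(y, scores)
    j = tpr - fpr
    best = int(np.argmax(j))
    t = float(thr[best])
    return min(max(t, 1e-6), 1 - 1e-6)


def train_signature(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    algorithms: tuple[str, ...] = ZOO_ALGORITHMS,
    folds: int = 5,
    seed: int = 0,
) -> dict[str, SignatureModel]:
    """Grid search each zoo algorithm over seeded stratified CV (mean AUC),
    refit on the full training set, and freeze the Youden threshold."""
    y = np.asarray(labels).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"stratification guard: minority class has {counts.min()} samples "
            f"for {folds}-fold CV"
        )
    X = features.to_numpy()
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    zoo = _zoo(seed)
    out: dict[str, SignatureModel] = {}
    for algo in algorithms:
        est, grid = zoo[algo]
        gs = GridSearchCV(est, grid, scoring="roc_auc", cv=cv, refit=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gs.fit(X, y)
        train_scores = gs.predict_proba(X)[:, 1]
        out[algo] = SignatureModel(
            algorithm=algo,
            feature_names=list(features.columns),
            estimator=gs.best_estimator_,
            threshold=_youden_threshold(y, train_scores),
            cv_auc=float(gs.best_score_),
            cv_results={
                "params": [str(p) for p in gs.cv_results_["params"]],
                "mean_auc": gs.cv_results_["mean_test_score"].tolist(),
            },
        )
    return out


def fit_signature(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    algorithm: str = "logistic",
    folds: int = 5,
    seed: int = 0,
) -> SignatureModel:
    """Train a single zoo algorithm (the default workhorse for pipelines)."""
    return train_signature(features, labels, (algorithm,), folds, seed)[algorithm]


def signature_cv_auc(
    features: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    algorithm: str = "logistic",
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Mean stratified-CV AUC of one zoo algorithm at default hyperparameters."""
    y = np.asarray(labels).astype(int)
    est, _ = _zoo(seed)[algorithm]
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = cross_val_score(est, features.to_numpy(), y, scoring="roc_auc", cv=cv)
    return float(scores.mean())


# ---------------------------------------------------------------------------
# Nomogram
# ---------------------------------------------------------------------------

@dataclass
class Nomogram:
    """Point-scale re-parameterization of a logistic fusion model.

    Per-variable points are ``100 * |beta_i| * (x_i - ref_i) / S`` with the
    reference at the variable's minimum-risk end and
    ``S = max_j |beta_j| * range_j``; the variable with the largest
    |beta|*range spans exactly 0-100. Probability at total points T is
    ``sigmoid(lp_ref + S * T / 100)`` — identical to the logistic model.
    """

    variables: list[str]
    coefficients: pd.Series
    intercept: float
    references: pd.Series
    scale: float

    def points(self, row: pd.Series) -> pd.Series:
        beta = self.coefficients
        pts = 100.0 * (beta * (row[self.variables] - self.references)).abs() / self.scale
        zero = beta == 0
        pts[zero[zero].index] = 0.0
        return pts

    def total_points(self, row: pd.Series) -> float:
        return float(self.points(row).sum())

    def probability_from_points(self, total: float) -> float:
        lp_ref = self.intercept + float(
            (self.coefficients * self.references).sum()
        )
        lp = lp_ref + self.scale * total / 100.0
        return float(1.0 / (1.0 + np.exp(-lp)))

    def probability(self, row: pd.Series) -> float:
        lp = self.intercept + float((self.coefficients * row[self.variables]).sum())
        return float(1.0 / (1.0 + np.exp(-lp)))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "variables": self.variables,
            "coefficients": self.coefficients.to_dict(),
            "intercept": self.intercept,
            "references": self.references.to_dict(),
            "scale": self.scale,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def build_nomogram(inputs: pd.DataFrame, labels: np.ndarray) -> Nomogram:
    """Fit the fusion logistic model and its point scales.

    ``inputs`` columns are the nomogram variables (clinical predictors plus
    component signature probabilities). References sit at each variable's
    observed minimum-risk end, so point contributions are non-negative.
    """
    X = _encode(inputs)
    y = np.asarray(labels, dtype=float)
    res, _ = _logit_fit(X, y)
    beta = res.params.drop("const")
    lo, hi = X.min(axis=0), X.max(axis=0)
    refs = pd.Series(
        {v: (lo[v] if beta[v] >= 0 else hi[v]) for v in X.columns}
    )
    ranges = hi - lo
    scale = float((beta.abs() * ranges).max())
    if scale == 0:
        raise ValueError("all nomogram coefficients or ranges are zero")
    return Nomogram(
        variables=list(X.columns),
        coefficients=beta,
        intercept=float(res.params["const"]),
        references=refs,
        scale=scale,
    )


def render_nomogram(
    nomogram: Nomogram,
    data: pd.DataFrame,
    path: str | Path,
) -> None:
    """Render the nomogram's per-variable point scales to SVG/PNG.

    ``data`` provides the observed value range of each variable (typically
    the training table the nomogram was fitted on).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    enc = _encode(data)
    n = len(nomogram.variables)
    fig, axes = plt.subplots(n + 1, 1, figsize=(7, 1.1 * (n + 1)), sharex=True)
    for ax, var in zip(axes[:-1], nomogram.variables):
        lo, hi = enc[var].min(), enc[var].max()
        xs = np.linspace(lo, hi, 50)
        pts = [
            nomogram.points(pd.Series({v: lo if v != var else x
                                       for v in nomogram.variables}))[var]
            for x in xs
        ]
        ax.plot(pts, np.zeros_like(xs), lw=0)
        for x, p in zip(xs[::7], pts[::7]):
            ax.annotate(f"{x:.3g}", (p, 0), fontsize=6, rotation=90,
                        ha="center", va="bottom")
        ax.set_yticks([])
        ax.set_ylabel(var, rotation=0, ha="right", va="center", fontsize=8)
        ax.set_xlim(-2, 102)
    axes[-1].set_yticks([])
    axes[-1].set_ylabel("points", rotation=0, ha="right", va="center", fontsize=8)
    axes[-1].set_xlim(-2, 102)
    axes[-1].set_xlabel("points per variable (0-100)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def apply_nomogram(nomogram: Nomogram, patient: pd.Series | pd.DataFrame):
    """Total points and probability for one patient (Series) or many (frame)."""
    if isinstance(patient, pd.DataFrame):
        enc = _encode(patient)
        totals = enc.apply(nomogram.total_points, axis=1)
        probs = enc.apply(nomogram.probability, axis=1)
        return totals, probs
    enc = _encode(patient.to_frame().T).iloc[0]
    return nomogram.total_points(enc), nomogram.probability(enc)
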