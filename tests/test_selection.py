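"""Feature-selection cascade: ICC, z-scoring, t-test screen, correlation
pruning, and LASSO with cross-validated penalty."""

import numpy as np
import pandas as pd
import pytest

from habitatmil.selection import (
    SelectionConfig,
    correlation_prune,
    icc_2_1,
    icc_filter,
    lasso_select,
    run_selection_cascade,
    ttest_filter,
    zscore_fit_apply,
)


def _frame(arr, prefix="f"):
    return pd.DataFrame(arr, columns=[f"{prefix}{i}" for i in range(arr.shape[1])])


class TestICC:
    def test_identical_tables_all_kept(self):
        rng = np.random.default_rng(0)
        a = _frame(rng.normal(size=(30, 8)))
        keep, icc = icc_filter(a, a.copy())
        assert keep == list(a.columns)
        assert np.allclose(icc.values, 1.0)

    def test_independent_noise_all_dropped(self):
        rng = np.random.default_rng(1)
        a = _frame(rng.normal(size=(30, 50)))
        b = _frame(rng.normal(size=(30, 50)))
        keep, icc = icc_filter(a, b)
        assert keep == []
        assert abs(icc.mean()) < 0.15

    def test_threshold_is_inclusive(self):
        rng = np.random.default_rng(2)
        truth = rng.normal(size=(30, 6))
        a = _frame(truth + 0.3 * rng.normal(size=(30, 6)))
        b = _frame(truth + 0.3 * rng.normal(size=(30, 6)))
        _, icc = icc_filter(a, b)
        pick = float(icc.iloc[2])
        cfg = SelectionConfig(icc_threshold=pick)
        keep, _ = icc_filter(a, b, cfg)
        assert a.columns[2] in keep

    def test_matches_pingouin_oracle(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        truth = rng.normal(size=(25, 4))
        a = truth + 0.5 * rng.normal(size=(25, 4))
        b = truth + 0.5 * rng.normal(size=(25, 4))
        ours = icc_2_1(a, b)
        for j in range(4):
            long = pd.DataFrame({
                "target": np.repeat(np.arange(25), 2),
                "rater": np.tile([0, 1], 25),
                "score": np.column_stack([a[:, j], b[:, j]]).ravel(),
            })
            ref = pg.intraclass_corr(long, targets="target", raters="rater",
                                     ratings="score")
            # absolute-agreement, single-rater row (= two-way random ICC(2,1))
            icc2 = ref.loc[ref["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0]
            assert ours[j] == pytest.approx(icc2, abs=1e-8)


class TestZscore:
    def test_train_moments(self):
        rng = np.random.default_rng(0)
        (z,) = zscore_fit_apply(_frame(rng.normal(3, 5, size=(40, 6))))
        assert np.abs(z.mean(axis=0)).max() < 1e-10
        assert np.abs(z.std(axis=0, ddof=0) - 1).max() < 1e-10

    def test_population_sd_convention(self):
        (z,) = zscore_fit_apply(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(z["x"].values, [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_shift_preserved_in_standardized_units(self):
        rng = np.random.default_rng(1)
        train = _frame(rng.normal(size=(50, 3)))
        test = train + 2.0
        z_tr, z_te = zscore_fit_apply(train, test)
        shift = (z_te.mean(axis=0) - z_tr.mean(axis=0)).values
        np.testing.assert_allclose(shift, 2.0 / train.std(axis=0, ddof=0).values)

    def test_zero_sd_column_dropped(self):
        train = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        (z,) = zscore_fit_apply(train)
        assert list(z.columns) == ["a"]


class TestTTest:
    def test_strong_feature_kept(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 30)
        table = _frame(np.column_stack([y + 0.01 * rng.normal(size=60),
                                        rng.normal(size=60)]))
        keep, p = ttest_filter(table, y)
        assert "f0" in keep
        assert p["f0"] < 1e-6

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(42)
        y = np.repeat([0, 1], 100)
        table = _frame(rng.normal(size=(200, 2000)))
        keep, p = ttest_filter(table, y)
        rate = len(keep) / 2000
        assert abs(rate - 0.05) <= 0.02

    def test_strictly_below_alpha(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 20)
        table = _frame(rng.normal(size=(40, 50)))
        keep, p = ttest_filter(table, y)
        assert set(keep) == set(p.index[p < 0.05])

    def test_tiny_class_raises(self):
        table = _frame(np.random.default_rng(0).normal(size=(4, 3)))
        with pytest.raises(ValueError):
            ttest_filter(table, np.array([0, 0, 0, 1]))


class TestCorrelationPrune:
    def test_duplicate_column_removed(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        table = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=50)})
        keep = correlation_prune(table)
        assert len(keep) == 2 and "c" in keep

    def test_orthogonal_columns_kept(self):
        rng = np.random.default_rng(1)
        table = _frame(rng.normal(size=(200, 6)))
        assert correlation_prune(table) == list(table.columns)

    def test_hub_feature_removed_first(self):
        """A correlates > 0.9 with both B and C (B, C below threshold):
        A has two over-threshold partners and is deleted; B and C survive."""
        rng = np.random.default_rng(2)
        n = 2000
        b = rng.normal(size=n)
        rho = 0.76
        c = rho * b + np.sqrt(1 - rho ** 2) * rng.normal(size=n)
        a = (b + c) / np.sqrt(2 * (1 + rho))
        table = pd.DataFrame({"A": a, "B": b, "C": c})
        r = table.corr().abs()
        assert r.loc["A", "B"] > 0.9 and r.loc["A", "C"] > 0.9 and r.loc["B", "C"] < 0.9
        assert set(correlation_prune(table)) == {"B", "C"}


class TestLasso:
    def test_huge_penalty_selects_nothing(self):
        rng = np.random.default_rng(0)
        X = _frame(rng.normal(size=(80, 10)))
        y = rng.integers(0, 2, 80)
        cfg = SelectionConfig(lasso_lambda_grid=(100.0,))
        selected, coefs, lam = lasso_select(X, y, cfg)
        assert selected == [] and lam == 100.0

    def test_vanishing_penalty_matches_least_squares(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(120, 5))
        beta = np.array([1.0, -0.5, 0.3, 0.0, 0.8])
        y = X @ beta + 0.05 * rng.normal(size=120)
        cfg = SelectionConfig(lasso_lambda_grid=(1e-7,))
        _, coefs, _ = lasso_select(_frame(X), y, cfg)
        ols = np.linalg.lstsq(np.column_stack([np.ones(120), X]), y, rcond=None)[0][1:]
        np.testing.assert_allclose(coefs.values, ols, atol=1e-2)

    def test_planted_predictors_recovered(self):
        rng = np.random.default_rng(5)
        n, p, k = 400, 200, 5
        X = rng.normal(size=(n, p))
        beta = np.zeros(p)
        beta[:k] = 0.5
        y = ((X @ beta + rng.logistic(size=n)) > 0).astype(float)
        selected, _, _ = lasso_select(_frame(X), y)
        assert {f"f{i}" for i in range(k)} <= set(selected)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            SelectionConfig(lasso_lambda_grid=())


def test_cascade_stages_are_nested():
    rng = np.random.default_rng(9)
    n = 120
    y = rng.integers(0, 2, n)
    signal = y[:, None] + rng.normal(size=(n, 10))
    noise = rng.normal(size=(n, 90))
    train = _frame(np.column_stack([signal, noise]))
    retest_a = train.copy()
    retest_b = train + 0.1 * rng.normal(size=train.shape)
    report = run_selection_cascade(train, y, icc_tables=(retest_a, retest_b))
    stages = list(report.stages.values())
    for prev, cur in zip(stages, stages[1:]):
        assert set(cur) <= set(prev)
    assert len(stages[-1]) < len(stages[0])


def test_icc_stage_optional():
    rng = np.random.default_rng(10)
    y = rng.integers(0, 2, 80)
    train = _frame(rng.normal(size=(80, 30)))
    report = run_selection_cascade(train, y, icc_tables=None)
    assert "icc" not in report.stages
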