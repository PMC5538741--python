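"""Sign-constrained LASSO, cross-validation, post-selection refit,
test-set evaluation and nested-model comparison."""

import warnings
from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cpinjury.association import (
    NegativeLasso,
    NegativeLassoCV,
    bonferroni_threshold,
    compare_models_anova,
    encode_covariates,
    evaluate_test,
    refit_ols,
    split_data,
)


def active_set_oracle(X, y, pen, lam):
    """Exact constrained-LASSO solution by active-set enumeration (p <= 4).

    For every subset of penalized features allowed to be negative, solve
    the smooth quadratic restricted to that support (the L1 term is linear
    on the negative orthant), then keep the KKT-feasible solution with the
    lowest objective.
    """
    n, p = X.shape
    means, sds = X.mean(0), X.std(0)
    scales = np.where(pen & (sds > 1e-12), sds, 1.0)
    xs = (X - means) / scales
    yc = y - y.mean()
    pen_idx = np.where(pen)[0]
    free_idx = np.where(~pen)[0]
    best = None
    for active in product([0, 1], repeat=len(pen_idx)):
        act = [pen_idx[i] for i, a in enumerate(active) if a]
        cols = list(act) + list(free_idx)
        beta = np.zeros(p)
        if cols:
            A = xs[:, cols]
            g = np.array([lam if j in act else 0.0 for j in cols])
            b = np.linalg.solve(A.T @ A / n, A.T @ yc / n + g)
            for i, j in enumerate(cols):
                beta[j] = b[i]
        if any(beta[j] > 1e-12 for j in act):
            continue
        r = yc - xs @ beta
        feasible = all(
            (xs[:, j] @ r) / n >= -lam - 1e-10 for j in pen_idx if j not in act
        )
        if not feasible:
            continue
        obj = 0.5 * np.mean(r**2) + lam * np.abs(beta[pen_idx]).sum()
        if best is None or obj < best[0] - 1e-15:
            best = (obj, beta)
    return best[1]


class TestNegativeLasso:
    def test_one_sided_soft_threshold_closed_form(self):
        """Standardized feature with rho = -0.5 at lambda 0.2 gives -0.3."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        x = (x - x.mean()) / x.std()
        y = -0.5 * x
        model = NegativeLasso(alpha=0.2).fit(x[:, None], y)
        assert model.coef_std_[0] == pytest.approx(-0.3, abs=1e-6)

    def test_positive_correlation_never_retained(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        y = 0.7 * x + rng.normal(size=200) * 0.1
        for lam in (0.0, 0.05, 0.5):
            model = NegativeLasso(alpha=lam).fit(x[:, None], y)
            assert model.coef_[0] == 0.0

    def test_lambda_max_boundary(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 6))
        y = X @ (-np.abs(rng.normal(size=6))) + rng.normal(size=80)
        lam_max = NegativeLasso().lambda_max(X, y)
        at = NegativeLasso(alpha=lam_max * (1 + 1e-9)).fit(X, y)
        below = NegativeLasso(alpha=lam_max * 0.9).fit(X, y)
        assert np.all(at.coef_ == 0.0)
        assert np.any(below.coef_ < 0.0)

    def test_matches_active_set_oracle(self):
        """Coordinate descent equals the enumeration oracle (p <= 4)."""
        rng = np.random.default_rng(3)
        worst = 0.0
        for _ in range(40):
            n, p = 20, int(rng.integers(1, 5))
            X = rng.normal(size=(n, p))
            pen = rng.random(p) < 0.8
            if not pen.any():
                pen[0] = True
            y = X @ rng.normal(size=p) + rng.normal(size=n)
            lam = rng.uniform(0.01, 0.5)
            model = NegativeLasso(alpha=lam, penalized=pen, tol=1e-10).fit(X, y)
            oracle = active_set_oracle(X, y, pen, lam)
            worst = max(worst, np.abs(model.coef_std_ - oracle).max())
        assert worst < 1e-6

    def test_kkt_conditions_hold(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n, p = 120, 30
            X = rng.normal(size=(n, p))
            pen = np.ones(p, bool)
            pen[-3:] = False
            y = X @ (rng.normal(size=p) * 0.3) + rng.normal(size=n)
            model = NegativeLasso(alpha=0.1, penalized=pen, tol=1e-9).fit(X, y)
            assert model.kkt_violation(X, y) < 1e-5

    def test_objective_nonincreasing_equivalent_convergence(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 10))
        y = X @ (-np.abs(rng.normal(size=10))) + rng.normal(size=60)
        model = NegativeLasso(alpha=0.05, tol=1e-9).fit(X, y)
        assert model.converged_

    def test_nonfinite_inputs_rejected(self):
        X = np.ones((10, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            NegativeLasso().fit(X, np.ones(10))

    def test_unpenalized_covariates_free_sign(self):
        """Covariates may take positive coefficients (age effects do)."""
        rng = np.random.default_rng(6)
        X = rng.normal(size=(150, 3))
        pen = np.array([True, True, False])
        y = -1.0 * X[:, 0] + 2.5 * X[:, 2] + rng.normal(size=150) * 0.1
        model = NegativeLasso(alpha=0.01, penalized=pen).fit(X, y)
        assert model.coef_[2] > 1.0


class TestLambdaSelection:
    def test_pure_noise_selects_sparse_models(self):
        """On pure noise the CV lambda sits high and retains few features."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(60, 10))
            y = rng.normal(size=60)
            cv = NegativeLassoCV(cv=5, seed=seed).fit(X, y)
            if (cv.coef_ < 0).sum() <= 2:
                hits += 1
        assert hits >= 8

    def test_strong_signal_retains_true_features(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            X = rng.normal(size=(100, 8))
            beta = np.zeros(8)
            beta[:2] = [-2.0, -1.5]
            noise_sd = np.sqrt(np.var(X @ beta) * (1 - 0.9) / 0.9)
            y = X @ beta + rng.normal(size=100) * noise_sd
            cv = NegativeLassoCV(cv=5, seed=seed).fit(X, y)
            if cv.coef_[0] < 0 and cv.coef_[1] < 0:
                hits += 1
        assert hits >= 8

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 6))
        y = X @ (-np.abs(rng.normal(size=6))) + rng.normal(size=60)
        l1 = NegativeLassoCV(cv=5, seed=3).fit(X, y).lambda_
        l2 = NegativeLassoCV(cv=5, seed=3).fit(X, y).lambda_
        assert l1 == l2

    def test_enlargement_redundant_with_lesions_is_dropped(self):
        """When enlargement features are noisy copies of lesion features,
        selection prefers the lesion features."""
        prefer_lesion = 0
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            n = 120
            lesion = np.abs(rng.normal(size=(n, 2)))
            enlargement = lesion @ np.array([[0.8, 0.1], [0.1, 0.8]]) + rng.normal(
                size=(n, 2)
            ) * 0.4
            X = np.hstack([lesion, enlargement])
            y = lesion @ np.array([-2.0, -1.0]) + rng.normal(size=n) * 1.0
            cv = NegativeLassoCV(cv=5, seed=seed).fit(X, y)
            lesion_weight = np.abs(cv.coef_[:2]).sum()
            enlargement_weight = np.abs(cv.coef_[2:]).sum()
            if lesion_weight > enlargement_weight:
                prefer_lesion += 1
        assert prefer_lesion >= 7


class TestRefitAndEvaluation:
    @staticmethod
    def _frame(X, y, outcome="AHA", features=None):
        features = features or [f"f{i}" for i in range(X.shape[1])]
        df = pd.DataFrame(X, columns=features)
        df[outcome] = y
        return df, features

    def test_exact_linear_fit(self):
        X = np.array([[1.0], [2.0], [3.0]])
        df, feats = self._frame(X, np.array([2.0, 4.0, 6.0]))
        model = refit_ols(df, "AHA", feats, [])
        coef = model.coefficients.set_index("term")["coef"]
        assert coef["intercept"] == pytest.approx(0.0, abs=1e-10)
        assert coef["f0"] == pytest.approx(2.0, abs=1e-10)
        assert model.r2 == pytest.approx(1.0)

    def test_coefficients_within_two_se_of_truth(self):
        """OLS refit recovers known generator weights within 2 SE."""
        rng = np.random.default_rng(8)
        hits = trials = 0
        for _ in range(20):
            X = rng.normal(size=(150, 3))
            beta = np.array([-2.0, -0.5, 1.5])
            y = X @ beta + rng.normal(size=150) * 0.5
            df, feats = self._frame(X, y)
            model = refit_ols(df, "AHA", feats, [])
            rows = model.coefficients.set_index("term")
            for name, true in zip(feats, beta):
                trials += 1
                if abs(rows.loc[name, "coef"] - true) <= 2 * rows.loc[name, "se"]:
                    hits += 1
        assert hits / trials >= 0.90

    def test_perfect_predictions(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 1))
        y = 3.0 * X[:, 0] + 1.0
        df, feats = self._frame(X, y)
        model = refit_ols(df, "AHA", feats, [])
        report = evaluate_test(model, df)
        assert report.pearson_r == pytest.approx(1.0)
        assert report.relative_mean_error_pct == pytest.approx(0.0, abs=1e-8)

    def test_fisher_ci_closed_form(self):
        """r=0.6 at n=42: CI = tanh(atanh(0.6) +- 1.96/sqrt(39))."""
        rng = np.random.default_rng(10)
        n = 42
        # build data with sample correlation very close to a target
        x = rng.normal(size=n)
        e = rng.normal(size=n)
        e -= e.mean() + x * np.cov(x, e)[0, 1] / np.var(x)
        y = x + np.sqrt(1 / 0.6**2 - 1) * e / e.std() * x.std()
        df = pd.DataFrame({"f0": x, "AHA": y})
        model = refit_ols(df, "AHA", ["f0"], [])
        report = evaluate_test(model, df)
        z = np.arctanh(report.pearson_r)
        half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
        assert report.ci_low == pytest.approx(np.tanh(z - half), abs=1e-9)
        assert report.ci_high == pytest.approx(np.tanh(z + half), abs=1e-9)
        assert report.ci_low < report.pearson_r < report.ci_high

    def test_zero_variance_predictions_rejected(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({"f0": np.zeros(10), "AHA": rng.normal(size=10)})
        model = refit_ols(df, "AHA", [], [])  # intercept-only model
        with pytest.raises(ValueError):
            evaluate_test(model, df)


class TestBonferroni:
    def test_six_models(self):
        assert round(bonferroni_threshold(0.05, 6), 3) == 0.008

    def test_identity_and_arithmetic(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.05, 5) == pytest.approx(0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 3)


class TestModelComparison:
    @staticmethod
    def _fit(X, y, feature_names, covariates=()):
        df = pd.DataFrame(X, columns=feature_names)
        df["AHA"] = y
        model = refit_ols(df, "AHA", list(feature_names), list(covariates))
        return model, df

    def test_reduced_equals_full_is_skipped(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(50, 2))
        y = X @ [-1.0, -0.5] + rng.normal(size=50)
        model, df = self._fit(X, y, ["shape__a__thickness", "shape__b__thickness"])
        cmp_ = compare_models_anova(model, "cortical-only", df)
        assert cmp_.skipped and "0 df" in cmp_.reason

    def test_empty_family_is_skipped(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(50, 1))
        y = -X[:, 0] + rng.normal(size=50)
        model, df = self._fit(X, y, ["shape__a__thickness"])
        cmp_ = compare_models_anova(model, "lesion-only", df)
        assert cmp_.skipped

    def test_null_pvalues_uniform(self):
        """Dropping pure-noise features gives uniform F-test p-values."""
        rng = np.random.default_rng(14)
        pvals = []
        for _ in range(200):
            X = rng.normal(size=(50, 3))
            y = -1.0 * X[:, 0] + rng.normal(size=50)
            model, df = self._fit(
                X, y, ["shape__a__thickness", "lesion__b__WM", "lesion__c__WM"]
            )
            cmp_ = compare_models_anova(model, "cortical-only", df)
            pvals.append(cmp_.p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_power_against_strong_feature(self):
        """A dropped feature with a large true weight is detected."""
        rng = np.random.default_rng(15)
        hits = 0
        for _ in range(20):
            X = rng.normal(size=(60, 2))
            y = X @ [-1.0, -10.0] + rng.normal(size=60)
            model, df = self._fit(X, y, ["shape__a__thickness", "lesion__b__WM"])
            cmp_ = compare_models_anova(model, "cortical-only", df)
            if cmp_.p_value < 0.05:
                hits += 1
        assert hits >= 18

    def test_rss_nesting_inequality(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(50, 2))
        y = X @ [-1.0, -2.0] + rng.normal(size=50)
        model, df = self._fit(X, y, ["shape__a__thickness", "lesion__b__WM"])
        cmp_ = compare_models_anova(model, "cortical-only", df)
        assert cmp_.rss_reduced >= cmp_.rss_full
        assert cmp_.f_statistic >= 0


class TestSplit:
    @staticmethod
    def _table(n=100):
        rng = np.random.default_rng(17)
        return pd.DataFrame(
            {
                "AHA": rng.normal(size=n),
                "sex": rng.integers(0, 2, n),
                "x": rng.normal(size=n),
            },
            index=[f"s{i}" for i in range(n)],
        )

    def test_75_25_split(self):
        train, test = split_data(self._table(), "AHA", seed=0)
        assert len(train) == 75 and len(test) == 25
        assert set(train.index).isdisjoint(test.index)

    def test_same_seed_identical(self):
        t1, _ = split_data(self._table(), "AHA", seed=5)
        t2, _ = split_data(self._table(), "AHA", seed=5)
        assert list(t1.index) == list(t2.index)

    def test_stratified_by_sex(self):
        table = self._table(200)
        train, test = split_data(table, "AHA", seed=1)
        for sex in (0, 1):
            frac = (train.sex == sex).sum() / (table.sex == sex).sum()
            assert 0.70 <= frac <= 0.80

    def test_full_fraction_leaves_empty_test(self):
        train, test = split_data(self._table(), "AHA", fraction=1.0, seed=0)
        assert len(test) == 0
        model = refit_ols(train, "AHA", ["x"], [])
        with pytest.raises(ValueError):
            evaluate_test(model, test)

    def test_too_few_cases_raises(self):
        with pytest.raises(ValueError):
            split_data(self._table(10), "AHA", seed=0)

    def test_nan_outcomes_dropped(self):
        table = self._table()
        table.loc[table.index[:30], "AHA"] = np.nan
        train, test = split_data(table, "AHA", seed=0)
        assert len(train) + len(test) == 70


def test_encode_covariates_sequence_dummy():
    df = pd.DataFrame({"sequence": ["A", "B", "B"], "age": [5.0, 6.0, 7.0]})
    out = encode_covariates(df)
    assert list(out["sequence_B"]) == [0.0, 1.0, 1.0]
    assert "sequence" not in out.columns
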