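"""Structure-function association: sign-constrained LASSO per clinical score.

For each clinical score a LASSO with **non-positive** coefficients on the
injury biomarkers is fitted (injury can only reduce function), with age,
sex and scanner sequence as unpenalized, unconstrained covariates.  The
penalty weight is selected by seeded 10-fold cross-validation over a
100-point log-spaced path.  The selected support is then refitted by
ordinary least squares to obtain coefficients, standard errors, p-values
and adjusted R²; models are validated on a held-out test set via Pearson
correlation (Fisher-z confidence intervals), with Bonferroni correction
across the six scores, and nested-model F-tests compare the full model
against single-family (cortical-only / lesion-only) reductions.

The solver is coordinate descent on

    (1/2n) ||y - X beta - Z gamma||^2 + lambda * sum_j |beta_j|,
    beta_j <= 0,

with the one-sided soft-threshold update ``beta_j <- min(0, (rho_j +
lambda) / c_j)`` where ``rho_j`` is the partial-residual correlation and
``c_j`` the column scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold

from .biomarkers import ENLARGEMENT_PREFIX, LESION_PREFIX, SHAPE_PREFIX

__all__ = [
    "NegativeLasso",
    "NegativeLassoCV",
    "FittedModel",
    "EvaluationReport",
    "ModelComparison",
    "split_data",
    "fit_neg_lasso",
    "select_lambda_cv",
    "refit_ols",
    "evaluate_test",
    "bonferroni_threshold",
    "compare_models_anova",
    "encode_covariates",
    "COVARIATE_COLS",
]

COVARIATE_COLS = ("age", "sex", "sequence_B")

FAMILY_PREFIX = {
    "cortical-only": SHAPE_PREFIX,
    "lesion-only": LESION_PREFIX,
    "enlargement-only": ENLARGEMENT_PREFIX,
}


def encode_covariates(table: pd.DataFrame) -> pd.DataFrame:
    """Numeric covariate encoding: scanner sequence B as a 0/1 dummy."""
    out = table.copy()
    if "sequence" in out.columns and out["sequence"].dtype == object:
        out["sequence_B"] = (out["sequence"] == "B").astype(float)
        out = out.drop(columns=["sequence"])
    return out


# ---------------------------------------------------------------------------
# constrained LASSO
# ---------------------------------------------------------------------------


class NegativeLasso(BaseEstimator, RegressorMixin):
    """LASSO with non-positive coefficients on penalized features.

    Parameters
    ----------
    alpha : penalty weight (the lambda of the objective).
    penalized : boolean mask over columns of X; True columns carry the L1
        penalty and the ``beta_j <= 0`` constraint, False columns
        (covariates) are unpenalized and unconstrained.  None penalizes
        every column.
    max_iter, tol : coordinate-descent stopping rule (max absolute
        coefficient change on the standardized scale).

    Penalized columns are standardized internally (mean 0, unit sd) and
    covariates centred, as the objective requires; ``coef_`` is reported
    on the original scale.
    """

    def __init__(
        self,
        alpha: float = 1.0,
        penalized: np.ndarray | None = None,
        max_iter: int = 2000,
        tol: float = 1e-7,
    ):
        self.alpha = alpha
        self.penalized = penalized
        self.max_iter = max_iter
        self.tol = tol

    def _prepare(self, X: np.ndarray):
        pen = (
            np.ones(X.shape[1], dtype=bool)
            if self.penalized is None
            else np.asarray(self.penalized, dtype=bool)
        )
        if pen.shape != (X.shape[1],):
            raise ValueError("penalized mask length must match n_features")
        means = X.mean(axis=0)
        sds = X.std(axis=0)
        scales = np.where(pen & (sds > 1e-12), sds, 1.0)
        return pen, means, scales

    def fit(self, X, y) -> "NegativeLasso":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in the design or response")
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X and y are incompatible")
        n, p = X.shape
        pen, means, scales = self._prepare(X)
        xs = (X - means) / scales
        y_mean = y.mean()
        r = y - y_mean  # residual with all coefficients at zero
        beta = np.zeros(p)
        c = (xs * xs).sum(axis=0) / n  # column scales (1 for standardized)
        c = np.maximum(c, 1e-12)
        lam = float(self.alpha)

        for n_iter in range(1, self.max_iter + 1):
            max_delta = 0.0
            for j in range(p):
                xj = xs[:, j]
                rho = (xj @ r) / n + c[j] * beta[j]  # partial-residual correlation
                if pen[j]:
                    new = min(0.0, (rho + lam) / c[j])
                else:
                    new = rho / c[j]
                delta = new - beta[j]
                if delta != 0.0:
                    r -= xj * delta
                    beta[j] = new
                    max_delta = max(max_delta, abs(delta))
            if max_delta < self.tol:
                break
        self.n_iter_ = n_iter
        self.converged_ = max_delta < self.tol

        self.coef_std_ = beta.copy()
        self.coef_ = beta / scales
        self.intercept_ = y_mean - float(means @ self.coef_)
        self.penalized_mask_ = pen
        self._means = means
        self._scales = scales
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    def kkt_violation(self, X, y) -> float:
        """Maximum KKT violation at the fitted solution (standardized scale).

        For penalized ``beta_j < 0``: ``rho_j + lambda = c_j beta_j``;
        for ``beta_j = 0``: ``rho_j >= -lambda``.  Unpenalized columns
        must have ``rho_j = c_j gamma_j`` (ordinary normal equations).
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n = X.shape[0]
        xs = (X - self._means) / self._scales
        r = y - y.mean() - xs @ self.coef_std_
        c = np.maximum((xs * xs).sum(axis=0) / n, 1e-12)
        lam = float(self.alpha)
        worst = 0.0
        for j in range(X.shape[1]):
            rho = (xs[:, j] @ r) / n + c[j] * self.coef_std_[j]
            if not self.penalized_mask_[j]:
                worst = max(worst, abs(rho - c[j] * self.coef_std_[j]))
            elif self.coef_std_[j] < 0:
                worst = max(worst, abs(rho + lam - c[j] * self.coef_std_[j]))
            else:
                worst = max(worst, max(0.0, -lam - rho))
        return worst

    def lambda_max(self, X, y) -> float:
        """Smallest lambda at which every penalized coefficient is zero."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n = X.shape[0]
        pen, means, scales = self._prepare(X)
        xs = (X - means) / scales
        # partial out the unpenalized covariates first
        z = xs[:, ~pen]
        r = y - y.mean()
        if z.shape[1]:
            gamma, *_ = np.linalg.lstsq(z, r, rcond=None)
            r = r - z @ gamma
        rho = (xs[:, pen].T @ r) / n
        return float(np.max(np.maximum(-rho, 0.0), initial=0.0))


class NegativeLassoCV(BaseEstimator, RegressorMixin):
    """Cross-validated penalty selection for :class:`NegativeLasso`.

    A 100-point log-spaced path from ``lambda_max`` down to
    ``lambda_max * 1e-3`` is evaluated by seeded k-fold cross-validation;
    the lambda minimising mean squared error is refitted on all rows.
    """

    def __init__(
        self,
        penalized: np.ndarray | None = None,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 1e-3,
        cv: int = 10,
        seed: int = 0,
        max_iter: int = 2000,
        tol: float = 1e-7,
    ):
        self.penalized = penalized
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y) -> "NegativeLassoCV":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n = X.shape[0]
        if n < 2 * self.cv:
            raise ValueError(f"too few rows ({n}) for {self.cv}-fold CV")
        lam_max = NegativeLasso(penalized=self.penalized).lambda_max(X, y)
        if lam_max <= 0:
            lam_max = 1e-6  # no negatively correlated feature: path is all-null
        grid = np.geomspace(lam_max, lam_max * self.lambda_min_ratio, self.n_lambdas)
        folds = KFold(n_splits=self.cv, shuffle=True, random_state=self.seed)
        errors = np.zeros((self.cv, self.n_lambdas))
        for f, (tr, te) in enumerate(folds.split(X)):
            model = NegativeLasso(
                alpha=grid[0], penalized=self.penalized, max_iter=self.max_iter, tol=self.tol
            )
            for i, lam in enumerate(grid):  # warm start down the path
                model.alpha = lam
                model.fit(X[tr], y[tr])
                pred = model.predict(X[te])
                errors[f, i] = float(np.mean((pred - y[te]) ** 2))
        self.cv_errors_ = errors.mean(axis=0)
        self.lambdas_ = grid
        best = int(np.argmin(self.cv_errors_))
        self.lambda_ = float(grid[best])
        self.best_ = NegativeLasso(
            alpha=self.lambda_, penalized=self.penalized, max_iter=self.max_iter, tol=self.tol
        ).fit(X, y)
        self.coef_ = self.best_.coef_
        self.intercept_ = self.best_.intercept_
        return self

    def predict(self, X) -> np.ndarray:
        return self.best_.predict(X)


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------


@dataclass
class FittedModel:
    """Post-selection OLS refit of one clinical-score model."""

    outcome: str
    retained: list[str]  # features with nonzero LASSO coefficients
    covariates: list[str]
    coefficients: pd.DataFrame  # term, coef, se, p
    adj_r2: float
    r2: float
    lambda_: float
    n_train: int
    lasso_coef: pd.Series = field(repr=False, default=None)

    def design(self, table: pd.DataFrame) -> np.ndarray:
        cols = self.retained + self.covariates
        return sm.add_constant(table[cols].to_numpy(dtype=float), has_constant="add")

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        beta = self.coefficients["coef"].to_numpy()
        return self.design(table) @ beta


@dataclass
class EvaluationReport:
    outcome: str
    pearson_r: float
    ci_low: float
    ci_high: float
    p_value: float
    relative_mean_error_pct: float
    n_test: int
    significant: bool | None = None


@dataclass
class ModelComparison:
    outcome: str
    reduced_family: str
    rss_full: float
    rss_reduced: float
    df_full: int
    df_reduced: int
    f_statistic: float | None
    p_value: float | None
    skipped: bool = False
    reason: str = ""


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def split_data(
    table: pd.DataFrame,
    outcome: str,
    fraction: float = 0.75,
    seed: int = 0,
    stratify_col: str = "sex",
    min_cases: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Complete-case train/test split, stratified, rounding toward train."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    complete = table.dropna(subset=[outcome])
    if len(complete) < min_cases:
        raise ValueError(
            f"only {len(complete)} complete cases for {outcome} (< {min_cases})"
        )
    rng = np.random.default_rng(seed)
    train_idx: list = []
    strata = (
        complete.groupby(stratify_col).groups.items()
        if stratify_col in complete.columns
        else [(None, complete.index)]
    )
    for _, idx in strata:
        idx = np.asarray(list(idx))
        perm = rng.permutation(len(idx))
        n_train = int(np.ceil(fraction * len(idx)))
        train_idx.extend(idx[perm[:n_train]])
    train = complete.loc[complete.index.isin(train_idx)]
    test = complete.loc[~complete.index.isin(train_idx)]
    return train, test


def fit_neg_lasso(
    X: np.ndarray, y: np.ndarray, penalized: np.ndarray | None, lam: float, **kwargs
) -> np.ndarray:
    """Coefficients of the sign-constrained LASSO at one lambda."""
    return NegativeLasso(alpha=lam, penalized=penalized, **kwargs).fit(X, y).coef_


def select_lambda_cv(
    X: np.ndarray, y: np.ndarray, penalized: np.ndarray | None = None, seed: int = 0, **kwargs
) -> float:
    """CV-selected lambda (thin wrapper over :class:`NegativeLassoCV`)."""
    return NegativeLassoCV(penalized=penalized, seed=seed, **kwargs).fit(X, y).lambda_


def refit_ols(
    train: pd.DataFrame,
    outcome: str,
    retained: list[str],
    covariates: list[str],
    lambda_: float = np.nan,
) -> FittedModel:
    """Unconstrained OLS refit on the selected support.

    Produces per-coefficient standard errors, t-test p-values and adjusted
    R² — the post-selection quantities a pure LASSO fit does not provide.
    Rank-deficient designs are fitted by pseudo-inverse with a warning.
    """
    cols = retained + covariates
    X = sm.add_constant(train[cols].to_numpy(dtype=float), has_constant="add")
    y = train[outcome].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("rank-deficient design in OLS refit; using pseudo-inverse")
    res = sm.OLS(y, X).fit()
    coef = pd.DataFrame(
        {
            "term": ["intercept"] + cols,
            "coef": res.params,
            "se": res.bse,
            "p": res.pvalues,
        }
    )
    return FittedModel(
        outcome=outcome,
        retained=list(retained),
        covariates=list(covariates),
        coefficients=coef,
        adj_r2=float(res.rsquared_adj),
        r2=float(res.rsquared),
        lambda_=float(lambda_),
        n_train=len(train),
    )


def evaluate_test(
    model: FittedModel,
    test: pd.DataFrame,
    alpha_threshold: float | None = None,
    min_rows: int = 5,
) -> EvaluationReport:
    """Test-set Pearson correlation with Fisher-z CI and relative mean error."""
    if len(test) < min_rows:
        raise ValueError(f"test set has {len(test)} rows (< {min_rows})")
    pred = model.predict(test)
    obs = test[model.outcome].to_numpy(dtype=float)
    if np.std(pred) < 1e-12:
        raise ValueError("zero-variance predictions: correlation undefined")
    r, p = stats.pearsonr(pred, obs)
    n = len(test)
    if n > 3:
        z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
        half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
        ci_low, ci_high = float(np.tanh(z - half)), float(np.tanh(z + half))
    else:
        ci_low, ci_high = -1.0, 1.0
    mean_obs = obs.mean()
    rme = 100.0 * (pred.mean() - mean_obs) / mean_obs if mean_obs != 0 else np.nan
    return EvaluationReport(
        outcome=model.outcome,
        pearson_r=float(r),
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=float(p),
        relative_mean_error_pct=float(rme),
        n_test=n,
        significant=None if alpha_threshold is None else bool(p < alpha_threshold),
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold controlling the family-wise error at ``alpha``."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / m


def compare_models_anova(
    full: FittedModel, reduced_family: str, train: pd.DataFrame
) -> ModelComparison:
    """Nested-model F-test: full retained set vs one biomarker family.

    The reduced model keeps only the retained features of the named family
    (plus covariates), refitted on the same rows.  Degenerate nestings
    (no features dropped, or the family empty) are flagged as skipped.
    """
    if reduced_family not in FAMILY_PREFIX:
        raise ValueError(f"unknown family {reduced_family!r}")
    prefix = FAMILY_PREFIX[reduced_family]
    kept = [f for f in full.retained if f.startswith(prefix)]
    dropped = [f for f in full.retained if not f.startswith(prefix)]
    if not kept:
        return ModelComparison(
            outcome=full.outcome, reduced_family=reduced_family,
            rss_full=np.nan, rss_reduced=np.nan, df_full=0, df_reduced=0,
            f_statistic=None, p_value=None, skipped=True,
            reason=f"no retained {reduced_family} features",
        )
    if not dropped:
        return ModelComparison(
            outcome=full.outcome, reduced_family=reduced_family,
            rss_full=np.nan, rss_reduced=np.nan, df_full=0, df_reduced=0,
            f_statistic=None, p_value=None, skipped=True,
            reason="reduced model equals the full model (0 df)",
        )
    y = train[full.outcome].to_numpy(dtype=float)

    def rss_and_df(features: list[str]) -> tuple[float, int]:
        X = sm.add_constant(
            train[features + full.covariates].to_numpy(dtype=float), has_constant="add"
        )
        res = sm.OLS(y, X).fit()
        return float(res.ssr), int(res.df_resid)

    rss_f, df_f = rss_and_df(full.retained)
    rss_r, df_r = rss_and_df(kept)
    f_stat = ((rss_r - rss_f) / (df_r - df_f)) / (rss_f / df_f)
    p = float(stats.f.sf(f_stat, df_r - df_f, df_f))
    return ModelComparison(
        outcome=full.outcome, reduced_family=reduced_family,
        rss_full=rss_f, rss_reduced=rss_r, df_full=df_f, df_reduced=df_r,
        f_statistic=float(f_stat), p_value=p,
    )
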