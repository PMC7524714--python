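"""Predictor selection for the postoperative standing SOP.

The statistical pipeline is:

1. a LASSO path over a log-spaced penalty grid, on predictors standardized
   to unit SD (response centered), with coefficients reported back on the
   original scale;
2. leave-one-out cross-validation (LOOCV) of the whole path, with the
   standard error of the CV mean squared error taken over the n
   per-observation squared errors;
3. a four-model family read off the path -- ``max`` (smallest penalty),
   ``minMSE`` (penalty minimizing the LOOCV MSE), ``oneSE`` (largest
   penalty whose MSE is within one SE of the minimum) and ``min`` (largest
   penalty retaining a single predictor) -- with coefficients below a floor
   (default 1e-3) dropped from the support;
4. unpenalized OLS refits of each selected support (coefficient SEs,
   p-values, adjusted R^2 and hat-matrix LOOCV RMSE);
5. nested comparisons by likelihood-ratio test and AIC/BIC differences.

The penalized problem is solved by a warm-started, Gram-based coordinate
descent (jit-compiled), cheap enough that the full path is refit from
scratch inside every leave-one-out fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

import statsmodels.api as sm

__all__ = [
    "LassoPath",
    "SelectedModel",
    "ModelComparison",
    "EmptyModelError",
    "lasso_path",
    "loocv_mse",
    "select_models",
    "refit_linear",
    "compare_models",
    "model_family",
    "MODEL_IDS",
]

MODEL_IDS = ("max", "minMSE", "oneSE", "min")

#: ΔAIC support thresholds for preferring the larger model.
AIC_MODERATE = 4.6
AIC_VERY_STRONG = 13.8


class EmptyModelError(ValueError):
    """No model on the path retains any predictor above the floor."""


def _as_matrix(X) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(map(str, X.columns))
    X = np.asarray(X, dtype=float)
    return X, tuple(f"x{i}" for i in range(X.shape[1]))


@dataclass
class LassoPath:
    """A fitted LASSO path with optional LOOCV error curve.

    ``coefs`` has shape (n_lambda, p) and holds original-scale coefficients;
    ``lambdas`` is strictly decreasing.
    """

    lambdas: np.ndarray
    coefs: np.ndarray
    intercepts: np.ndarray
    feature_names: tuple[str, ...]
    n: int
    mse: np.ndarray | None = None
    se: np.ndarray | None = None

    def support(self, idx: int, coef_floor: float = 0.0) -> tuple[str, ...]:
        mask = np.abs(self.coefs[idx]) > coef_floor
        return tuple(np.asarray(self.feature_names)[mask])

    @property
    def has_cv(self) -> bool:
        return self.mse is not None and self.se is not None


def _standardize(X: np.ndarray, y: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD; only a fixed rescaling
    keep = sd > 1e-12
    Xs = (X[:, keep] - mu[keep]) / sd[keep]
    ybar = y.mean()
    return Xs, y - ybar, mu, sd, keep, ybar


def default_lambda_grid(X, y, n_lambdas: int = 100,
                        ratio: float = 1e-4) -> np.ndarray:
    """Log-spaced grid from lambda_max (all coefficients zero) down to
    ``ratio * lambda_max``."""
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    Xs, yc, *_ = _standardize(Xm, y)
    lam_max = float(np.max(np.abs(Xs.T @ yc)) / len(y))
    return np.geomspace(lam_max, ratio * lam_max, n_lambdas)


@njit(cache=True)
def _cd_path_gram(G: np.ndarray, c: np.ndarray, lambdas: np.ndarray,
                  n: int, tol: float, max_sweeps: int,
                  beta_init: np.ndarray) -> np.ndarray:
    """Coordinate-descent LASSO path on precomputed Gram quantities.

    Solves min_b (1/(2n))||y - Xb||^2 + lam*||b||_1 for every lam in the
    (decreasing) grid; G = X'X, c = X'y. Each lambda starts from
    ``beta_init`` (zeros select the previous lambda's solution, i.e. the
    classical warm start). Every coordinate sweep is non-increasing in the
    objective; a sweep whose largest coefficient change falls below ``tol``
    relative to the largest coefficient ends the iteration for that lambda.
    """
    p = G.shape[0]
    n_lam = len(lambdas)
    use_init = beta_init.shape[0] == n_lam
    beta = np.zeros(p)
    out = np.zeros((n_lam, p))
    for li in range(n_lam):
        if use_init:
            beta = beta_init[li].copy()
        lam_n = lambdas[li] * n
        prev_sign = np.full(p, 127, dtype=np.int8)
        tried_sign = np.full(p, 127, dtype=np.int8)
        for _ in range(max_sweeps):
            max_change = 0.0
            max_beta = 0.0
            for j in range(p):
                gjj = G[j, j]
                if gjj <= 0.0:
                    continue
                rho = c[j] - np.dot(G[j], beta) + gjj * beta[j]
                if rho > lam_n:
                    bj = (rho - lam_n) / gjj
                elif rho < -lam_n:
                    bj = (rho + lam_n) / gjj
                else:
                    bj = 0.0
                change = abs(bj - beta[j])
                if change > max_change:
                    max_change = change
                beta[j] = bj
                if abs(bj) > max_beta:
                    max_beta = abs(bj)
            if max_change <= tol * max(max_beta, 1e-12):
                break
            # once the sign pattern is stable, finish with the exact
            # piecewise-linear (KKT) solution on the active set
            sign = np.zeros(p, dtype=np.int8)
            for j in range(p):
                if beta[j] > 0.0:
                    sign[j] = 1
                elif beta[j] < 0.0:
                    sign[j] = -1
            if np.all(sign == prev_sign) and not np.all(sign == tried_sign):
                tried_sign = sign.copy()
                active = np.flatnonzero(sign != 0)
                na = len(active)
                if na > 0:
                    Ga = np.empty((na, na))
                    rhs = np.empty(na)
                    for a in range(na):
                        ja = active[a]
                        rhs[a] = c[ja] - lam_n * sign[ja]
                        for b in range(na):
                            Ga[a, b] = G[ja, active[b]]
                    sol = np.linalg.lstsq(Ga, rhs, rcond=1e-12)[0]
                    ok = True
                    for a in range(na):
                        if sol[a] * sign[active[a]] <= 0.0:
                            ok = False
                            break
                    if ok:  # stationarity of the would-be-zero coords
                        cand = np.zeros(p)
                        for a in range(na):
                            cand[active[a]] = sol[a]
                        for j in range(p):
                            if sign[j] == 0 and G[j, j] > 0.0:
                                grad = c[j] - np.dot(G[j], cand)
                                if abs(grad) > lam_n * (1.0 + 1e-9) + 1e-9:
                                    ok = False
                                    break
                    if ok:
                        beta = cand
                        break
            prev_sign = sign
        out[li] = beta
    return out


_NO_INIT = np.zeros((0, 0))


def _solve_path(Xs: np.ndarray, yc: np.ndarray, lambdas: np.ndarray,
                beta_init: np.ndarray | None = None) -> np.ndarray:
    """Standardized-scale coefficients for a decreasing penalty grid.

    Penalty convention: (1/(2n))||y - Xb||^2 + lambda ||b||_1. Exact zeros
    in the grid are solved by ordinary least squares.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    coefs = np.zeros((len(lambdas), Xs.shape[1]))
    pos = lambdas > 0
    if pos.any():
        G = Xs.T @ Xs
        c = Xs.T @ yc
        init = _NO_INIT if beta_init is None else beta_init[pos]
        coefs[pos] = _cd_path_gram(G, c, lambdas[pos], len(yc),
                                   1e-7, 10_000, init)
    if (~pos).any():
        ols = np.linalg.lstsq(Xs, yc, rcond=None)[0]
        coefs[~pos] = ols
    return coefs


def lasso_path(X, y, lambda_grid: Sequence[float] | None = None,
               n_lambdas: int = 100) -> LassoPath:
    """Fit the LASSO coefficient path.

    Predictors are standardized to unit SD and the response is centered
    before penalization; reported coefficients and intercepts are on the
    original scale. Constant predictors are dropped with a warning.
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n <= 2:
        raise ValueError("need more than 2 observations")
    if np.isnan(Xm).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")

    Xs, yc, mu, sd, keep, ybar = _standardize(Xm, y)
    if not keep.all():
        dropped = [names[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"dropping constant predictors: {dropped}",
                      stacklevel=2)
    kept_names = tuple(n_ for n_, k in zip(names, keep) if k)

    if lambda_grid is None:
        lam_max = float(np.max(np.abs(Xs.T @ yc)) / n)
        lambdas = np.geomspace(lam_max, 1e-4 * lam_max, n_lambdas)
    else:
        lambdas = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    coefs_std = _solve_path(Xs, yc, lambdas)
    coefs = coefs_std / sd[keep]
    intercepts = ybar - coefs @ mu[keep]
    return LassoPath(lambdas=lambdas, coefs=coefs, intercepts=intercepts,
                     feature_names=kept_names, n=n)


def loocv_mse(X, y, lambda_grid: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out CV error of the LASSO path.

    For every left-out observation the path is refit on the remaining n-1
    (standardized within the training fold) and the squared prediction
    error recorded. Returns per-lambda (MSE, SE) with SE = SD/sqrt(n) of
    the n per-observation squared errors.
    """
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("LOOCV needs at least 10 observations")
    lambdas = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    # full-data solution warm-starts every fold: leaving one observation
    # out perturbs the path by O(1/n), so each fold needs few sweeps
    Xs_full, yc_full, *_ = _standardize(Xm, y)
    beta_full = _solve_path(Xs_full, yc_full, lambdas)

    sq_err = np.empty((n, len(lambdas)))
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        Xs, yc, mu, sd, keep, ybar = _standardize(Xm[tr], y[tr])
        coefs_std = _solve_path(Xs, yc, lambdas,
                                beta_init=beta_full[:, keep])
        xi = (Xm[i, keep] - mu[keep]) / sd[keep]
        pred = coefs_std @ xi + ybar
        sq_err[i] = (y[i] - pred) ** 2
    mse = sq_err.mean(axis=0)
    se = sq_err.std(axis=0, ddof=1) / np.sqrt(n)
    return mse, se


def fit_lasso_with_cv(X, y, lambda_grid: Sequence[float] | None = None,
                      n_lambdas: int = 100) -> LassoPath:
    """Convenience: path plus LOOCV error curve on the same grid."""
    path = lasso_path(X, y, lambda_grid=lambda_grid, n_lambdas=n_lambdas)
    mse, se = loocv_mse(X, y, path.lambdas)
    path.mse = mse
    path.se = se
    return path


@dataclass(frozen=True)
class SelectedModel:
    """A model of the four-model family: a predictor subset, optionally
    completed by an unpenalized OLS refit."""

    model_id: str
    predictors: tuple[str, ...]
    lambda_value: float | None = None
    intercept: float | None = None
    coefficients: Mapping[str, float] | None = None
    coef_se: Mapping[str, float] | None = None
    p_values: Mapping[str, float] | None = None
    loocv_rmse: float | None = None
    r2_adj: float | None = None

    @property
    def n_predictors(self) -> int:
        return len(self.predictors)

    @property
    def fitted(self) -> bool:
        return self.coefficients is not None


def select_models(path: LassoPath,
                  coef_floor: float = 1e-3) -> dict[str, SelectedModel]:
    """Read the four-model family off a cross-validated LASSO path.

    Predictors whose original-scale coefficient magnitude falls below
    ``coef_floor`` are excluded from every support.
    """
    if not path.has_cv:
        raise ValueError("path carries no LOOCV error curve; "
                         "use fit_lasso_with_cv or attach mse/se first")
    if len(path.lambdas) == 0:
        raise EmptyModelError("empty path")

    supports = [path.support(i, coef_floor) for i in range(len(path.lambdas))]
    sizes = np.array([len(s) for s in supports])
    if sizes.max() == 0:
        raise EmptyModelError(
            "no predictor exceeds the coefficient floor anywhere on the path")

    i_max = len(path.lambdas) - 1           # smallest lambda
    i_min_mse = int(np.argmin(path.mse))
    thresh = path.mse[i_min_mse] + path.se[i_min_mse]
    i_one_se = int(np.flatnonzero(path.mse <= thresh)[0])  # largest lambda
    ones = np.flatnonzero(sizes == 1)
    if len(ones) > 0:
        i_min = int(ones[0])
    else:  # grid skipped straight past a singleton support
        nonzero = np.flatnonzero(sizes > 0)
        i_min = int(nonzero[np.argmin(sizes[nonzero])])

    out = {}
    for model_id, i in (("max", i_max), ("minMSE", i_min_mse),
                        ("oneSE", i_one_se), ("min", i_min)):
        out[model_id] = SelectedModel(model_id=model_id,
                                      predictors=supports[i],
                                      lambda_value=float(path.lambdas[i]))
    return out


def _ols(X_sub: np.ndarray, y: np.ndarray):
    Xd = sm.add_constant(X_sub, has_constant="add")
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise ValueError("rank-deficient design in refit")
    return sm.OLS(y, Xd).fit()


def refit_linear(X_subset, y, model_id: str = "custom",
                 lambda_value: float | None = None) -> SelectedModel:
    """Unpenalized OLS refit of a selected predictor subset.

    Reports coefficient SEs from the standard covariance estimator,
    two-sided t-test p-values, adjusted R^2 and the LOOCV RMSE obtained
    from the hat-matrix identity (no refitting required).
    """
    Xm, names = _as_matrix(X_subset)
    y = np.asarray(y, dtype=float)
    if Xm.shape[1] >= len(y) - 2:
        raise ValueError("support too large for a stable refit")
    res = _ols(Xm, y)
    h = res.get_influence().hat_matrix_diag
    loo = res.resid / (1.0 - h)
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    pvals = np.asarray(res.pvalues)
    return SelectedModel(
        model_id=model_id,
        predictors=names,
        lambda_value=lambda_value,
        intercept=float(params[0]),
        coefficients=dict(zip(names, params[1:])),
        coef_se=dict(zip(names, bse[1:])),
        p_values=dict(zip(names, pvals[1:])),
        loocv_rmse=float(np.sqrt(np.mean(loo**2))),
        r2_adj=float(res.rsquared_adj),
    )


@dataclass(frozen=True)
class ModelComparison:
    """Nested-model comparison: LRT plus information-criterion differences.

    ``delta_aic``/``delta_bic`` are criterion(smaller) - criterion(larger):
    positive values support the larger model.
    """

    lrt_statistic: float
    lrt_df: int
    lrt_p: float
    delta_aic: float
    delta_bic: float
    support_label: str


def _gaussian_loglik(rss: float, n: int) -> float:
    return -0.5 * n * (np.log(2.0 * np.pi * rss / n) + 1.0)


def compare_models(smaller: SelectedModel, larger: SelectedModel,
                   X, y) -> ModelComparison:
    """Likelihood-ratio test and Delta-AIC/BIC for two nested supports."""
    if not set(smaller.predictors) <= set(larger.predictors):
        raise ValueError("models are not nested")
    Xm, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    cols = {nm: i for i, nm in enumerate(names)}

    def rss_k(model: SelectedModel) -> tuple[float, int]:
        sub = Xm[:, [cols[p] for p in model.predictors]]
        res = _ols(sub, y)
        return float(res.ssr), len(model.predictors) + 1  # + intercept

    rss_s, k_s = rss_k(smaller)
    rss_l, k_l = rss_k(larger)
    ll_s = _gaussian_loglik(rss_s, n)
    ll_l = _gaussian_loglik(rss_l, n)
    lrt = max(2.0 * (ll_l - ll_s), 0.0)
    df = k_l - k_s
    p = float(stats.chi2.sf(lrt, df)) if df > 0 else 1.0

    aic_s, aic_l = 2 * k_s - 2 * ll_s, 2 * k_l - 2 * ll_l
    bic_s, bic_l = k_s * np.log(n) - 2 * ll_s, k_l * np.log(n) - 2 * ll_l
    delta_aic = float(aic_s - aic_l)
    delta_bic = float(bic_s - bic_l)
    if delta_aic > AIC_VERY_STRONG:
        label = "very strong"
    elif delta_aic > AIC_MODERATE:
        label = "moderate"
    else:
        label = "limited"
    return ModelComparison(lrt_statistic=float(lrt), lrt_df=df, lrt_p=p,
                           delta_aic=delta_aic, delta_bic=delta_bic,
                           support_label=label)


def model_family(X, y, coef_floor: float = 1e-3,
                 lambda_grid: Sequence[float] | None = None,
                 n_lambdas: int = 100):
    """The complete analysis for one cohort: cross-validated path, the four
    selected models refit by OLS, and the nested comparison chain
    min -> oneSE -> minMSE -> max.

    Returns (models, comparisons, path) where ``models`` maps model id to a
    fitted :class:`SelectedModel` and ``comparisons`` maps
    "min_vs_oneSE" / "oneSE_vs_minMSE" / "minMSE_vs_max" to
    :class:`ModelComparison` (comparisons whose supports are not nested are
    skipped).
    """
    path = fit_lasso_with_cv(X, y, lambda_grid=lambda_grid,
                             n_lambdas=n_lambdas)
    skeletons = select_models(path, coef_floor=coef_floor)

    if isinstance(X, pd.DataFrame):
        def subset(pred):
            return X.loc[:, list(pred)]
    else:
        Xm, names = _as_matrix(X)
        cols = {nm: i for i, nm in enumerate(names)}

        def subset(pred):
            return Xm[:, [cols[p] for p in pred]]

    models = {}
    for model_id, skel in skeletons.items():
        if skel.n_predictors == 0:
            models[model_id] = skel
            continue
        fitted = refit_linear(subset(skel.predictors), y, model_id=model_id,
                              lambda_value=skel.lambda_value)
        models[model_id] = replace(fitted, predictors=skel.predictors)

    chain = (("min", "oneSE"), ("oneSE", "minMSE"), ("minMSE", "max"))
    comparisons = {}
    for small_id, large_id in chain:
        small, large = models[small_id], models[large_id]
        if set(small.predictors) <= set(large.predictors) \
                and small.predictors != large.predictors:
            comparisons[f"{small_id}_vs_{large_id}"] = \
                compare_models(small, large, X, y)
    return models, comparisons, path
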