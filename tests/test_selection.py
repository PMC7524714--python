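"""LASSO path, LOOCV, the four-model family, refits and nested tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pelvisop.selection import (
    EmptyModelError,
    SelectedModel,
    _gaussian_loglik,
    compare_models,
    default_lambda_grid,
    fit_lasso_with_cv,
    lasso_path,
    loocv_mse,
    model_family,
    refit_linear,
    select_models,
)
from pelvisop.synthetic_data import (
    RESPONSE,
    GeneratorConfig,
    generate_cohort,
    predictor_matrix,
)


def toy_data(rng, n=60, p=5, sd=1.0):
    X = rng.normal(0, 1, (n, p))
    beta = np.array([2.0, -1.0, 0.0, 0.0, 0.5])[:p]
    y = 1.5 + X @ beta + rng.normal(0, sd, n)
    return X, y


def ols_oracle(X, y):
    """Normal-equations OLS with intercept."""
    Xd = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(Xd.T @ Xd, Xd.T @ y)


def test_lambda_above_lambda_max_kills_everything(rng):
    X, y = toy_data(rng)
    grid = default_lambda_grid(X, y)
    path = lasso_path(X, y, lambda_grid=[10 * grid[0]])
    assert np.allclose(path.coefs, 0.0)


def test_lambda_zero_equals_ols_oracle(rng):
    X, y = toy_data(rng)
    path = lasso_path(X, y, lambda_grid=[0.0])
    oracle = ols_oracle(X, y)
    assert np.allclose(path.coefs[0], oracle[1:], atol=1e-6)
    assert np.isclose(path.intercepts[0], oracle[0], atol=1e-6)


def test_orthonormal_design_soft_thresholding(rng):
    # columns with exact zero mean and unit SD, mutually orthogonal
    x1 = np.tile([1.0, -1.0], 8)
    x2 = np.tile([1.0, 1.0, -1.0, -1.0], 4)
    X = np.column_stack([x1, x2])
    y = rng.normal(0, 1, 16)
    bhat = X.T @ (y - y.mean()) / len(y)  # OLS on standardized design
    for lam in (0.05, 0.2, 0.8):
        path = lasso_path(X, y, lambda_grid=[lam])
        expected = np.sign(bhat) * np.maximum(np.abs(bhat) - lam, 0.0)
        assert np.allclose(path.coefs[0], expected, atol=1e-7)


def test_constant_predictor_dropped_with_warning(rng):
    X, y = toy_data(rng, p=3)
    X[:, 1] = 4.2
    with pytest.warns(UserWarning, match="constant"):
        path = lasso_path(X, y, lambda_grid=[0.01])
    assert len(path.feature_names) == 2


def test_against_sklearn_cross_check(rng):
    # independent implementation of the same penalized objective
    from sklearn.linear_model import lasso_path as sk_lasso_path
    from pelvisop.selection import _standardize, _solve_path

    X, y = toy_data(rng, n=80, p=5)
    grid = default_lambda_grid(X, y, n_lambdas=30)
    Xs, yc, *_ = _standardize(X, y)
    mine = _solve_path(Xs, yc, grid)
    _, theirs, _ = sk_lasso_path(Xs, yc, alphas=grid, tol=1e-12,
                                 max_iter=100_000)
    assert np.abs(mine - theirs.T).max() < 1e-7


def test_loocv_matches_hat_matrix_identity_at_lambda_zero(rng):
    X, y = toy_data(rng, n=20, p=3)
    mse, se = loocv_mse(X, y, [0.0])
    Xd = np.column_stack([np.ones(len(y)), X])
    H = Xd @ np.linalg.solve(Xd.T @ Xd, Xd.T)
    resid = y - H @ y
    loo = resid / (1.0 - np.diag(H))
    assert np.isclose(mse[0], np.mean(loo**2), atol=1e-8)
    assert np.isclose(se[0], np.std(loo**2, ddof=1) / np.sqrt(len(y)),
                      atol=1e-8)


def test_loocv_noiseless_single_predictor(rng):
    X = rng.normal(0, 1, (30, 1))
    y = 3.0 * X[:, 0] + 1.0
    grid = default_lambda_grid(X, y)
    mse, _ = loocv_mse(X, y, grid)
    assert mse[-1] < 1e-6  # smallest penalty: essentially OLS, zero noise


def test_loocv_permuted_response_floor_is_response_variance(rng):
    X = rng.normal(0, 1, (100, 5))
    y = rng.permutation(rng.normal(0, 2.0, 100))
    grid = default_lambda_grid(X, y)
    mse, _ = loocv_mse(X, y, grid)
    assert abs(mse.min() - y.var()) / y.var() < 0.2


def test_select_models_single_predictor_truth(rng):
    X = rng.normal(0, 1, (80, 4))
    y = 2.5 * X[:, 0] + rng.normal(0, 0.5, 80)
    path = fit_lasso_with_cv(pd.DataFrame(X, columns=list("abcd")), y)
    models = select_models(path)
    for model in models.values():
        assert "a" in model.predictors
    assert models["min"].predictors == ("a",)
    sizes = [models[k].n_predictors for k in ("min", "oneSE", "minMSE", "max")]
    assert sizes == sorted(sizes)


def test_select_models_requires_cv_and_support(rng):
    X, y = toy_data(rng)
    path = lasso_path(X, y)
    with pytest.raises(ValueError, match="LOOCV"):
        select_models(path)
    path = fit_lasso_with_cv(X, y)
    with pytest.raises(EmptyModelError):
        select_models(path, coef_floor=np.inf)


def test_refit_recovers_orthogonal_design_exactly(rng):
    x1 = np.tile([1.0, -1.0], 10)
    x2 = np.tile([1.0, 1.0, -1.0, -1.0], 5)
    X = pd.DataFrame({"u": x1, "v": x2})
    y = 4.0 + 2.0 * x1 - 3.0 * x2
    m = refit_linear(X, y)
    assert np.isclose(m.coefficients["u"], 2.0, atol=1e-10)
    assert np.isclose(m.coefficients["v"], -3.0, atol=1e-10)
    assert np.isclose(m.intercept, 4.0, atol=1e-10)


def test_refit_r2adj_below_r2(rng):
    X, y = toy_data(rng, n=40, p=4, sd=2.0)
    m = refit_linear(X, y)
    Xd = np.column_stack([np.ones(len(y)), X])
    fit = np.linalg.lstsq(Xd, y, rcond=None)[0]
    resid = y - Xd @ fit
    r2 = 1 - resid.var() / y.var()
    assert m.r2_adj <= r2 + 1e-12


def test_compare_models_identical_supports(rng):
    X, y = toy_data(rng, p=2)
    X = pd.DataFrame(X, columns=["a", "b"])
    m = refit_linear(X, y)
    c = compare_models(m, m, X, y)
    assert c.lrt_statistic == 0.0
    assert c.lrt_df == 0
    assert c.lrt_p == 1.0
    assert c.delta_aic == 0.0


def test_lrt_closed_form():
    # RSS 20 -> 10 at n = 10, one extra parameter: LRT = 10 ln 2
    lrt = 2.0 * (_gaussian_loglik(10.0, 10) - _gaussian_loglik(20.0, 10))
    assert np.isclose(lrt, 10.0 * np.log(2.0), atol=1e-12)


def test_compare_models_matches_rss_formula(rng):
    X, y = toy_data(rng, n=50, p=3)
    X = pd.DataFrame(X, columns=["a", "b", "c"])
    small = refit_linear(X[["a"]], y)
    large = refit_linear(X[["a", "b"]], y)
    c = compare_models(small, large, X, y)

    def rss(cols):
        Xd = np.column_stack([np.ones(len(y)), X[cols].to_numpy()])
        return np.sum((y - Xd @ np.linalg.lstsq(Xd, y, rcond=None)[0]) ** 2)

    expected = len(y) * np.log(rss(["a"]) / rss(["a", "b"]))
    assert np.isclose(c.lrt_statistic, expected, atol=1e-8)
    with pytest.raises(ValueError, match="nested"):
        compare_models(large, small, X, y)


def test_lrt_null_distribution_is_chi2(rng):
    # adding one pure-noise predictor: LRT ~ chi2(1) over seeded nulls
    stats_out = []
    for _ in range(400):
        X = rng.normal(0, 1, (60, 2))
        y = rng.normal(0, 1, 60)
        Xd = pd.DataFrame(X, columns=["a", "b"])
        small = SelectedModel(model_id="s", predictors=("a",))
        large = SelectedModel(model_id="l", predictors=("a", "b"))
        stats_out.append(compare_models(small, large, Xd, y).lrt_statistic)
    _, p = stats.kstest(stats_out, stats.chi2(1).cdf)
    assert p > 0.01


def test_one_se_rule_on_cv_curve(rng):
    X, y = toy_data(rng, n=60, p=5, sd=1.5)
    path = fit_lasso_with_cv(X, y)
    models = select_models(path)
    i_min = int(np.argmin(path.mse))
    lam_one_se = models["oneSE"].lambda_value
    idx = int(np.argmin(np.abs(path.lambdas - lam_one_se)))
    assert path.mse[idx] <= path.mse[i_min] + path.se[i_min] + 1e-12
    assert lam_one_se >= models["minMSE"].lambda_value


def test_scenario_b_family_end_to_end():
    df = generate_cohort(GeneratorConfig(n=400, seed=5, scenario="B"))
    models, comparisons, _ = model_family(predictor_matrix(df, "B"),
                                          df[RESPONSE])
    assert models["min"].predictors == ("standing_sop",)
    assert {"supine_sop", "standing_sop"} <= set(models["oneSE"].predictors)
    assert comparisons["min_vs_oneSE"].lrt_p < 0.001
    assert comparisons["min_vs_oneSE"].delta_aic > 13.8
    one_se = models["oneSE"]
    assert one_se.loocv_rmse < models["min"].loocv_rmse
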