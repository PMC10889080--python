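"""Penalized model selection over collinear adiposity indices.

The adiposity panel (VAT, WFM, BMI, WHR, IWB) is strongly collinear, so
ordinary least squares cannot apportion the prediction of liver traits
among the indices. This module fits ridge, lasso and elastic-net models
with *unpenalized* demographic covariates (age, sex, age^2, age x sex,
age^2 x sex), selects among the three families by nested cross-validation
(80/20 split, 10-fold outer CV for family comparison, inner CV for
hyperparameter tuning by minimum MSE), and ranks predictors by absolute
standardized coefficient.

Unpenalized covariates are concentrated out exactly: for any penalty on
the adiposity block, the optimal covariate coefficients are the OLS fit
of the partial residual, so the penalized block solves the same problem
with trait and predictors residualized on the covariate space. Ridge is
then a closed form; lasso/elastic-net use coordinate descent on the Gram
matrix. The objective is

    (1/2n) ||y - X b||^2 + lambda * (alpha ||b||_1 + (1-alpha)/2 ||b||^2)

so ``alpha=0`` is ridge, ``alpha=1`` lasso.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

__all__ = [
    "PenalizedFit",
    "SelectionResult",
    "fit_penalized",
    "nested_cv_select",
    "standardized_ranking",
    "penalized_objective",
    "lambda_max",
    "lambda_path",
]

_TOL = 1e-8
_MAX_SWEEPS = 100_000


@dataclass
class PenalizedFit:
    alpha: float
    lam: float
    coefficients: pd.Series           # penalized (standardized) predictor effects
    covariate_coefficients: np.ndarray
    mse: float
    n_sweeps: int = 0

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.mse < 0:
            raise ValueError("mse must be non-negative")


@dataclass
class SelectionResult:
    best_family: str
    best_alpha: float
    best_lambda: float
    cv_mse: dict                      # outer-CV MSE per family
    test_mse: float
    fit: PenalizedFit                 # final refit on all data
    tuning_table: pd.DataFrame        # (alpha, lambda, cv_mse) of the final tuning CV


def _check_design(X: np.ndarray, y: np.ndarray, names):
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite entries in the design or response")
    sd = X.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance predictor: {names[dead[0]]}")


def _residualize(X: np.ndarray, y: np.ndarray, covariates: np.ndarray | None):
    n = len(y)
    C = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    Q, _ = np.linalg.qr(C)
    return X - Q @ (Q.T @ X), y - Q @ (Q.T @ y), C


def penalized_objective(X, y, b, alpha, lam):
    """Value of the elastic-net objective on (already residualized) data."""
    n = len(y)
    r = y - X @ b
    return float(
        r @ r / (2 * n) + lam * (alpha * np.abs(b).sum() + 0.5 * (1 - alpha) * b @ b)
    )


def _coordinate_descent(S, c, alpha, lam, b0=None, tol=_TOL, max_sweeps=_MAX_SWEEPS):
    """Gram-matrix coordinate descent; S = X'X/n, c = X'y/n."""
    p = len(c)
    b = np.zeros(p) if b0 is None else b0.copy()
    thr = lam * alpha
    denom = np.diag(S) + lam * (1 - alpha)
    for sweep in range(1, max_sweeps + 1):
        delta = 0.0
        for j in range(p):
            r = c[j] - S[j] @ b + S[j, j] * b[j]
            new = np.sign(r) * max(abs(r) - thr, 0.0) / denom[j]
            delta = max(delta, abs(new - b[j]))
            b[j] = new
        if delta < tol:
            break
    return b, sweep


def fit_penalized(
    X,
    y,
    alpha: float,
    lam: float,
    covariates: np.ndarray | None = None,
    names=None,
    tol: float = _TOL,
) -> PenalizedFit:
    """Fit the penalized model with unpenalized covariates.

    ``X`` must be standardized and ``y`` transformed by the caller (the
    pipeline passes rank-inverse-normal liver traits). Ridge (alpha=0) is
    solved in closed form; otherwise coordinate descent to ``tol`` on the
    maximum coefficient change.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    _check_design(X, y, list(names))
    Xr, yr, C = _residualize(X, y, covariates)
    n, p = Xr.shape
    S = Xr.T @ Xr / n
    c = Xr.T @ yr / n
    sweeps = 0
    if alpha == 0.0:
        b = np.linalg.solve(S + lam * np.eye(p), c)
    else:
        b, sweeps = _coordinate_descent(S, c, alpha, lam, tol=tol)
    gamma, *_ = np.linalg.lstsq(C, y - X @ b, rcond=None)
    resid = y - X @ b - C @ gamma
    return PenalizedFit(
        alpha=alpha,
        lam=lam,
        coefficients=pd.Series(b, index=list(names)),
        covariate_coefficients=gamma,
        mse=float(resid @ resid / n),
        n_sweeps=sweeps,
    )


def lambda_max(X, y, covariates=None, alpha: float = 1.0) -> float:
    """Smallest penalty that zeroes every lasso/elastic-net coefficient."""
    Xr, yr, _ = _residualize(np.asarray(X, float), np.asarray(y, float), covariates)
    n = len(yr)
    return float(np.max(np.abs(Xr.T @ yr)) / (n * max(alpha, 1e-3)))


def lambda_path(X, y, covariates=None, alpha=1.0, n_lambda=50, ratio=1e-4):
    lmax = lambda_max(X, y, covariates, alpha)
    return np.geomspace(lmax, lmax * ratio, n_lambda)


def _cv_mse_grid(X, y, covariates, alphas, lambdas, folds):
    """Mean CV MSE over folds for every (alpha, lambda) pair.

    Ridge members of the grid reuse an eigendecomposition of the fold
    Gram matrix across the lambda path; lasso/elastic-net warm-start
    coordinate descent down the path.
    """
    n = len(y)
    mse = np.zeros((len(alphas), len(lambdas)))
    for train, test in folds:
        Xr, yr, C = _residualize(X[train], y[train], None if covariates is None else covariates[train])
        # covariate design evaluated on the held-out fold
        Ct = (np.ones((len(test), 1)) if covariates is None
              else np.column_stack([np.ones(len(test)), covariates[test]]))
        nt = len(train)
        S = Xr.T @ Xr / nt
        c = Xr.T @ yr / nt
        d, V = np.linalg.eigh(S)
        cV = V.T @ c
        for ai, alpha in enumerate(alphas):
            b_prev = None
            for li, lam in enumerate(lambdas):
                if alpha == 0.0:
                    b = V @ (cV / (d + lam))
                else:
                    b, _ = _coordinate_descent(S, c, alpha, lam, b0=b_prev, tol=1e-7)
                    b_prev = b
                gamma, *_ = np.linalg.lstsq(
                    np.ones((nt, 1)) if covariates is None
                    else np.column_stack([np.ones(nt), covariates[train]]),
                    y[train] - X[train] @ b,
                    rcond=None,
                )
                pred = X[test] @ b + Ct @ gamma
                mse[ai, li] += np.mean((y[test] - pred) ** 2)
    return mse / len(folds)


_FAMILIES = {"ridge": lambda a: a == 0.0, "lasso": lambda a: a == 1.0,
             "enet": lambda a: 0.0 < a < 1.0}


def nested_cv_select(
    X,
    y,
    covariates: np.ndarray | None = None,
    names=None,
    alpha_grid=(0.0, 0.25, 0.5, 0.75, 1.0),
    n_lambda: int = 50,
    outer_folds: int = 10,
    inner_folds: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Three-stage nested cross-validated model selection.

    1. Hold out a random 20% test set. 2. On the 80% training set, compare
    the ridge / lasso / elastic-net families by 10-fold outer CV, tuning
    (alpha, lambda) in an inner CV per outer fold by minimum MSE. 3. Tune
    the winning family on the full training set in a 10-fold CV, evaluate
    on the held-out 20%, then refit on all data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least two predictors")
    if n < 20:
        raise ValueError("need at least 20 samples for the nested CV")
    if names is None:
        names = [f"x{j}" for j in range(p)]
    _check_design(X, y, list(names))

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = max(1, int(round(0.2 * n)))
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    Xtr, ytr = X[train_idx], y[train_idx]
    ctr = None if covariates is None else covariates[train_idx]

    lambdas = lambda_path(Xtr, ytr, ctr, alpha=1.0, n_lambda=n_lambda)
    fam_alphas = {f: [a for a in alpha_grid if ok(a)] for f, ok in _FAMILIES.items()}
    fam_alphas = {f: a for f, a in fam_alphas.items() if a}

    outer = list(KFold(outer_folds, shuffle=True, random_state=seed).split(Xtr))
    cv_mse = {}
    for fam, alphas in fam_alphas.items():
        fold_mse = []
        for k, (otr, ote) in enumerate(outer):
            inner = list(
                KFold(inner_folds, shuffle=True, random_state=seed + 1 + k).split(otr)
            )
            inner_idx = [(otr[a], otr[b]) for a, b in inner]
            grid = _cv_mse_grid(Xtr, ytr, ctr, alphas, lambdas, inner_idx)
            ai, li = np.unravel_index(np.argmin(grid), grid.shape)
            fit = fit_penalized(Xtr[otr], ytr[otr], alphas[ai], lambdas[li],
                                None if ctr is None else ctr[otr], names)
            Ct = (np.ones((len(ote), 1)) if ctr is None
                  else np.column_stack([np.ones(len(ote)), ctr[ote]]))
            pred = Xtr[ote] @ fit.coefficients.to_numpy() + Ct @ fit.covariate_coefficients
            fold_mse.append(float(np.mean((ytr[ote] - pred) ** 2)))
        cv_mse[fam] = float(np.mean(fold_mse))

    best_family = min(cv_mse, key=lambda f: (cv_mse[f], f))

    # final tuning of the winner on the full training set
    alphas = fam_alphas[best_family]
    tune_folds = list(KFold(inner_folds, shuffle=True, random_state=seed + 101).split(Xtr))
    grid = _cv_mse_grid(Xtr, ytr, ctr, alphas, lambdas, tune_folds)
    ai, li = np.unravel_index(np.argmin(grid), grid.shape)
    best_alpha, best_lambda = float(alphas[ai]), float(lambdas[li])
    tuning_table = pd.DataFrame(
        [
            {"alpha": a, "lambda": l, "cv_mse": grid[i, j]}
            for i, a in enumerate(alphas)
            for j, l in enumerate(lambdas)
        ]
    )

    train_fit = fit_penalized(Xtr, ytr, best_alpha, best_lambda, ctr, names)
    Ct = (np.ones((len(test_idx), 1)) if covariates is None
          else np.column_stack([np.ones(len(test_idx)), covariates[test_idx]]))
    pred = X[test_idx] @ train_fit.coefficients.to_numpy() + Ct @ train_fit.covariate_coefficients
    test_mse = float(np.mean((y[test_idx] - pred) ** 2))

    final = fit_penalized(X, y, best_alpha, best_lambda, covariates, names)
    return SelectionResult(
        best_family=best_family,
        best_alpha=best_alpha,
        best_lambda=best_lambda,
        cv_mse=cv_mse,
        test_mse=test_mse,
        fit=final,
        tuning_table=tuning_table,
    )


def standardized_ranking(fit: PenalizedFit) -> pd.DataFrame:
    """Predictors ordered by |standardized coefficient| (ties alphabetical)."""
    coefs = fit.coefficients
    order = sorted(coefs.index, key=lambda k: (-abs(coefs[k]), k))
    return pd.DataFrame(
        {"predictor": order, "coefficient": [coefs[k] for k in order]}
    ).reset_index(drop=True)
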