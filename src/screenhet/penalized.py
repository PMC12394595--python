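"""Penalized logistic regression: elastic net by IRLS + coordinate descent.

The solver follows the familiar penalized-GLM recipe: an outer
iteratively-reweighted least-squares loop builds a quadratic approximation to
the binomial log-likelihood, and an inner cyclic coordinate-descent loop
solves the penalized weighted least-squares problem with soft-thresholding.
Fits are computed over a warm-started, log-spaced lambda path; 10-fold
cross-validated binomial deviance selects lambda.  Per-term penalty factors
are supported (a factor of zero exempts a term from shrinkage -- used for the
screening main effect and prespecified interactions in effect models).

The objective, on internally standardized predictors, is::

    -(1/n) loglik(b0, beta) + lam * sum_j pf_j * (alpha*|beta_j| + (1-alpha)/2*beta_j^2)

At ``lam = 0`` the solver reduces to IRLS and converges to the unpenalized
maximum-likelihood estimate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

_EXPIT_CLIP = 30.0


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -_EXPIT_CLIP, _EXPIT_CLIP)))


def binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    """Mean binomial deviance, -2/n * loglik."""
    eps = 1e-12
    p = np.clip(p, eps, 1.0 - eps)
    return float(-2.0 * np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


@dataclass
class ElasticNetFit:
    """A fitted elastic-net logistic regression.

    Coefficients are reported on the original predictor scale; the
    per-term standardization constants used internally are retained so that
    refits reproduce the solution and serialized models can score new data.
    """

    terms: list[str]
    coefficients: dict[str, float]
    intercept: float
    alpha_mix: float
    lambda_: float
    lambda_path: np.ndarray
    penalty_factor: dict[str, float]
    standardization: dict[str, tuple[float, float]]
    cv_folds: int = 0
    cv_seed: int = 0
    cv_deviance: np.ndarray | None = None
    fold_assignment: np.ndarray | None = field(default=None, repr=False)
    dropped_terms: list[str] = field(default_factory=list)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        lp = np.full(len(X), self.intercept)
        for t in self.terms:
            lp += self.coefficients[t] * X[t].to_numpy(float)
        return lp

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return _expit(self.linear_predictor(X))

    def to_dict(self) -> dict:
        return {
            "kind": "elastic_net_logistic",
            "terms": self.terms,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "alpha_mix": self.alpha_mix,
            "lambda": self.lambda_,
            "penalty_factor": self.penalty_factor,
            "standardization": {k: list(v) for k, v in self.standardization.items()},
            "cv_folds": self.cv_folds,
            "cv_seed": self.cv_seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ElasticNetFit":
        return cls(
            terms=list(d["terms"]),
            coefficients=dict(d["coefficients"]),
            intercept=float(d["intercept"]),
            alpha_mix=float(d["alpha_mix"]),
            lambda_=float(d["lambda"]),
            lambda_path=np.array([]),
            penalty_factor=dict(d["penalty_factor"]),
            standardization={k: (v[0], v[1]) for k, v in d["standardization"].items()},
            cv_folds=int(d.get("cv_folds", 0)),
            cv_seed=int(d.get("cv_seed", 0)),
        )


def _soft_threshold(z: float, g: float) -> float:
    if z > g:
        return z - g
    if z < -g:
        return z + g
    return 0.0


def _cd_solve(Xs: np.ndarray, y: np.ndarray, alpha: float, lam: float,
              pf: np.ndarray, beta: np.ndarray, b0: float,
              tol: float = 1e-9, max_irls: int = 60,
              max_cd: int = 100) -> tuple[np.ndarray, float]:
    """One (alpha, lam) solve, warm-started from (beta, b0).

    The inner penalized weighted least squares is solved by coordinate
    descent on the weighted Gram matrix (covariance updates), so each sweep
    is O(p^2) regardless of n.
    """
    n, p = Xs.shape
    for _ in range(max_irls):
        eta = b0 + Xs @ beta
        mu = _expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-4, None)
        z = eta + (y - mu) / w
        wn = w / n
        sw = wn.sum()
        xw = Xs * wn[:, None]          # n x p, cheap for small p
        G = xw.T @ Xs                  # Gram / n
        u = xw.sum(axis=0)             # X'W1 / n
        q = xw.T @ z                   # X'Wz / n
        v = wn @ z
        denom = np.diag(G) + lam * (1.0 - alpha) * pf
        thr = lam * alpha * pf
        beta_old_irls = beta.copy()
        b0_old_irls = b0
        for _ in range(max_cd):
            max_delta = 0.0
            for j in range(p):
                bj = beta[j]
                rho = q[j] - u[j] * b0 - G[j] @ beta + G[j, j] * bj
                new_bj = _soft_threshold(rho, thr[j]) / denom[j]
                if new_bj != bj:
                    max_delta = max(max_delta, abs(new_bj - bj))
                    beta[j] = new_bj
            new_b0 = (v - u @ beta) / sw
            if new_b0 != b0:
                max_delta = max(max_delta, abs(new_b0 - b0))
                b0 = new_b0
            if max_delta < tol:
                break
            if np.abs(beta).max(initial=0.0) > 12.0:
                break
        if max(abs(b0 - b0_old_irls),
               float(np.max(np.abs(beta - beta_old_irls), initial=0.0))) < tol * 10:
            break
        # quasi-separation guard: unpenalized terms can diverge on rare-event
        # outcomes; beyond this point further IRLS steps move predictions
        # negligibly, so the current penalized solution is returned
        if np.abs(beta).max(initial=0.0) > 12.0 or abs(b0) > 25.0:
            break
    return beta, b0


def _constant_columns(X: np.ndarray) -> np.ndarray:
    mean = X.mean(axis=0)
    return X.std(axis=0) <= 1e-10 * (1.0 + np.abs(mean))


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(_constant_columns(X), 0.0, scale)
    return (X - mean) / np.where(scale > 0, scale, 1.0), mean, scale


def _lambda_path(Xs, y, alpha, pf, nlambda, lambda_min_ratio) -> np.ndarray:
    n = len(y)
    ybar = y.mean()
    grad = np.abs(Xs.T @ (y - ybar)) / n
    penalized = pf > 0
    a = max(alpha, 1e-3)
    if penalized.any():
        lam_max = float(np.max(grad[penalized] / (a * pf[penalized])))
    else:
        lam_max = float(np.max(grad) / a) if len(grad) else 1.0
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, nlambda)


def _solve_path(Xs, y, alpha, lam_path, pf, tol=1e-9, max_irls=60,
                max_cd=100):
    p = Xs.shape[1]
    beta = np.zeros(p)
    b0 = float(np.log(np.clip(y.mean(), 1e-12, 1 - 1e-12)
                      / np.clip(1 - y.mean(), 1e-12, 1 - 1e-12)))
    out = np.empty((len(lam_path), p))
    b0s = np.empty(len(lam_path))
    for i, lam in enumerate(lam_path):
        beta, b0 = _cd_solve(Xs, y, alpha, lam, pf, beta, b0, tol=tol,
                             max_irls=max_irls, max_cd=max_cd)
        out[i] = beta
        b0s[i] = b0
    return out, b0s


def make_folds(y: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Event-stratified fold assignment, deterministic given the seed."""
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(y), dtype=np.int32)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % folds
    return assignment


def fit_elastic_net_logistic(
    X: pd.DataFrame,
    y: Sequence[float] | np.ndarray,
    alpha_mix: float = 0.5,
    folds: int = 10,
    seed: int = 0,
    penalty_factor: Mapping[str, float] | None = None,
    nlambda: int = 30,
    lambda_min_ratio: float = 1e-3,
    lambda_: float | None = None,
    tol: float = 1e-9,
) -> ElasticNetFit:
    """Fit an elastic-net logistic regression with CV-selected penalty.

    Parameters
    ----------
    X
        Numeric design table (no missing cells; imputation happens upstream).
    alpha_mix
        L1/L2 mixing in [0, 1]; 1 is the lasso, 0 is ridge.
    folds, seed
        Cross-validation folds (event-stratified) and the fold-assignment
        seed.  Lambda minimizing mean held-out binomial deviance is selected.
    penalty_factor
        Per-term multipliers on the penalty; 0 exempts a term.
    lambda_
        Fix the penalty instead of cross-validating (used by bootstrap
        refits and by nested scaled-down analyses).

    Constant columns are dropped with a warning.  Deterministic given
    ``seed``.
    """
    terms = list(X.columns)
    Xmat = X.to_numpy(float)
    yv = np.asarray(y, dtype=float)
    if np.isnan(Xmat).any():
        bad = [t for t, c in zip(terms, np.isnan(Xmat).any(axis=0)) if c]
        raise ValueError(f"design has missing cells in {bad}; impute upstream")

    const = _constant_columns(Xmat)
    dropped = [t for t, c in zip(terms, const) if c]
    if dropped:
        warnings.warn(f"dropping constant design columns {dropped}")
        Xmat = Xmat[:, ~const]
        terms = [t for t, c in zip(terms, const) if not c]
    pf = np.array([(penalty_factor or {}).get(t, 1.0) for t in terms], dtype=float)

    Xs, mean, scale = _standardize(Xmat)
    if lambda_ is not None:
        lam_path = np.array([float(lambda_)])
        cv_dev = None
        fold_assignment = None
        best = 0
    else:
        lam_path = _lambda_path(Xs, yv, alpha_mix, pf, nlambda, lambda_min_ratio)
        fold_assignment = make_folds(yv, folds, seed)
        if min(np.bincount(fold_assignment[yv == 1], minlength=folds)) < 2:
            warnings.warn("fewer than 2 events in some CV fold")
        dev = np.zeros((folds, len(lam_path)))
        for f in range(folds):
            tr = fold_assignment != f
            te = ~tr
            Xtr, mtr, str_ = _standardize(Xs[tr])
            # held-out deviance is insensitive to solver precision; fold fits
            # run at a loose tolerance, the final fit at the requested one
            betas, b0s = _solve_path(Xtr, yv[tr], alpha_mix, lam_path, pf,
                                     tol=max(tol, 1e-4), max_irls=12)
            Xte = (Xs[te] - mtr) / np.where(str_ > 0, str_, 1.0)
            etas = b0s[None, :] + Xte @ betas.T
            for i in range(len(lam_path)):
                dev[f, i] = binomial_deviance(yv[te], _expit(etas[:, i]))
        cv_dev = dev.mean(axis=0)
        best = int(np.argmin(cv_dev))

    betas, b0s = _solve_path(Xs, yv, alpha_mix, lam_path[:best + 1], pf,
                             tol=max(tol, 1e-6), max_irls=20, max_cd=50)
    # refine the selected solution to full precision, warm-started
    beta_std, b0 = _cd_solve(Xs, yv, alpha_mix, float(lam_path[best]), pf,
                             betas[best].copy(), float(b0s[best]), tol=tol)
    beta_orig = beta_std / np.where(scale > 0, scale, 1.0)
    intercept = float(b0 - (beta_orig * mean).sum())
    return ElasticNetFit(
        terms=terms,
        coefficients={t: float(b) for t, b in zip(terms, beta_orig)},
        intercept=intercept,
        alpha_mix=alpha_mix,
        lambda_=float(lam_path[best]),
        lambda_path=lam_path,
        penalty_factor={t: float(f) for t, f in zip(terms, pf)},
        standardization={t: (float(m), float(s)) for t, m, s in zip(terms, mean, scale)},
        cv_folds=0 if lambda_ is not None else folds,
        cv_seed=seed,
        cv_deviance=cv_dev,
        fold_assignment=fold_assignment,
        dropped_terms=dropped,
    )


def fit_enet_raw(Xmat: np.ndarray, y: np.ndarray, alpha_mix: float,
                 lambda_: float, pf: np.ndarray, tol: float = 1e-7,
                 init: tuple[float, np.ndarray] | None = None,
                 ) -> tuple[float, np.ndarray]:
    """Array-level single-lambda solve on the original scale.

    Used by bootstrap refits, where the lambda selected on the full data is
    held fixed and the full-data solution (``init``, on the original scale)
    warm-starts the solver.  Returns ``(intercept, beta)``.  Constant
    columns get a zero coefficient.
    """
    y = np.asarray(y, float)
    Xs, mean, scale = _standardize(Xmat)
    ok = scale > 0
    Xs = Xs[:, ok]
    if init is not None:
        b0_init, beta_init = init
        beta0 = np.asarray(beta_init, float)[ok] * scale[ok]
        b0 = float(b0_init + np.asarray(beta_init, float) @ mean)
    else:
        beta0 = np.zeros(ok.sum())
        b0 = float(np.log(np.clip(y.mean(), 1e-12, 1 - 1e-12)
                          / np.clip(1 - y.mean(), 1e-12, 1 - 1e-12)))
    beta_s, b0 = _cd_solve(Xs, y, alpha_mix, float(lambda_),
                           np.asarray(pf, float)[ok], beta0.copy(), b0, tol=tol)
    beta = np.zeros(Xmat.shape[1])
    beta[ok] = beta_s / scale[ok]
    intercept = float(b0 - beta @ mean)
    return intercept, beta


# ---------------------------------------------------------------------------
# unpenalized Newton logistic (stage-2 scale and oracles)
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    """Unpenalized logistic MLE with log-likelihood and covariance, for
    second-stage models and likelihood-ratio tests."""

    terms: list[str]
    coef: np.ndarray        # includes leading intercept
    loglik: float
    cov: np.ndarray
    n: int

    @property
    def df(self) -> int:
        return len(self.coef)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X1 = np.column_stack([np.ones(len(X)), X])
        return _expit(X1 @ self.coef)


def newton_logistic(X: np.ndarray, y: np.ndarray,
                    terms: Sequence[str] | None = None,
                    max_iter: int = 60, tol: float = 1e-10) -> LogisticFit:
    """Newton-Raphson logistic MLE (intercept added internally).

    Raises on non-convergence or a singular information matrix, with
    diagnostics naming the model terms.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    X1 = np.column_stack([np.ones(len(X)), X])
    names = ["intercept"] + list(terms or [f"x{j}" for j in range(X.shape[1])])
    eps = 1e-12

    def loglik(b: np.ndarray) -> float:
        mu = _expit(X1 @ b)
        return float(np.sum(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps)))

    beta = np.zeros(X1.shape[1])
    beta[0] = float(np.log(np.clip(y.mean(), 1e-12, 1 - 1e-12)
                           / np.clip(1 - y.mean(), 1e-12, 1 - 1e-12)))
    ll = loglik(beta)
    # small Levenberg ridge keeps the information matrix invertible when a
    # column is (near-)constant or collinear, e.g. a fully shrunk stage-1
    # linear predictor
    scale = float(np.mean(X1 ** 2, axis=0).max())
    ridge = 1e-10 * max(scale, 1.0)
    converged = False
    for _ in range(max_iter):
        mu = _expit(X1 @ beta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = X1.T @ (y - mu)
        hess = (X1 * w[:, None]).T @ X1 + ridge * np.eye(X1.shape[1])
        step = np.linalg.solve(hess, grad)
        # backtracking line search on the log-likelihood
        for _ in range(30):
            cand = beta + step
            ll_new = loglik(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step *= 0.5
        beta = beta + step
        improved = ll_new - ll
        ll = ll_new
        if np.max(np.abs(step)) < tol or (0 <= improved < 1e-12):
            converged = True
            break
    if not converged:
        raise RuntimeError(f"logistic fit did not converge for terms {names}")
    mu = _expit(X1 @ beta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    cov = np.linalg.inv((X1 * w[:, None]).T @ X1 + ridge * np.eye(X1.shape[1]))
    return LogisticFit(terms=names, coef=beta, loglik=ll, cov=cov, n=len(y))


def save_model_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=float)


def load_model_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
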