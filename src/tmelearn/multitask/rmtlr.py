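"""Regularized multi-task linear regression: a grouped elastic net fitted
by block coordinate descent.

The objective, for N samples, p features, and q tasks, is

    (1/N) sum_i ||y_i - b0 - x_i B||_2^2
        + lambda * sum_j ( g * ||B_j||_2 + h * ||B_j||_2^2 )

where ``B_j`` is the j-th feature row of the coefficient matrix (its values
across all tasks).  The group-lasso term zeroes entire rows, so a feature is
selected for all tasks or for none.  Under the default (as-printed)
convention ``g = 1 - alpha`` and ``h = alpha``; ``convention="glmnet"``
swaps the two to match the common elastic-net parameterization.

Each block update has a closed form.  With ``r_j = x_j^T R_j / N`` (the
partial-residual correlation of feature j, a length-q vector) and
``s_j = x_j^T x_j / N``:

    ||B_j|| = (2 ||r_j|| - lambda * g)_+ / (2 s_j + 2 lambda * h),
    direction r_j / ||r_j||.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from tmelearn.multitask.standardize import Standardizer

logger = logging.getLogger(__name__)


def _penalty_multipliers(alpha: float, convention: str) -> tuple[float, float]:
    if convention == "as_printed":
        return 1.0 - alpha, alpha  # group multiplier, ridge multiplier
    if convention == "glmnet":
        return alpha, 1.0 - alpha
    raise ValueError(f"unknown penalty convention {convention!r}")


@dataclass
class RMTLRModel:
    beta: np.ndarray  # p × q
    beta0: np.ndarray  # q
    lam: float
    alpha: float
    convention: str = "as_printed"
    x_standardizer: Standardizer | None = None
    y_standardizer: Standardizer | None = None
    feature_names: list[str] | None = None
    task_names: list[str] | None = None
    n_train: int = 0
    n_iter: int = 0
    converged: bool = True

    @property
    def p(self) -> int:
        return self.beta.shape[0]

    @property
    def q(self) -> int:
        return self.beta.shape[1]

    def nonzero_rows(self) -> np.ndarray:
        return np.any(self.beta != 0, axis=1)

    def to_dict(self) -> dict:
        d = {
            "beta": self.beta.tolist(),
            "beta0": self.beta0.tolist(),
            "lam": self.lam,
            "alpha": self.alpha,
            "convention": self.convention,
            "feature_names": self.feature_names,
            "task_names": self.task_names,
            "n_train": self.n_train,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }
        d["x_standardizer"] = self.x_standardizer.to_dict() if self.x_standardizer else None
        d["y_standardizer"] = self.y_standardizer.to_dict() if self.y_standardizer else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RMTLRModel":
        return cls(
            beta=np.asarray(d["beta"], dtype=float),
            beta0=np.asarray(d["beta0"], dtype=float),
            lam=float(d["lam"]),
            alpha=float(d["alpha"]),
            convention=d.get("convention", "as_printed"),
            x_standardizer=Standardizer.from_dict(d["x_standardizer"])
            if d.get("x_standardizer") else None,
            y_standardizer=Standardizer.from_dict(d["y_standardizer"])
            if d.get("y_standardizer") else None,
            feature_names=d.get("feature_names"),
            task_names=d.get("task_names"),
            n_train=int(d.get("n_train", 0)),
            n_iter=int(d.get("n_iter", 0)),
            converged=bool(d.get("converged", True)),
        )


def rmtlr_objective(X: np.ndarray, Y: np.ndarray, beta: np.ndarray, beta0: np.ndarray,
                    lam: float, alpha: float, convention: str = "as_printed") -> float:
    """Evaluate the penalized objective exactly as defined above."""
    g, h = _penalty_multipliers(alpha, convention)
    n = X.shape[0]
    resid = Y - beta0[None, :] - X @ beta
    row_norms = np.linalg.norm(beta, axis=1)
    return float(
        (resid ** 2).sum() / n + lam * (g * row_norms.sum() + h * (row_norms ** 2).sum())
    )


def lambda_max(X: np.ndarray, Y: np.ndarray, alpha: float,
               convention: str = "as_printed") -> float:
    """Smallest lambda at which every coefficient row is zero.

    At B = 0 the intercepts are the task means, so the row j stays at zero
    iff 2 ||x_j^T (Y - mean) / N|| <= lambda * g.
    """
    g, _ = _penalty_multipliers(alpha, convention)
    n = X.shape[0]
    Yc = Y - Y.mean(axis=0, keepdims=True)
    grads = X.T @ Yc / n  # p × q
    top = 2.0 * np.linalg.norm(grads, axis=1).max()
    if g == 0:
        return np.inf
    return float(top / g)


def rmtlr_fit(
    X: np.ndarray,
    Y: np.ndarray,
    lam: float,
    alpha: float,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    convention: str = "as_printed",
    beta_init: np.ndarray | None = None,
) -> RMTLRModel:
    """Fit by block coordinate descent over feature rows.

    Converges when the maximum absolute parameter change over a full sweep
    falls below ``tol``.  The objective is non-increasing across sweeps.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("non-finite values in X or Y")
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    q = Y.shape[1]
    g, h = _penalty_multipliers(alpha, convention)

    s = (X ** 2).sum(axis=0) / n  # per-feature x_j'x_j / N
    beta = np.zeros((p, q)) if beta_init is None else beta_init.copy()
    beta0 = (Y - X @ beta).mean(axis=0)
    resid = Y - beta0[None, :] - X @ beta

    n_iter = 0
    converged = False
    for sweep in range(max_iter):
        n_iter = sweep + 1
        max_change = 0.0
        for j in range(p):
            if s[j] == 0:  # constant (all-zero standardized) feature
                continue
            bj_old = beta[j]
            if np.any(bj_old):
                resid += np.outer(X[:, j], bj_old)
            r_j = X[:, j] @ resid / n
            norm_r = np.linalg.norm(r_j)
            shrunk = 2.0 * norm_r - lam * g
            if shrunk <= 0.0 or norm_r == 0.0:
                bj_new = np.zeros(q)
            else:
                scale = shrunk / (2.0 * s[j] + 2.0 * lam * h)
                bj_new = (scale / norm_r) * r_j
            if np.any(bj_new):
                resid -= np.outer(X[:, j], bj_new)
            max_change = max(max_change, float(np.abs(bj_new - bj_old).max()))
            beta[j] = bj_new
        # intercept update (exact coordinate minimizer)
        delta0 = resid.mean(axis=0)
        beta0 += delta0
        resid -= delta0[None, :]
        max_change = max(max_change, float(np.abs(delta0).max()))
        if max_change < tol:
            converged = True
            break
    if not converged:
        obj = rmtlr_objective(X, Y, beta, beta0, lam, alpha, convention)
        warnings.warn(
            f"RMTLR did not converge in {max_iter} sweeps (objective {obj:.6g})",
            RuntimeWarning,
        )
    return RMTLRModel(beta=beta, beta0=beta0, lam=lam, alpha=alpha,
                      convention=convention, n_train=n, n_iter=n_iter,
                      converged=converged)


def rmtlr_predict(model: RMTLRModel, X_new) -> np.ndarray:
    """Predict tasks for new samples; returns values on the task scale.

    Accepts an ndarray with the model's feature count or a pandas DataFrame
    with named features (missing features raise an error listing them).
    Stored standardizers, when present, are applied to the input and
    inverted on the output.
    """
    import pandas as pd

    if isinstance(X_new, pd.DataFrame):
        if model.feature_names is None:
            X_new = X_new.to_numpy(dtype=float)
        else:
            missing = [f for f in model.feature_names if f not in X_new.columns]
            if missing:
                raise ValueError(f"missing features: {missing}")
            X_new = X_new[model.feature_names].to_numpy(dtype=float)
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[1] != model.p:
        raise ValueError(
            f"feature mismatch: model has {model.p} features, input has {X_new.shape[1]}"
        )
    if model.x_standardizer is not None:
        X_new = model.x_standardizer.transform(X_new)
    pred = model.beta0[None, :] + X_new @ model.beta
    if model.y_standardizer is not None:
        pred = model.y_standardizer.inverse_transform(pred)
    return pred


def _lambda_path(lmax: float, n_lambda: int, lambda_min_ratio: float) -> np.ndarray:
    if not np.isfinite(lmax) or lmax <= 0:
        lmax = 1.0
    return np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)


def _kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [fold for fold in np.array_split(order, k)]


def rmtlr_cv_grid(
    X: np.ndarray,
    Y: np.ndarray,
    alpha_grid=(0.5,),
    n_lambda: int = 10,
    k: int = 5,
    seed: int = 0,
    lambda_min_ratio: float = 1e-3,
    tol: float = 1e-5,
    max_iter: int = 2_000,
    convention: str = "as_printed",
) -> list[dict]:
    """Mean k-fold CV error (MSE over tasks and folds) for every grid point.

    The lambda path runs geometrically from the data-derived ``lambda_max``
    down over ``n_lambda`` values, separately per alpha; fits are
    warm-started along the path.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} samples")
    folds = _kfold_indices(n, k, seed)
    results = []
    for alpha in alpha_grid:
        lmax = lambda_max(X, Y, alpha, convention)
        path = _lambda_path(lmax, n_lambda, lambda_min_ratio)
        errors = np.zeros((len(path), k))
        for f, test_idx in enumerate(folds):
            mask = np.ones(n, dtype=bool)
            mask[test_idx] = False
            X_tr, Y_tr = X[mask], Y[mask]
            X_te, Y_te = X[test_idx], Y[test_idx]
            beta_init = None
            for li, lam in enumerate(path):
                model = rmtlr_fit(X_tr, Y_tr, lam, alpha, tol=tol, max_iter=max_iter,
                                  convention=convention, beta_init=beta_init)
                beta_init = model.beta
                pred = model.beta0[None, :] + X_te @ model.beta
                errors[li, f] = float(((Y_te - pred) ** 2).mean())
        for li, lam in enumerate(path):
            results.append({"alpha": float(alpha), "lam": float(lam),
                            "cv_error": float(errors[li].mean())})
    return results


def rmtlr_cv_tune(
    X: np.ndarray,
    Y: np.ndarray,
    alpha_grid=(0.5,),
    n_lambda: int = 10,
    k: int = 5,
    seed: int = 0,
    **kwargs,
) -> tuple[float, float]:
    """Pick (lambda, alpha) minimizing the mean 5-fold CV error."""
    grid = rmtlr_cv_grid(X, Y, alpha_grid, n_lambda, k, seed, **kwargs)
    best = min(grid, key=lambda d: d["cv_error"])
    return best["lam"], best["alpha"]
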