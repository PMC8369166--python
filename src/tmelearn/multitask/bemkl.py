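"""Bayesian efficient multiple-kernel learning (multi-task variant).

A variational Bayesian regression over view-specific kernels.  The decision
function per task is

    f(x) = a^T ( sum_m e_m k_m(x, X_train) ) + b,

with kernel weights ``e`` shared across tasks and sample weights ``a`` and
bias ``b`` task-specific.  All precisions carry Gamma priors; intermediate
per-kernel outputs ``G`` link the sample weights to the combined output.
Posteriors are learned by deterministic variational (mean-field) updates,
so fitting is reproducible given inputs and hyperparameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class BEMKLPriors:
    """Gamma shape/rate hyperparameters and the intermediate-output SD."""

    alpha_lambda: float = 1.0
    beta_lambda: float = 1.0
    alpha_gamma: float = 1.0
    beta_gamma: float = 1.0
    alpha_omega: float = 1.0
    beta_omega: float = 1.0
    alpha_epsilon: float = 1.0
    beta_epsilon: float = 1.0
    sigma_g: float = 0.1


@dataclass
class BEMKLModel:
    sample_weights: np.ndarray  # N × q posterior means of a
    kernel_weights: np.ndarray  # M posterior means of e
    bias: np.ndarray  # q posterior means of b
    sample_weight_var: np.ndarray  # N × q posterior variances of a
    kernel_weight_var: np.ndarray  # M posterior variances of e
    noise_precision: float
    priors: BEMKLPriors = field(default_factory=BEMKLPriors)
    n_iter: int = 0
    kernel_sigmas: list[float] | None = None  # widths used to build the kernels

    @property
    def n_kernels(self) -> int:
        return len(self.kernel_weights)

    @property
    def n_train(self) -> int:
        return self.sample_weights.shape[0]

    def to_dict(self) -> dict:
        return {
            "sample_weights": self.sample_weights.tolist(),
            "kernel_weights": self.kernel_weights.tolist(),
            "bias": self.bias.tolist(),
            "sample_weight_var": self.sample_weight_var.tolist(),
            "kernel_weight_var": self.kernel_weight_var.tolist(),
            "noise_precision": self.noise_precision,
            "n_iter": self.n_iter,
            "kernel_sigmas": self.kernel_sigmas,
            "priors": vars(self.priors),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BEMKLModel":
        return cls(
            sample_weights=np.asarray(d["sample_weights"], dtype=float),
            kernel_weights=np.asarray(d["kernel_weights"], dtype=float),
            bias=np.asarray(d["bias"], dtype=float),
            sample_weight_var=np.asarray(d["sample_weight_var"], dtype=float),
            kernel_weight_var=np.asarray(d["kernel_weight_var"], dtype=float),
            noise_precision=float(d["noise_precision"]),
            priors=BEMKLPriors(**d.get("priors", {})),
            n_iter=int(d.get("n_iter", 0)),
            kernel_sigmas=d.get("kernel_sigmas"),
        )


def _check_kernels(kernels: list[np.ndarray], n: int) -> list[np.ndarray]:
    checked = []
    for m, K in enumerate(kernels):
        K = np.asarray(K, dtype=float)
        if K.shape != (n, n):
            raise ValueError(f"kernel {m} has shape {K.shape}, expected ({n}, {n})")
        eigmin = float(np.linalg.eigvalsh((K + K.T) / 2.0).min())
        if eigmin < -1e-6:
            raise ValueError(f"kernel {m} is not PSD (min eigenvalue {eigmin:.3g})")
        checked.append(K)
    return checked


def bemkl_fit(
    kernels: list[np.ndarray],
    Y: np.ndarray,
    priors: BEMKLPriors | None = None,
    n_iter: int = 200,
) -> BEMKLModel:
    """Run the deterministic variational updates for ``n_iter`` iterations."""
    pr = priors or BEMKLPriors()
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, q = Y.shape
    kernels = _check_kernels(kernels, n)
    M = len(kernels)
    sg2 = pr.sigma_g ** 2
    KK = sum(K @ K.T for K in kernels)  # N × N

    # posterior state
    lam_mean = np.full((n, q), pr.alpha_lambda / pr.beta_lambda)
    mu_a = np.zeros((n, q))
    var_a = np.ones((n, q))
    # data-driven init: with e = 1 and b = 0, e^T g reproduces y
    mu_G = [np.tile(Y[:, t] / M, (M, 1)) for t in range(q)]  # each M × N
    Sigma_G = np.eye(M) * sg2
    gamma_mean = np.full(q, pr.alpha_gamma / pr.beta_gamma)
    omega_mean = np.full(M, pr.alpha_omega / pr.beta_omega)
    eps_mean = pr.alpha_epsilon / pr.beta_epsilon
    mu_e = np.ones(M)
    mu_b = np.zeros(q)
    Eee = np.outer(mu_e, mu_e) + np.eye(M)
    Ebe = [mu_b[t] * mu_e for t in range(q)]
    Ebb = mu_b ** 2 + 1.0
    var_e = np.ones(M)

    yTy = (Y ** 2).sum(axis=0)
    for it in range(n_iter):
        # lambda (precisions of a) and a, per task
        Sigma_a_list = []
        for t in range(q):
            lam_mean[:, t] = (pr.alpha_lambda + 0.5) / (
                pr.beta_lambda + 0.5 * (mu_a[:, t] ** 2 + var_a[:, t])
            )
            Sigma_a = np.linalg.inv(np.diag(lam_mean[:, t]) + KK / sg2)
            rhs = sum(kernels[m] @ mu_G[t][m] for m in range(M)) / sg2
            mu_a[:, t] = Sigma_a @ rhs
            var_a[:, t] = np.diag(Sigma_a)
            Sigma_a_list.append(Sigma_a)

        # intermediate outputs G
        Sigma_G = np.linalg.inv(np.eye(M) / sg2 + eps_mean * Eee)
        for t in range(q):
            A = np.vstack([kernels[m] @ mu_a[:, t] for m in range(M)]) / sg2
            A += eps_mean * (np.outer(mu_e, Y[:, t]) - np.outer(Ebe[t], np.ones(n)))
            mu_G[t] = Sigma_G @ A

        # gamma (bias precisions), omega (kernel-weight precisions)
        gamma_mean = (pr.alpha_gamma + 0.5) / (pr.beta_gamma + 0.5 * Ebb)
        omega_mean = (pr.alpha_omega + 0.5) / (
            pr.beta_omega + 0.5 * (mu_e ** 2 + var_e)
        )

        # joint posterior of (b_1..b_q, e)
        GGt = [n * Sigma_G + mu_G[t] @ mu_G[t].T for t in range(q)]  # sum_i <g g^T>
        G1 = [mu_G[t] @ np.ones(n) for t in range(q)]  # sum_i <g>
        P = np.zeros((q + M, q + M))
        rhs = np.zeros(q + M)
        for t in range(q):
            P[t, t] = gamma_mean[t] + eps_mean * n
            P[t, q:] = P[q:, t] = eps_mean * G1[t]
            rhs[t] = eps_mean * Y[:, t].sum()
        P[q:, q:] = np.diag(omega_mean) + eps_mean * sum(GGt)
        rhs[q:] = eps_mean * sum(mu_G[t] @ Y[:, t] for t in range(q))
        Sigma_be = np.linalg.inv(P)
        mu_be = Sigma_be @ rhs
        mu_b = mu_be[:q]
        mu_e = mu_be[q:]
        var_e = np.diag(Sigma_be)[q:]
        Eee = Sigma_be[q:, q:] + np.outer(mu_e, mu_e)
        Ebe = [Sigma_be[t, q:] + mu_b[t] * mu_e for t in range(q)]
        Ebb = np.diag(Sigma_be)[:q] + mu_b ** 2

        # noise precision epsilon
        sq = 0.0
        for t in range(q):
            sq += yTy[t]
            sq -= 2.0 * Y[:, t] @ (mu_G[t].T @ mu_e + mu_b[t])
            sq += float(np.trace(Eee @ GGt[t]))
            sq += 2.0 * Ebe[t] @ G1[t]
            sq += n * Ebb[t]
        eps_mean = (pr.alpha_epsilon + 0.5 * n * q) / (pr.beta_epsilon + 0.5 * max(sq, 0.0))

        state = np.concatenate([mu_a.ravel(), mu_e, mu_b, [eps_mean]])
        if not np.isfinite(state).all():
            raise FloatingPointError(f"BEMKL update diverged at iteration {it}")

    return BEMKLModel(
        sample_weights=mu_a,
        kernel_weights=mu_e,
        bias=mu_b,
        sample_weight_var=var_a,
        kernel_weight_var=np.asarray(var_e, dtype=float),
        noise_precision=float(eps_mean),
        priors=pr,
        n_iter=n_iter,
    )


def bemkl_predict(model: BEMKLModel, test_kernels: list[np.ndarray]) -> np.ndarray:
    """Posterior predictive mean per task.

    ``test_kernels`` holds one N_test × N_train matrix per training kernel;
    the prediction is the e-weighted kernel combination times the sample
    weights, plus the task bias.
    """
    if len(test_kernels) != model.n_kernels:
        raise ValueError(
            f"expected {model.n_kernels} test kernels, got {len(test_kernels)}"
        )
    n_train = model.n_train
    combined = None
    for m, K in enumerate(test_kernels):
        K = np.atleast_2d(np.asarray(K, dtype=float))
        if K.shape[1] != n_train:
            raise ValueError(
                f"test kernel {m} has {K.shape[1]} columns, expected {n_train}"
            )
        term = model.kernel_weights[m] * K
        combined = term if combined is None else combined + term
    return combined @ model.sample_weights + model.bias[None, :]
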