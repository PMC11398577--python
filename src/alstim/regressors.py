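"""A single fit/predict contract over four regression families.

Families: ridge regression, support vector regression with linear and RBF
kernels, and Gaussian process regression.  Hyperparameters are fixed at
construction (no cross-validation inside an episode — the model queried
mid-experiment is deliberately unoptimized), and every fit is
deterministic: rows are canonically sorted before fitting so permuting
the training set cannot change the fitted function.

Also provides the bootstrap committee used by variance-based query
strategies: P models, each trained on a same-size resample (with
replacement) of the labeled set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.linear_model import Ridge
from sklearn.svm import SVR

__all__ = ["RegressorSpec", "FittedModel", "Committee", "fit", "predict", "bootstrap_committee"]

FAMILIES = ("ridge", "svr_linear", "svr_rbf", "gpr")


@dataclass(frozen=True)
class RegressorSpec:
    """One regression family with fixed hyperparameters.

    Fields irrelevant to the chosen family are stored but ignored.
    ``rbf_sigma="auto"`` resolves at fit time to
    sqrt(d * mean per-feature variance) of the training matrix, and the
    RBF kernel is exp(-||x - x'||^2 / (2 sigma^2)).
    """

    family: Literal["ridge", "svr_linear", "svr_rbf", "gpr"] = "ridge"
    ridge_lambda: float = 0.1
    svr_C: float = 1.0
    svr_epsilon: float = 0.1
    rbf_sigma: float | str = "auto"
    gpr_noise_variance: float = 1e-2
    gpr_lengthscale: float | str = "optimize"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be nonnegative")
        if self.svr_C <= 0:
            raise ValueError("svr_C must be positive")
        if self.svr_epsilon < 0:
            raise ValueError("svr_epsilon must be nonnegative")
        if self.rbf_sigma != "auto" and float(self.rbf_sigma) <= 0:
            raise ValueError("rbf_sigma must be positive or 'auto'")
        if self.gpr_noise_variance <= 0:
            raise ValueError("gpr_noise_variance must be positive")
        if self.gpr_lengthscale != "optimize" and float(self.gpr_lengthscale) <= 0:
            raise ValueError("gpr_lengthscale must be positive or 'optimize'")


@dataclass
class FittedModel:
    """Opaque fitted regressor with a deterministic predict."""

    spec: RegressorSpec
    estimator: object
    n_train: int
    d: int
    y_offset: float = 0.0  # training-target mean added back for GPR

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)


def _canonical_order(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Sort rows lexicographically by features then target.

    Makes every fit invariant to training-row permutation, including for
    solvers (libsvm SMO, L-BFGS) that are order sensitive on ties.
    """
    return np.lexsort((y,) + tuple(X[:, j] for j in range(X.shape[1] - 1, -1, -1)))


def _resolve_sigma(spec: RegressorSpec, X: np.ndarray) -> float:
    if spec.rbf_sigma != "auto":
        return float(spec.rbf_sigma)
    pooled_var = float(np.mean(X.var(axis=0)))
    sigma = np.sqrt(X.shape[1] * pooled_var)
    return sigma if sigma > 0 else 1.0


def fit(spec: RegressorSpec, X: np.ndarray, y: np.ndarray) -> FittedModel:
    """Fit one model; deterministic for fixed inputs and spec."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] == 0:
        raise ValueError("cannot fit on an empty training set")
    if X.shape[0] != y.size:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.size}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("training data contain non-finite values")

    order = _canonical_order(X, y)
    X, y = X[order], y[order]
    y_offset = 0.0

    if spec.family == "ridge":
        est = Ridge(alpha=spec.ridge_lambda, fit_intercept=True, solver="cholesky")
        est.fit(X, y)
    elif spec.family == "svr_linear":
        est = SVR(kernel="linear", C=spec.svr_C, epsilon=spec.svr_epsilon, tol=1e-6)
        est.fit(X, y)
    elif spec.family == "svr_rbf":
        sigma = _resolve_sigma(spec, X)
        est = SVR(
            kernel="rbf",
            gamma=1.0 / (2.0 * sigma**2),
            C=spec.svr_C,
            epsilon=spec.svr_epsilon,
            tol=1e-6,
        )
        est.fit(X, y)
    else:  # gpr: zero-mean prior on centered targets, RBF + white noise
        y_offset = float(y.mean())
        if spec.gpr_lengthscale == "optimize":
            kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(1.0, (1e-2, 1e2)) + WhiteKernel(
                max(spec.gpr_noise_variance, 1e-6), (1e-6, 1e1)
            )
            est = GaussianProcessRegressor(
                kernel=kernel, optimizer="fmin_l_bfgs_b", n_restarts_optimizer=0, random_state=0
            )
        else:
            kernel = ConstantKernel(1.0, "fixed") * RBF(
                float(spec.gpr_lengthscale), "fixed"
            ) + WhiteKernel(spec.gpr_noise_variance, "fixed")
            est = GaussianProcessRegressor(kernel=kernel, optimizer=None)
        est.fit(X, y - y_offset)

    return FittedModel(spec=spec, estimator=est, n_train=X.shape[0], d=X.shape[1], y_offset=y_offset)


def predict(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Predict responses for query rows; repeated calls are identical."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.d:
        raise ValueError(f"query rows have {X.shape[1]} features, model expects {model.d}")
    return np.asarray(model.estimator.predict(X), dtype=float) + model.y_offset


@dataclass
class Committee:
    """Ordered bootstrap committee sharing one RegressorSpec."""

    members: list
    spec: RegressorSpec
    bootstrap_seed: int

    @property
    def size(self) -> int:
        return len(self.members)

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        """Member predictions, shape ``(n_rows, P)``."""
        return np.column_stack([predict(m, X) for m in self.members])


def bootstrap_committee(
    spec: RegressorSpec, X: np.ndarray, y: np.ndarray, P: int, seed: int
) -> Committee:
    """Train ``P`` models on seeded same-size resamples of the labeled set.

    Each member sees ``S0`` draws with replacement from the ``S0`` labeled
    rows; draws and member order are reproducible under ``seed``.
    """
    if P < 1:
        raise ValueError(f"committee size must be >= 1, got {P}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    s0 = X.shape[0]
    if s0 < 1:
        raise ValueError("need at least one labeled sample")
    rng = np.random.default_rng(seed)
    members = []
    for _ in range(P):
        idx = rng.integers(0, s0, size=s0)
        members.append(fit(spec, X[idx], y[idx]))
    return Committee(members=members, spec=spec, bootstrap_seed=seed)
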