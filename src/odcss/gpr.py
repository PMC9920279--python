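"""Gaussian-process regression base learner.

Every predictive component (per-cluster models, the just-in-time model,
the pseudo-label confidence check and the baselines) goes through this one
wrapper around scikit-learn's ``GaussianProcessRegressor`` with a Matérn
covariance plus a white-noise term.

Targets are centered by their training mean inside the model and the mean
is added back at prediction time: a zero-prior-mean GP on raw process
concentrations would be badly specified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import warnings

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Kernel, Matern, WhiteKernel

from .config import KernelConfig

__all__ = ["GPRModel", "InsufficientDataError", "fit_gpr", "predict_gpr"]

# hyperparameter bounds, standardized-feature units
LENGTH_SCALE_BOUNDS = (1e-2, 1e3)
SIGNAL_VARIANCE_BOUNDS = (1e-3, 1e3)
NOISE_VARIANCE_BOUNDS = (1e-8, 1e1)

# jitter escalation on Cholesky failure
_JITTERS = (1e-10, 1e-8, 1e-6)


class InsufficientDataError(ValueError):
    """Raised when fewer than two training rows are available."""


@dataclass
class GPRModel:
    """A fitted GP: training data, centered-target offset and the sklearn fit."""

    X: np.ndarray
    y: np.ndarray
    y_offset: float
    gp: GaussianProcessRegressor

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def kernel_(self) -> Kernel:
        return self.gp.kernel_


def _build_kernel(cfg: KernelConfig) -> Kernel:
    return (
        ConstantKernel(cfg.signal_variance_init, SIGNAL_VARIANCE_BOUNDS)
        * Matern(length_scale=cfg.length_scale_init, length_scale_bounds=LENGTH_SCALE_BOUNDS, nu=cfg.nu)
        + WhiteKernel(cfg.noise_variance_init, NOISE_VARIANCE_BOUNDS)
    )


def fit_gpr(
    X: np.ndarray,
    y: np.ndarray,
    kernel: KernelConfig | None = None,
    seed: int = 0,
    fixed_kernel: Optional[Kernel] = None,
) -> GPRModel:
    """Fit a GP on (X, y).

    When ``kernel.optimize`` is on, hyperparameters maximize the log
    marginal likelihood starting from the configured initial values (plus
    ``n_restarts`` seeded restarts). ``fixed_kernel`` overrides everything
    and fits with those hyperparameters frozen — used when two fits must
    differ only in their training set, e.g. the pseudo-label confidence
    pair.

    Raises
    ------
    InsufficientDataError
        If fewer than 2 training rows are given.
    """
    kernel = kernel or KernelConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    if X.shape[0] < 2:
        raise InsufficientDataError("insufficient training data")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in training data")

    y_offset = float(y.mean())
    yc = y - y_offset

    if fixed_kernel is not None:
        k, optimizer, restarts = fixed_kernel.clone_with_theta(fixed_kernel.theta), None, 0
    elif kernel.optimize:
        k, optimizer, restarts = _build_kernel(kernel), "fmin_l_bfgs_b", kernel.n_restarts
    else:
        k, optimizer, restarts = _build_kernel(kernel), None, 0

    last_err: Exception | None = None
    for jitter in _JITTERS:
        gp = GaussianProcessRegressor(
            kernel=k,
            alpha=jitter,
            optimizer=optimizer,
            n_restarts_optimizer=restarts,
            normalize_y=False,
            random_state=seed,
        )
        try:
            # hyperparameters legitimately sit on their bounds for smooth or
            # noiseless data; the resulting ConvergenceWarnings are expected
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gp.fit(X, yc)
            return GPRModel(X=X, y=y, y_offset=y_offset, gp=gp)
        except np.linalg.LinAlgError as err:  # escalate jitter and retry
            last_err = err
    raise np.linalg.LinAlgError(f"kernel matrix singular after jitter escalation: {last_err}")


def predict_gpr(model: GPRModel, x: np.ndarray) -> tuple[float, float]:
    """Posterior predictive mean and variance at a single query point.

    The variance includes the fitted white-noise term (it is the variance
    of a new noisy observation, which is what a soft sensor reports).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != model.d:
        raise ValueError(f"dimension mismatch: query has {x.shape[0]}, model has {model.d}")
    mean, std = model.gp.predict(x[None, :], return_std=True)
    return float(mean[0] + model.y_offset), float(max(std[0] ** 2, 0.0))


def predict_gpr_batch(model: GPRModel, X: np.ndarray) -> np.ndarray:
    """Posterior mean at many query points (no variance)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return model.gp.predict(X) + model.y_offset
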