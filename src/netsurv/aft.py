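"""Accelerated failure time regression under right-censoring.

The AFT model regresses log survival time on covariates,
``log T = alpha + x' beta + sigma * eps``.  Right-censoring is handled by
weighted least squares with Kaplan-Meier jump (Stute) weights: each
observation is weighted by the mass the Kaplan-Meier estimator of the
survival-time distribution places on it, so censored observations get
weight zero and the weighted criterion remains consistent for the
regression coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["StuteWeights", "AFTFit", "stute_weights", "fit_aft_wls", "StuteAFTRegressor"]


@dataclass(frozen=True)
class StuteWeights:
    """Kaplan-Meier jump weights.

    Attributes
    ----------
    weights : ndarray
        Non-negative weights in time-sorted order; zero for censored
        observations; they sum to at most 1 (exactly 1 when the largest
        observation is an event).
    order : ndarray
        Permutation mapping sorted position -> original sample index.
    """

    weights: np.ndarray
    order: np.ndarray

    def in_original_order(self) -> np.ndarray:
        out = np.empty_like(self.weights)
        out[self.order] = self.weights
        return out

    @property
    def n_effective(self) -> int:
        """Number of observations carrying positive weight."""
        return int(np.sum(self.weights > 0))


@dataclass(frozen=True)
class AFTFit:
    intercept: float
    coefficients: np.ndarray
    weighted_rss: float


def stute_weights(time, event) -> StuteWeights:
    """Kaplan-Meier jump sizes as regression weights.

    With observations sorted by time (events preceding censorings at tied
    times), the weight of the i-th sorted observation is

        w_(i) = d_(i) / (n - i + 1) * prod_{j < i} ((n - j)/(n - j + 1))^d_(j)

    where ``d`` is the event indicator.  These are exactly the jumps of the
    Kaplan-Meier estimator of the time distribution.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.ndim != 1 or time.shape != event.shape:
        raise ValueError("time and event must be 1-d arrays of equal length")
    if np.any(time <= 0):
        raise ValueError("survival times must be strictly positive")
    if not np.all(np.isin(event, (0, 1))):
        raise ValueError("event indicators must be 0 or 1")

    n = time.size
    # stable sort on (time, censoring-status): events come first at ties
    order = np.lexsort((1 - event, time))
    d = event[order]
    i = np.arange(1, n + 1)
    step = ((n - i) / (n - i + 1.0)) ** d
    prefix = np.concatenate(([1.0], np.cumprod(step)[:-1]))
    w = d / (n - i + 1.0) * prefix
    return StuteWeights(weights=w, order=order)


def _solve_weighted_ls(X: np.ndarray, y: np.ndarray, w: np.ndarray, ridge: float = 1e-8):
    """Weighted normal equations; ridge jitter applied only for rank safety.

    A well-conditioned Gram matrix is solved exactly (so the uncensored fit
    reproduces OLS to machine precision); otherwise the jitter stabilises
    near-singular designs and a genuinely singular one raises with the
    offending columns.
    """
    Xw = X * w[:, None]
    gram = X.T @ Xw
    rhs = Xw.T @ y
    beta = None
    try:
        if np.linalg.cond(gram) < 1e10:
            beta = np.linalg.solve(gram, rhs)
        else:
            beta = np.linalg.solve(gram + ridge * np.eye(gram.shape[0]), rhs)
    except np.linalg.LinAlgError:
        beta = None
    if beta is None or not np.all(np.isfinite(beta)) or np.abs(beta).max() > 1e10:
        # identify (near-)collinear columns through the pivots of a QR
        r = np.linalg.qr(Xw, mode="r")
        diag = np.abs(np.diag(r))
        bad = np.flatnonzero(diag < 1e-10 * max(diag.max(), 1.0))
        raise np.linalg.LinAlgError(
            f"singular design beyond ridge jitter; collinear columns: {bad.tolist()}"
        )
    return beta


def fit_aft_wls(X, time, event, weights: StuteWeights | None = None) -> AFTFit:
    """Fit the AFT model by Stute-weighted least squares.

    Minimises ``sum_i w_i (log t_i - alpha - x_i' beta)^2`` where ``w`` are the
    Kaplan-Meier jump weights.  With no censoring this reduces exactly to OLS
    of log-time on the covariates.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if X.ndim != 2 or X.shape[0] != time.size:
        raise ValueError("X must be (n_samples, n_predictors) matching time")
    if weights is None:
        weights = stute_weights(time, event)
    w = weights.in_original_order()
    if not np.any(w > 0):
        raise ValueError("all observations censored: every Stute weight is zero")

    y = np.log(time)
    Z = np.column_stack([np.ones(X.shape[0]), X])
    beta = _solve_weighted_ls(Z, y, w)
    resid = y - Z @ beta
    return AFTFit(
        intercept=float(beta[0]),
        coefficients=beta[1:],
        weighted_rss=float(np.sum(w * resid**2)),
    )


class StuteAFTRegressor(RegressorMixin, BaseEstimator):
    """Accelerated failure time regression with Kaplan-Meier weights.

    Parameters
    ----------
    ridge : float, default 1e-8
        Jitter added to the Gram matrix for rank safety.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Covariate effects on log survival time.
    intercept_ : float
    weighted_rss_ : float
        Stute-weighted residual sum of squares at the fit.
    stute_weights_ : StuteWeights
    """

    def __init__(self, ridge: float = 1e-8):
        self.ridge = ridge

    def fit(self, X, y):
        """Fit on covariates X and survival outcome y.

        y is an (n, 2) array-like of (time, event) or a DataFrame with
        ``time`` and ``event`` columns.
        """
        time, event = _unpack_survival(y)
        X = np.asarray(X, dtype=float)
        self.stute_weights_ = stute_weights(time, event)
        w = self.stute_weights_.in_original_order()
        if not np.any(w > 0):
            raise ValueError("all observations censored: nothing to fit")
        Z = np.column_stack([np.ones(X.shape[0]), X])
        beta = _solve_weighted_ls(Z, np.log(time), w, ridge=self.ridge)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        resid = np.log(time) - Z @ beta
        self.weighted_rss_ = float(np.sum(w * resid**2))
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        """Predicted log survival time."""
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_


def _unpack_survival(y):
    """Accept (time, event) in DataFrame, structured or (n, 2) array form."""
    if hasattr(y, "columns"):
        return np.asarray(y["time"], dtype=float), np.asarray(y["event"], dtype=int)
    arr = np.asarray(y)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return arr[:, 0].astype(float), arr[:, 1].astype(int)
    raise ValueError("survival outcome must be (n, 2) (time, event) or a DataFrame")
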