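"""Mean-variance modelling of log-counts with per-observation precision weights.

RNA-seq counts are heteroscedastic on the log scale: low counts are noisier.
The transform computes log2 counts-per-million, fits a lowess trend of the
square-root residual standard deviation against average log2 count, and
converts the predicted trend at each observation's fitted log-count into a
precision weight (predicted sqrt-sd to the power -4).  Downstream linear
modelling can then treat the log-expression values as approximately normal
with known weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = ["ExpressionMatrix", "voom_transform", "VoomTransformer"]

_LOWESS_FRAC = 0.5


@dataclass
class ExpressionMatrix:
    """log2-CPM expression (genes x samples) with matching precision weights."""

    log_expr: pd.DataFrame
    weights: pd.DataFrame

    def __post_init__(self):
        if self.log_expr.shape != self.weights.shape:
            raise ValueError("log_expr and weights must have identical shape")


def _fit_trend(log_expr: np.ndarray, lib: np.ndarray, group: np.ndarray):
    """Lowess trend of sqrt residual sd vs average log2 count.

    Returns (x_curve, y_curve) sorted in x; the fit excludes genes whose
    residual sd is zero (constant genes carry no variance information).
    """
    n = log_expr.shape[1]
    fitted = np.empty_like(log_expr)
    dof = 0
    for g in np.unique(group):
        cols = group == g
        fitted[:, cols] = log_expr[:, cols].mean(axis=1, keepdims=True)
        dof += 1
    resid = log_expr - fitted
    denom = max(n - dof, 1)
    sd = np.sqrt((resid**2).sum(axis=1) / denom)
    sqrt_sd = np.sqrt(sd)

    # average log2 count: shift log2-CPM back to the count scale using the
    # typical library size
    sx = log_expr.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    ok = sd > 0
    if ok.sum() < 2:
        warnings.warn("too few variable genes for a mean-variance trend; flat trend used")
        const = sqrt_sd[ok].mean() if ok.any() else 1.0
        return np.array([sx.min(), sx.max()]), np.array([const, const])
    fit = lowess(sqrt_sd[ok], sx[ok], frac=_LOWESS_FRAC, return_sorted=True)
    return fit[:, 0], fit[:, 1]


def voom_transform(counts: pd.DataFrame, group=None, lib_size=None) -> ExpressionMatrix:
    """Transform a genes x samples count matrix to weighted log2-CPM.

    ``group`` optionally gives a per-sample label (e.g. tissue) so residual
    variances are taken around group means rather than a single gene mean.
    ``lib_size`` overrides the per-sample library sizes -- pass the full
    experiment's totals when ``counts`` is a gene subset, so counts-per-
    million stay on the genome-wide scale.
    """
    if counts.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    c = counts.to_numpy(dtype=float)
    lib = c.sum(axis=0) if lib_size is None else np.asarray(lib_size, dtype=float)
    if lib.shape != (c.shape[1],) or np.any(lib <= 0):
        raise ValueError("lib_size must give a positive total per sample")
    log_expr = np.log2((c + 0.5) / (lib + 1.0) * 1e6)
    if group is None:
        group = np.zeros(c.shape[1], dtype=int)
    group = np.asarray(group)

    xc, yc = _fit_trend(log_expr, lib, group)
    order = np.argsort(xc)
    xc, yc = xc[order], yc[order]
    floor = max(yc[yc > 0].min() if np.any(yc > 0) else 1e-4, 1e-4)
    yc = np.maximum(yc, floor)

    # predicted sqrt-sd at each observation's fitted log2 count; fitted
    # log2-CPM per group mean, shifted by that sample's own library size
    fitted_cpm = np.empty_like(log_expr)
    for g in np.unique(group):
        cols = group == g
        fitted_cpm[:, cols] = log_expr[:, cols].mean(axis=1, keepdims=True)
    fitted_count = fitted_cpm + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    pred = np.interp(fitted_count, xc, yc)  # clips at the curve's range
    weights = pred**-4.0

    idx, cols = counts.index, counts.columns
    return ExpressionMatrix(
        log_expr=pd.DataFrame(log_expr, index=idx, columns=cols),
        weights=pd.DataFrame(weights, index=idx, columns=cols),
    )


class VoomTransformer(TransformerMixin, BaseEstimator):
    """Sklearn transformer view of the voom-style transform.

    ``fit_transform(X)`` on a samples x genes count matrix returns log2-CPM
    (samples x genes); the matching precision weights for the fitted data are
    stored in ``weights_``.  ``transform`` on new samples applies the stored
    mean-variance trend.
    """

    def __init__(self, group=None):
        self.group = group

    def fit(self, X, y=None):
        counts = self._to_counts(X)
        em = voom_transform(counts, group=self.group)
        self.trend_x_, self.trend_y_ = None, None  # recomputed below for reuse
        c = counts.to_numpy(dtype=float)
        lib = c.sum(axis=0)
        g = np.zeros(c.shape[1], int) if self.group is None else np.asarray(self.group)
        xc, yc = _fit_trend(np.log2((c + 0.5) / (lib + 1.0) * 1e6), lib, g)
        order = np.argsort(xc)
        self.trend_x_, self.trend_y_ = xc[order], np.maximum(yc[order], 1e-4)
        self.log_expr_ = em.log_expr.T
        self.weights_ = em.weights.T
        self.feature_names_in_ = np.asarray(counts.index)
        return self

    def transform(self, X):
        counts = self._to_counts(X)
        c = counts.to_numpy(dtype=float)
        lib = c.sum(axis=0)
        return np.log2((c + 0.5) / (lib + 1.0) * 1e6).T

    @staticmethod
    def _to_counts(X) -> pd.DataFrame:
        if hasattr(X, "columns"):
            return X.T
        return pd.DataFrame(np.asarray(X).T)
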