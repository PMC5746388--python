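"""Differential expression screening for count data.

A two-group negative-binomial Wald test: size factors by median-of-ratios,
per-gene dispersion by pooled method of moments on the normalized counts,
then a Wald test on the log2 ratio of group means with Benjamini-Hochberg
adjustment.  Also provides the magnitude threshold screen (padj < 0.05 and
|log2 FC| > 2) and the low-count filter that drops genes expressed in fewer
than 20% of samples.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "size_factors",
    "bh_adjust",
    "nb_de_test",
    "threshold_de",
    "low_count_filter",
    "NegativeBinomialDE",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]

_DISPERSION_FLOOR = 1e-8
_PSEUDOCOUNT = 0.5


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (genes x samples input).

    Each sample's factor is the median, over genes positive in every sample,
    of the ratio of its count to the gene's geometric mean.  Falls back to
    library-size ratios when no gene is positive everywhere.
    """
    c = counts.to_numpy(dtype=float)
    allpos = np.all(c > 0, axis=1)
    if allpos.sum() >= 1:
        logc = np.log(c[allpos])
        logratio = logc - logc.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logratio, axis=0))
    else:
        lib = c.sum(axis=0)
        sf = lib / np.exp(np.mean(np.log(np.maximum(lib, 1.0))))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _group_moments(norm: np.ndarray):
    mean = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1) if norm.shape[1] > 1 else np.zeros(norm.shape[0])
    return mean, var


def nb_de_test(normal: pd.DataFrame, tumor: pd.DataFrame) -> pd.DataFrame:
    """Per-gene negative-binomial Wald test of tumor vs normal mean counts.

    Returns a DataFrame with columns gene_id, log2fc (tumor over normal),
    pvalue, padj (BH across all tested genes) and direction (up/down).
    Genes with zero counts everywhere get log2fc 0 and padj 1.
    """
    if normal.shape[1] < 2 or tumor.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")
    genes = normal.index
    if not genes.equals(tumor.index):
        shared = normal.index.intersection(tumor.index)
        if shared.empty:
            raise ValueError("normal and tumor matrices share no genes")
        normal, tumor = normal.loc[shared], tumor.loc[shared]
        genes = shared

    combined = pd.concat([normal, tumor], axis=1)
    sf = size_factors(combined).to_numpy()
    n_n, n_t = normal.shape[1], tumor.shape[1]
    norm_all = combined.to_numpy(dtype=float) / sf
    norm_n, norm_t = norm_all[:, :n_n], norm_all[:, n_n:]

    m_n, v_n = _group_moments(norm_n)
    m_t, v_t = _group_moments(norm_t)

    # pooled method-of-moments dispersion: alpha = (var - mean) / mean^2
    with np.errstate(divide="ignore", invalid="ignore"):
        a_n = np.where(m_n > 0, (v_n - m_n) / np.maximum(m_n, 1e-300) ** 2, 0.0)
        a_t = np.where(m_t > 0, (v_t - m_t) / np.maximum(m_t, 1e-300) ** 2, 0.0)
    alpha = np.maximum(((n_n - 1) * a_n + (n_t - 1) * a_t) / (n_n + n_t - 2),
                       _DISPERSION_FLOOR)

    mp_n = m_n + _PSEUDOCOUNT
    mp_t = m_t + _PSEUDOCOUNT
    log2fc = np.log2(mp_t / mp_n)
    # delta method on log2 of the group mean: Var(log2 m) = (1/(n m) + a/n)/ln2^2
    se2 = (1.0 / (n_n * mp_n) + alpha / n_n + 1.0 / (n_t * mp_t) + alpha / n_t)
    se = np.sqrt(se2) / math.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / se, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(wald))

    allzero = (m_n == 0) & (m_t == 0)
    log2fc[allzero] = 0.0
    pvalue[allzero] = 1.0

    padj = multipletests(pvalue, method="fdr_bh")[1]
    padj[allzero] = 1.0
    return pd.DataFrame(
        {
            "gene_id": genes,
            "log2fc": log2fc,
            "pvalue": pvalue,
            "padj": padj,
            "direction": np.where(log2fc > 0, "up", "down"),
        }
    ).reset_index(drop=True)


def threshold_de(results: pd.DataFrame, alpha: float = 0.05, lfc: float = 2.0) -> set:
    """Genes passing padj < alpha and |log2fc| > lfc (both strict)."""
    if len(results) == 0:
        return set()
    keep = (results["padj"] < alpha) & (results["log2fc"].abs() > lfc)
    return set(results.loc[keep, "gene_id"])


def low_count_filter(counts: pd.DataFrame, min_fraction: float = 0.2) -> pd.DataFrame:
    """Keep genes detected (count > 0) in at least ceil(min_fraction * n) samples."""
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must lie in (0, 1]")
    need = math.ceil(min_fraction * counts.shape[1])
    keep = (counts > 0).sum(axis=1) >= need
    return counts.loc[keep]


class NegativeBinomialDE(BaseEstimator):
    """Two-group NB Wald differential expression test, sklearn style.

    ``fit(X, y)`` takes a samples x genes count matrix and binary labels
    (0 = normal, 1 = tumor); per-gene results land in ``results_`` and the
    thresholded gene set in ``selected_genes_``.
    """

    def __init__(self, alpha: float = 0.05, lfc: float = 2.0):
        self.alpha = alpha
        self.lfc = lfc

    def fit(self, X, y):
        y = np.asarray(y).astype(int)
        if hasattr(X, "columns"):
            counts = X.T  # genes x samples
        else:
            counts = pd.DataFrame(np.asarray(X).T)
        normal = counts.loc[:, y == 0]
        tumor = counts.loc[:, y == 1]
        self.results_ = nb_de_test(normal, tumor)
        self.selected_genes_ = threshold_de(self.results_, self.alpha, self.lfc)
        return self
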