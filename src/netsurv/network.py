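"""Weighted gene co-expression network construction and module detection.

The network is unsigned: similarity is |Pearson correlation| across samples,
raised elementwise to a soft-threshold power beta chosen as the smallest
power whose scale-free topology fit index reaches a target R^2.  Topological
overlap (direct edge plus shared-neighbor weight) defines the clustering
dissimilarity 1 - TOM; average-linkage hierarchical clustering with a static
cut at a quantile of the merge heights yields modules, with clusters below a
minimum size collected into a noise module labelled 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import linregress
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "ScaleFreeFitCurve",
    "CoexpressionNetwork",
    "similarity_matrix",
    "scale_free_fit_index",
    "scale_free_curve",
    "pick_soft_threshold",
    "topological_overlap",
    "detect_modules",
    "export_links",
    "WeightedCoexpressionNetwork",
]


@dataclass
class ScaleFreeFitCurve:
    powers: np.ndarray
    fit_index: np.ndarray
    mean_connectivity: np.ndarray


@dataclass
class CoexpressionNetwork:
    gene_ids: list
    similarity: np.ndarray
    beta: int
    adjacency: np.ndarray
    tom: np.ndarray
    module_of_gene: dict
    curve: ScaleFreeFitCurve | None = None
    noise_module: int = 0


def similarity_matrix(expr) -> np.ndarray:
    """Unsigned co-expression similarity |corr| from samples x genes data.

    Zero-variance genes get similarity 0 to every other gene (diagonal 1).
    """
    X = np.asarray(expr, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    sd = X.std(axis=0)
    dead = sd == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance gene(s): similarities set to 0")
        X = X.copy()
        X[:, dead] = np.random.default_rng(0).normal(size=(X.shape[0], dead.sum()))
    s = np.abs(np.corrcoef(X, rowvar=False))
    if dead.any():
        s[dead, :] = 0.0
        s[:, dead] = 0.0
    np.fill_diagonal(s, 1.0)
    return np.clip(s, 0.0, 1.0)


def scale_free_fit_index(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution regression.

    Bins log10 connectivity into equal-width bins, regresses log10 relative
    frequency on log10 mean connectivity per bin, and returns R^2 times
    -sign(slope), floored at 0, so only decreasing degree laws score high.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.allclose(k, k[0]):
        return 0.0
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max(), n_bins + 1)
    which = np.clip(np.digitize(logk, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0
    fit = linregress(xs, ys)
    r2 = fit.rvalue**2
    return float(max(0.0, -np.sign(fit.slope) * r2))


def scale_free_curve(similarity: np.ndarray, powers=range(1, 21)) -> ScaleFreeFitCurve:
    """Scale-free fit index and mean connectivity over candidate soft powers."""
    powers = np.asarray(list(powers), dtype=int)
    if powers.size == 0 or powers.min() < 1:
        raise ValueError("powers must be integers >= 1")
    s = np.asarray(similarity, dtype=float).copy()
    np.fill_diagonal(s, 0.0)
    fit = np.empty(powers.size)
    meank = np.empty(powers.size)
    for i, b in enumerate(powers):
        k = (s**b).sum(axis=1)
        fit[i] = scale_free_fit_index(k)
        meank[i] = k.mean()
    return ScaleFreeFitCurve(powers=powers, fit_index=fit, mean_connectivity=meank)


_DEFAULT_UNSIGNED_POWER = 6


def pick_soft_threshold(curve: ScaleFreeFitCurve, r2_target: float = 0.90) -> int:
    """Smallest power reaching the target fit index (else the argmax, warned).

    When no power shows a meaningful decreasing degree law (best fit index
    below 0.3, e.g. on block-structured data whose degree distribution is
    unimodal), the argmax is uninformative and the conventional
    unsigned-network default power 6 is returned instead.
    """
    if curve.powers.size == 0:
        raise ValueError("empty scale-free curve")
    hit = np.flatnonzero(curve.fit_index >= r2_target)
    if hit.size:
        return int(curve.powers[hit[0]])
    if curve.fit_index.max() < 0.3:
        warnings.warn(
            "degree distribution shows no scale-free trend at any power; "
            f"falling back to the conventional power {_DEFAULT_UNSIGNED_POWER}"
        )
        return _DEFAULT_UNSIGNED_POWER
    warnings.warn(
        f"no power reached fit index {r2_target}; "
        f"using argmax at {curve.fit_index.max():.3f}"
    )
    return int(curve.powers[int(np.argmax(curve.fit_index))])


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency in [0, 1].

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) off the
    diagonal, 1 on the diagonal.
    """
    a = np.asarray(adjacency, dtype=float).copy()
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    np.fill_diagonal(a, 0.0)
    shared = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return 0.5 * (tom + tom.T)


def detect_modules(tom: np.ndarray, min_module_size: int = 30,
                   cut_quantile: float = 0.90) -> np.ndarray:
    """Average-linkage clustering of 1 - TOM with a static quantile tree cut.

    The dendrogram is cut at the ``cut_quantile`` quantile of its merge
    heights; clusters smaller than ``min_module_size`` are collected into the
    noise module (label 0) and the rest are labelled 1..M by decreasing size.
    """
    n = tom.shape[0]
    if n < min_module_size:
        warnings.warn("fewer genes than min_module_size: everything is noise")
        return np.zeros(n, dtype=int)
    d = 1.0 - np.asarray(tom, dtype=float)
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    if d.max() < 1e-8:  # all genes (near-)identical: a single module
        return np.ones(n, dtype=int)
    Z = average(squareform(np.maximum(d, 0.0), checks=False))
    cut = float(np.quantile(Z[:, 2], cut_quantile))
    raw = fcluster(Z, t=cut, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    big = sizes[sizes >= min_module_size].index
    # order surviving clusters by decreasing size (ties by cluster id)
    order = sorted(big, key=lambda c: (-sizes[c], c))
    remap = {c: i + 1 for i, c in enumerate(order)}
    return np.array([remap.get(c, 0) for c in raw], dtype=int)


def export_links(network: CoexpressionNetwork, threshold: float = 0.5,
                 matrix: str = "adjacency") -> pd.DataFrame:
    """Edge table (gene_a, gene_b, weight) of pairs above a strict threshold.

    Suitable as a Circos link file; ``matrix`` selects adjacency or TOM.
    """
    if not (0 <= threshold <= 1):
        raise ValueError("threshold must lie in [0, 1]")
    mat = {"adjacency": network.adjacency, "tom": network.tom}[matrix]
    iu = np.triu_indices_from(mat, k=1)
    keep = mat[iu] > threshold
    genes = np.asarray(network.gene_ids)
    return pd.DataFrame(
        {
            "gene_a": genes[iu[0][keep]],
            "gene_b": genes[iu[1][keep]],
            "weight": mat[iu][keep],
        }
    )


class WeightedCoexpressionNetwork(ClusterMixin, BaseEstimator):
    """Soft-thresholded co-expression network with TOM-based modules.

    Fit on a samples x genes expression matrix.  The soft power is chosen
    from ``powers`` by the scale-free criterion unless ``beta`` pins it.

    Attributes
    ----------
    similarity_, adjacency_, tom_ : gene x gene matrices
    beta_ : chosen soft-threshold power
    curve_ : the scale-free fit curve over candidate powers
    labels_ : per-gene module labels (0 = noise module)
    network_ : assembled :class:`CoexpressionNetwork`
    """

    def __init__(self, powers=tuple(range(1, 21)), r2_target: float = 0.90,
                 beta: int | None = None, min_module_size: int = 30,
                 cut_quantile: float = 0.90):
        self.powers = powers
        self.r2_target = r2_target
        self.beta = beta
        self.min_module_size = min_module_size
        self.cut_quantile = cut_quantile

    def fit(self, X, y=None):
        gene_ids = list(X.columns) if hasattr(X, "columns") else list(range(np.shape(X)[1]))
        s = similarity_matrix(X)
        self.curve_ = scale_free_curve(s, self.powers)
        self.beta_ = int(self.beta) if self.beta is not None else pick_soft_threshold(
            self.curve_, self.r2_target
        )
        self.similarity_ = s
        self.adjacency_ = s**self.beta_
        self.tom_ = topological_overlap(self.adjacency_)
        self.labels_ = detect_modules(self.tom_, self.min_module_size, self.cut_quantile)
        self.network_ = CoexpressionNetwork(
            gene_ids=gene_ids,
            similarity=self.similarity_,
            beta=self.beta_,
            adjacency=self.adjacency_,
            tom=self.tom_,
            module_of_gene={g: int(m) for g, m in zip(gene_ids, self.labels_)},
            curve=self.curve_,
        )
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
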