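"""Synthetic RNA-seq cohorts with module structure and censored survival.

Generates the kind of data the pipeline assumes: negative-binomially
distributed read counts whose log-scale means carry (a) block correlation
from per-module latent factors (a Gaussian-copula-style log-normal mixing),
(b) a tumor-vs-normal mean shift for a planted set of differentially
expressed genes, and survival times for the tumor samples from a log-linear
AFT model driven by a sparse set of *signal* genes concentrated in a few
modules, under independent exponential right-censoring calibrated to a
target censored fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SimulationConfig", "GroundTruth", "simulate_cohort"]

# latent log2-scale standard deviation of gene expression around its
# baseline; shared between the module factor and the gene-specific part so
# that the within-module log-scale correlation equals within_module_corr
_LATENT_SD = 1.0
# baseline log survival time (natural log of days); exp(6.5) ~ 665 days
_LOG_TIME_INTERCEPT = 6.5


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a moderately sized cohort: 300 tumor and 100 normal
    samples, ten 50-gene co-expression modules plus 300 unclustered
    background ("noise") genes, within-module log-scale correlation 0.6,
    80% of each module's genes differentially expressed at |log2 FC| = 3,
    and survival driven by 5 signal genes in each of 3 modules with AFT
    coefficient 0.5, observed under ~30% independent censoring.

    ``de_fraction`` applies to module genes only: tumor-associated
    transcriptional programmes are exactly what co-expression modules model,
    while the unclustered background stays non-differential -- which also
    keeps the majority-unchanged assumption behind median-of-ratios
    normalization satisfied, as in a genome-scale experiment where most
    genes do not respond.
    """

    n_tumor: int = 300
    n_normal: int = 100
    n_modules: int = 10
    genes_per_module: int = 50
    n_noise_genes: int = 300
    within_module_corr: float = 0.6
    de_fraction: float = 0.8
    de_log2fc: float = 3.0
    signal_modules: int = 3
    signal_genes_per_module: int = 5
    signal_effect: float = 0.5
    baseline_mean: float = 100.0
    nb_dispersion: float = 0.1
    censor_rate: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_tumor", "n_normal", "n_modules", "genes_per_module",
                     "n_noise_genes", "signal_modules", "signal_genes_per_module"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_tumor < 1 or self.n_normal < 1:
            raise ValueError("need at least one tumor and one normal sample")
        if not (0 <= self.within_module_corr < 1):
            raise ValueError("within_module_corr must lie in [0, 1)")
        if not (0 <= self.de_fraction <= 1):
            raise ValueError("de_fraction must lie in [0, 1]")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if self.signal_modules > self.n_modules:
            raise ValueError("signal_modules cannot exceed n_modules")
        if self.signal_genes_per_module > self.genes_per_module:
            raise ValueError("signal_genes_per_module cannot exceed genes_per_module")


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort (module labels use 0 for noise)."""

    module_of_gene: dict
    de_genes: set
    signal_genes: set
    true_aft_coefficients: dict = field(default_factory=dict)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson mixing; Poisson when dispersion=0."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _calibrate_censor_rate(times: np.ndarray, target: float) -> float:
    """Exponential censoring rate giving an expected censored fraction ~target.

    Solves mean_i(1 - exp(-c * t_i)) = target for c by bisection; the left
    side is the probability, averaged over the realised event times, that an
    independent Exp(c) censoring time falls before the event.
    """
    def frac(c):
        return float(np.mean(-np.expm1(-c * times)))

    lo, hi = 1e-12, 1.0 / max(times.min(), 1e-12)
    while frac(hi) < target:
        hi *= 2.0
        if hi > 1e12:
            break
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def simulate_cohort(config: SimulationConfig):
    """Draw one cohort: (counts genes x samples, clinical table, ground truth).

    Counts are NB with log2-mean  log2(mu_g) + sd*(sqrt(rho) f_ms +
    sqrt(1-rho) e_gs)  plus a +/- de_log2fc tumor shift for DE genes; log
    survival time of tumor samples is a linear model in the standardized
    log2 expression of the signal genes; censoring is independent
    exponential with rate calibrated to the requested censored fraction.
    Everything is reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cfg = config

    n_genes = cfg.n_modules * cfg.genes_per_module + cfg.n_noise_genes
    n_samples = cfg.n_tumor + cfg.n_normal
    gene_ids = [f"gene_{i:05d}" for i in range(n_genes)]
    sample_ids = [f"tumor_{i:04d}" for i in range(cfg.n_tumor)] + [
        f"normal_{i:04d}" for i in range(cfg.n_normal)
    ]
    is_tumor = np.array([1] * cfg.n_tumor + [0] * cfg.n_normal, dtype=bool)

    # module labels: 1..n_modules, 0 for unclustered noise genes
    module_of = np.zeros(n_genes, dtype=int)
    for m in range(cfg.n_modules):
        module_of[m * cfg.genes_per_module:(m + 1) * cfg.genes_per_module] = m + 1

    # signal genes: first signal_genes_per_module genes of the first
    # signal_modules modules; DE genes: a per-module subset that always
    # includes the signal genes (so the DE screen cannot remove the signal)
    signal_mask = np.zeros(n_genes, dtype=bool)
    for m in range(cfg.signal_modules):
        start = m * cfg.genes_per_module
        signal_mask[start:start + cfg.signal_genes_per_module] = True

    de_mask = np.zeros(n_genes, dtype=bool)
    if cfg.de_fraction > 0:
        for m in range(cfg.n_modules):
            idx = np.flatnonzero(module_of == m + 1)
            k = int(round(cfg.de_fraction * idx.size))
            chosen = rng.choice(idx, size=k, replace=False) if k else np.array([], int)
            de_mask[chosen] = True
        de_mask |= signal_mask
    de_sign = np.where(rng.random(n_genes) < 0.5, 1.0, -1.0)

    # latent log2-scale structure
    mu = cfg.baseline_mean * np.exp(rng.normal(0.0, 1.0, size=n_genes))
    rho = cfg.within_module_corr
    f = rng.normal(size=(cfg.n_modules, n_samples))          # module factors
    e = rng.normal(size=(n_genes, n_samples))                # gene-specific
    log2_mean = np.log2(mu)[:, None] + _LATENT_SD * np.sqrt(1 - rho) * e
    in_module = module_of > 0
    log2_mean[in_module] += (
        _LATENT_SD * np.sqrt(rho) * f[module_of[in_module] - 1]
    )
    shift = np.where(de_mask, de_sign * cfg.de_log2fc, 0.0)
    log2_mean[:, is_tumor] += shift[:, None]

    counts = _nb_sample(rng, np.exp2(log2_mean), cfg.nb_dispersion)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)

    # survival: log-linear AFT in the standardized log2 expression of the
    # signal genes, separately realised for tumor and (baseline-only) normal
    def _survival(block, linpred):
        n = block.sum()
        log_t = _LOG_TIME_INTERCEPT + linpred + cfg.noise_sd * rng.normal(size=n)
        t = np.exp(log_t)
        if cfg.censor_rate <= 0:
            return t, np.ones(n, dtype=int)
        c = rng.exponential(1.0 / _calibrate_censor_rate(t, cfg.censor_rate), size=n)
        return np.minimum(t, c), (t <= c).astype(int)

    beta = np.where(signal_mask, cfg.signal_effect, 0.0)
    sig_idx = np.flatnonzero(signal_mask)
    if sig_idx.size:
        # standardized log2 counts-per-million: the same normalized scale the
        # selection stage models, so the planted effects live on the
        # covariates the method actually sees
        lib = counts[:, is_tumor].sum(axis=0)
        logx = np.log2((counts[sig_idx][:, is_tumor] + 0.5) / (lib + 1.0) * 1e6)
        z = (logx - logx.mean(axis=1, keepdims=True)) / np.where(
            logx.std(axis=1, keepdims=True) > 0, logx.std(axis=1, keepdims=True), 1.0
        )
        linpred_tumor = beta[sig_idx] @ z
    else:
        linpred_tumor = np.zeros(cfg.n_tumor)

    t_tumor, d_tumor = _survival(is_tumor, linpred_tumor)
    t_normal, d_normal = _survival(~is_tumor, np.zeros(cfg.n_normal))

    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "tissue": np.where(is_tumor, "tumor", "normal"),
            "time": np.concatenate([t_tumor, t_normal]),
            "event": np.concatenate([d_tumor, d_normal]),
        }
    )

    truth = GroundTruth(
        module_of_gene={g: int(m) for g, m in zip(gene_ids, module_of)},
        de_genes={g for g, m in zip(gene_ids, de_mask) if m},
        signal_genes={g for g, m in zip(gene_ids, signal_mask) if m},
        true_aft_coefficients={
            g: float(b) for g, b, m in zip(gene_ids, beta, signal_mask) if m
        },
    )
    return counts_df, clinical, truth
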