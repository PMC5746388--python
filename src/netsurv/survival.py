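"""Median-split Kaplan-Meier validation of selected genes.

Each candidate gene dichotomizes the cohort at its median expression
(strictly greater than the median is "high"; ties go to "low") and the two
groups are compared with the standard two-group log-rank test.  The sign of
the observed-minus-expected event count in the high group gives the
direction: ``high_worse`` when high expressors die faster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = ["KMValidation", "median_split", "logrank", "km_curves", "validate_genes"]


@dataclass
class KMValidation:
    gene_id: str
    chi2: float
    pvalue: float
    direction: str  # high_worse | low_worse
    n_high: int
    n_low: int


def median_split(values) -> np.ndarray:
    """Boolean high/low labels: True ("high") iff value > median.

    Median-tied samples land in the low group.  A constant vector yields
    all-low with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 samples to split")
    med = np.median(v)
    high = v > med
    if not high.any():
        warnings.warn("constant (or degenerate) expression: every sample is 'low'")
    return high


def logrank(groups, time, event) -> tuple[float, float]:
    """Two-group log-rank test.

    At each distinct event time the observed minus expected events in the
    first group are accumulated with the hypergeometric variance;
    chi2 = (sum(O-E))^2 / sum(V), p from chi-square with 1 df.  Returns
    (chi2, pvalue).  Use :func:`_logrank_detail` for the O-E sign.
    """
    chi2, p, _ = _logrank_detail(groups, time, event)
    return chi2, p


def _logrank_detail(groups, time, event):
    g = np.asarray(groups).astype(bool)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    if not (g.any() and (~g).any()):
        raise ValueError("both groups must be nonempty")
    if d.sum() == 0:
        raise ValueError("no events: log-rank test undefined")

    o_minus_e = 0.0
    var = 0.0
    for tt in np.unique(t[d == 1]):
        at_risk = t >= tt
        n = at_risk.sum()
        n1 = (at_risk & g).sum()
        dead = (t == tt) & (d == 1)
        dtot = dead.sum()
        d1 = (dead & g).sum()
        e1 = dtot * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += dtot * (n1 / n) * (1 - n1 / n) * (n - dtot) / (n - 1)
    if var == 0:
        return 0.0, 1.0, o_minus_e
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1)), float(o_minus_e)


def km_curves(groups, time, event) -> pd.DataFrame:
    """Kaplan-Meier curve coordinates per group (for plotting/export).

    Returns a tidy frame with columns group, time, survival, n_at_risk.
    """
    g = np.asarray(groups).astype(bool)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    frames = []
    for label, mask in (("high", g), ("low", ~g)):
        if not mask.any():
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], d[mask], label=label)
        tab = kmf.event_table
        frames.append(
            pd.DataFrame(
                {
                    "group": label,
                    "time": tab.index.to_numpy(dtype=float),
                    "survival": kmf.survival_function_[label].reindex(tab.index).to_numpy(),
                    "n_at_risk": tab["at_risk"].to_numpy(dtype=int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def validate_genes(expr: pd.DataFrame, time, event) -> pd.DataFrame:
    """Median-split log-rank validation for each gene (genes x samples input).

    Returns a DataFrame with gene_id, chi2, pvalue, direction and group
    sizes, one row per gene, in the input gene order.
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    rows = []
    for gene, values in expr.iterrows():
        high = median_split(values.to_numpy())
        if not high.any() or high.all():
            rows.append(KMValidation(gene, np.nan, np.nan, "undefined",
                                     int(high.sum()), int((~high).sum())))
            continue
        chi2, p, ome = _logrank_detail(high, t, d)
        rows.append(
            KMValidation(
                gene_id=gene,
                chi2=chi2,
                pvalue=p,
                direction="high_worse" if ome > 0 else "low_worse",
                n_high=int(high.sum()),
                n_low=int((~high).sum()),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
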