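"""Reading, writing and matching of count matrices and clinical tables.

Counts are stored genes x samples as TSV/CSV with a header row of sample
ids; clinical tables carry sample_id, tissue (normal|tumor), time and event
columns.  ``match_samples`` reproduces the cohort-assembly step: normal and
tumor expression sub-matrices restricted to samples present in both inputs,
ordered by the clinical table.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "read_counts",
    "write_counts",
    "read_clinical",
    "write_clinical",
    "write_ground_truth",
    "read_ground_truth",
    "match_samples",
]

logger = logging.getLogger(__name__)

_TISSUES = {"normal", "tumor"}


def read_counts(path) -> pd.DataFrame:
    """Read a genes x samples count matrix (delimiter auto-detected)."""
    cm = pd.read_csv(path, sep=None, engine="python", index_col=0)
    _validate_counts(cm)
    return cm


def _validate_counts(cm: pd.DataFrame) -> None:
    if cm.index.duplicated().any():
        raise ValueError("duplicate gene ids in count matrix")
    if cm.columns.duplicated().any():
        raise ValueError("duplicate sample ids in count matrix")
    vals = cm.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise ValueError("count matrix contains non-numeric entries")
    if (vals < 0).any():
        raise ValueError("count matrix contains negative entries")
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("count matrix contains non-integer entries")


def write_counts(cm: pd.DataFrame, path) -> None:
    cm.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical(path) -> pd.DataFrame:
    """Read and validate a clinical table; rows missing time/event are dropped."""
    ct = pd.read_csv(path, sep=None, engine="python")
    required = {"sample_id", "tissue", "time", "event"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"clinical table lacks columns: {sorted(missing)}")
    n0 = len(ct)
    ct = ct.dropna(subset=["time", "event"])
    if len(ct) < n0:
        logger.warning("dropped %d clinical rows with missing time/event", n0 - len(ct))
    return _validate_clinical(ct.reset_index(drop=True))


def _validate_clinical(ct: pd.DataFrame) -> pd.DataFrame:
    if ct["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in clinical table")
    bad = set(ct["tissue"]) - _TISSUES
    if bad:
        raise ValueError(f"unknown tissue labels: {sorted(bad)}")
    if (ct["time"].to_numpy(dtype=float) < 0).any():
        raise ValueError("negative survival times")
    if not np.isin(ct["event"].to_numpy(), (0, 1)).all():
        raise ValueError("event indicators must be 0 or 1")
    ct = ct.copy()
    ct["time"] = ct["time"].astype(float)
    ct["event"] = ct["event"].astype(int)
    return ct


def write_clinical(ct: pd.DataFrame, path) -> None:
    ct.to_csv(path, sep="\t", index=False)


def write_ground_truth(truth, path) -> None:
    """Ground truth as a per-gene TSV (module, DE flag, signal flag, beta)."""
    genes = sorted(truth.module_of_gene)
    pd.DataFrame(
        {
            "gene_id": genes,
            "module": [truth.module_of_gene[g] for g in genes],
            "is_de": [int(g in truth.de_genes) for g in genes],
            "is_signal": [int(g in truth.signal_genes) for g in genes],
            "aft_coefficient": [truth.true_aft_coefficients.get(g, 0.0) for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_ground_truth(path):
    from .simulate import GroundTruth

    df = pd.read_csv(path, sep="\t")
    return GroundTruth(
        module_of_gene=dict(zip(df["gene_id"], df["module"].astype(int))),
        de_genes=set(df.loc[df["is_de"] == 1, "gene_id"]),
        signal_genes=set(df.loc[df["is_signal"] == 1, "gene_id"]),
        true_aft_coefficients=dict(
            zip(df.loc[df["is_signal"] == 1, "gene_id"],
                df.loc[df["is_signal"] == 1, "aft_coefficient"])
        ),
    )


def match_samples(cm: pd.DataFrame, ct: pd.DataFrame):
    """Split counts into matched normal/tumor sub-matrices.

    Keeps exactly the samples present in both the count matrix and the
    clinical table, ordered as in the clinical table.  Returns
    (counts_normal, counts_tumor, clinical_tumor).  Idempotent; an empty
    intersection is a hard error.
    """
    _validate_counts(cm)
    ct = _validate_clinical(ct)
    present = ct["sample_id"].isin(cm.columns)
    matched = ct.loc[present]
    if matched.empty:
        raise ValueError("no overlap between count-matrix and clinical sample ids")
    normal_ids = matched.loc[matched["tissue"] == "normal", "sample_id"].tolist()
    tumor_ids = matched.loc[matched["tissue"] == "tumor", "sample_id"].tolist()
    clinical_tumor = matched.loc[matched["tissue"] == "tumor"].reset_index(drop=True)
    return cm[normal_ids], cm[tumor_ids], clinical_tumor
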