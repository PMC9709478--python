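"""cis and trans target prediction for differentially expressed lncRNAs.

cis targets are protein-coding genes within a genomic window (default
50 kb) of the lncRNA span on the same chromosome, strand ignored.  trans
targets are coding genes strongly co-expressed with the lncRNA
(|Spearman R| > 0.9 and p < 0.05 by default, both strict), optionally
required to also appear in a lncRNA-gene binding-evidence table (e.g.
triplex-prediction output supplied as a TSV).
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "cis_targets",
    "trans_coexpression_targets",
    "intersect_binding",
    "load_binding_table",
]


def cis_targets(
    lncs: Sequence[GeneModel],
    coding: Sequence[GeneModel],
    window_bp: int = 50_000,
) -> pd.DataFrame:
    """Coding genes within ``window_bp`` of each lncRNA span (same chromosome).

    ``distance_bp`` is the signed gap between nearest edges: negative when
    the coding gene lies upstream (left) of the lncRNA, zero when the spans
    overlap.  The window applies symmetrically, so gene-within-window-of-lnc
    and lnc-within-window-of-gene are the same predicate.
    """
    if not len(lncs) or not len(coding):
        raise ValueError("both gene lists must be non-empty")
    rows = []
    coding_by_chrom: dict[str, list[GeneModel]] = {}
    for g in coding:
        coding_by_chrom.setdefault(g.chrom, []).append(g)
    for lnc in lncs:
        for g in coding_by_chrom.get(lnc.chrom, ()):
            if g.gene_id == lnc.gene_id:
                continue
            if g.start >= lnc.end:
                dist = g.start - lnc.end
            elif g.end <= lnc.start:
                dist = -(lnc.start - g.end)
            else:
                dist = 0
            if abs(dist) <= window_bp:
                rows.append((lnc.gene_id, g.gene_id, "cis", dist))
    return pd.DataFrame(
        rows, columns=["lnc_id", "target_gene_id", "mode", "distance_bp"]
    )


def trans_coexpression_targets(
    lnc_expr: pd.DataFrame,
    coding_expr: pd.DataFrame,
    r_min: float = 0.9,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """lncRNA-coding gene pairs with |Spearman R| > ``r_min`` and
    p < ``p_max`` (both strict) across shared samples.

    Expression frames are features x samples; p-values use the t
    approximation.  Constant rows never qualify.
    """
    shared = [s for s in lnc_expr.columns if s in set(coding_expr.columns)]
    n = len(shared)
    if n < 3:
        raise ValueError(f"need >= 3 shared samples, got {n}")

    def ranked(frame: pd.DataFrame) -> np.ndarray:
        X = sps.rankdata(frame[shared].to_numpy(dtype=float), axis=1)
        sd = X.std(axis=1)
        sd[sd == 0] = np.nan  # constant rows -> nan correlations
        return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]

    L = ranked(lnc_expr)
    C = ranked(coding_expr)
    R = (L @ C.T) / n  # lnc x coding Spearman matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        t = R * np.sqrt((n - 2) / np.maximum(1.0 - R * R, 0.0))
    P = np.where(np.abs(R) >= 1.0, 0.0, 2 * sps.t.sf(np.abs(t), n - 2))
    keep = (np.abs(R) > r_min) & (P < p_max)
    li, ci = np.nonzero(np.nan_to_num(keep, nan=False))
    out = pd.DataFrame(
        {
            "lnc_id": lnc_expr.index.to_numpy()[li],
            "target_gene_id": coding_expr.index.to_numpy()[ci],
            "mode": "trans",
            "coexpression_r": R[li, ci],
            "pvalue": P[li, ci],
            "binding_supported": False,
        }
    )
    return out[out["lnc_id"] != out["target_gene_id"]].reset_index(drop=True)


def load_binding_table(path: str) -> pd.DataFrame:
    """Binding-evidence TSV with columns lnc_id and gene_id."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = {"lnc_id", "gene_id"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: binding table missing columns {sorted(missing)}")
    return df[["lnc_id", "gene_id"]].dropna()


def intersect_binding(
    predictions: pd.DataFrame,
    binding_table: Optional[pd.DataFrame] = None,
    require_binding: bool = True,
) -> pd.DataFrame:
    """Combine trans co-expression predictions with binding evidence.

    With a binding table and ``require_binding`` (default), only predictions
    whose (lnc, gene) pair appears in the table are kept, flagged
    ``binding_supported``; the permissive mode keeps all predictions and
    only sets the flag.  Without a table, all predictions pass through
    unsupported, with a warning.  Table rows naming unknown genes are
    ignored (logged).
    """
    preds = predictions.copy()
    if binding_table is None:
        logger.warning("no binding table supplied; passing predictions through")
        preds["binding_supported"] = False
        return preds
    pairs = set(zip(binding_table["lnc_id"], binding_table["gene_id"]))
    known = set(zip(preds["lnc_id"], preds["target_gene_id"]))
    unknown = pairs - known
    if unknown:
        logger.info(
            "%d binding-table rows do not match any prediction; ignored", len(unknown)
        )
    supported = [
        (l, g) in pairs for l, g in zip(preds["lnc_id"], preds["target_gene_id"])
    ]
    preds["binding_supported"] = supported
    if require_binding:
        preds = preds[preds["binding_supported"]].reset_index(drop=True)
    return preds
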