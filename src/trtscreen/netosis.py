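"""Gene-set activity scoring by first principal component (PC1).

The activity of the NETosis programme (neutrophil extracellular trap
formation) is summarised per sample as PC1 of the expression of pathway
genes detected in more than half of the patients.  The sign of a principal
component is arbitrary; here it is fixed so that the majority of gene-PC1
correlations are *negative*, i.e. lower PC1 means higher pathway
expression and more active NETosis — matching the orientation convention
of the source analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .quantify import ExpressionMatrix
from .stats import (
    BINARY_TRAITS,
    NUMERIC_TRAITS,
    compare_burden_groups,
    correlate_burden_trait,
    spearman,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetScore",
    "select_expressed_genes",
    "pc1_score",
    "orient_and_diagnose",
    "associate_score_traits",
    "gene_trait_correlation_scan",
]


@dataclass
class GeneSetScore:
    """Per-sample PC1 score of a gene set, with orientation diagnostics."""

    scores: pd.Series  # sample_id -> pc1
    loadings: pd.Series  # gene -> loading (unit norm)
    variance_explained: float
    scaling: str
    gene_pc1_corr: Optional[pd.Series] = None  # gene -> Spearman R with PC1
    oriented: bool = False

    @property
    def n_total(self) -> int:
        return len(self.loadings)

    @property
    def n_negative(self) -> int:
        if self.gene_pc1_corr is None:
            raise ValueError("run orient_and_diagnose first")
        return int((self.gene_pc1_corr < 0).sum())


def _expr_frame(expr) -> pd.DataFrame:
    return expr.fpkm if isinstance(expr, ExpressionMatrix) else expr


def select_expressed_genes(
    expr,
    gene_set: Sequence[str],
    patient_ids: Sequence[str],
    min_frac: float = 0.5,
    expressed_min_fpkm: float = 0.0,
) -> list[str]:
    """Gene-set members detected (FPKM > ``expressed_min_fpkm``) in strictly
    more than ``min_frac`` of the patients.

    Genes absent from the expression matrix are ignored with a warning; an
    empty result is an error suggesting a lower threshold.
    """
    frame = _expr_frame(expr)
    gene_set = list(dict.fromkeys(gene_set))
    if not gene_set:
        raise ValueError("gene set is empty")
    present = [g for g in gene_set if g in frame.index]
    absent = set(gene_set) - set(present)
    if absent:
        logger.warning(
            "%d gene-set members absent from expression matrix (e.g. %s)",
            len(absent),
            sorted(absent)[:3],
        )
    sub = frame.loc[present, list(patient_ids)]
    frac = (sub > expressed_min_fpkm).mean(axis=1)
    kept = list(frac.index[frac > min_frac])
    if not kept:
        raise ValueError(
            "no gene-set member expressed in more than "
            f"{min_frac:.0%} of patients; lower min_frac or expressed_min_fpkm"
        )
    return kept


def pc1_score(expr_sub, scaling: str = "zscore") -> GeneSetScore:
    """PC1 of a genes x samples expression block.

    ``scaling`` applies per gene before the PCA: ``zscore`` (default,
    recommended since FPKM spans orders of magnitude), ``center``, or
    ``none``.  Deterministic up to the global sign, which
    :func:`orient_and_diagnose` fixes.
    """
    frame = _expr_frame(expr_sub)
    if frame.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    if frame.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if scaling not in ("zscore", "center", "none"):
        raise ValueError(f"unknown scaling {scaling!r}")
    X = frame.to_numpy(dtype=float).T  # samples x genes
    if scaling == "zscore":
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            logger.warning(
                "dropping %d zero-variance genes before z-scored PCA",
                int((~keep).sum()),
            )
            X = X[:, keep]
            frame = frame.loc[frame.index[keep]]
            sd = sd[keep]
        if X.shape[1] < 2:
            raise ValueError("fewer than 2 genes with nonzero variance")
        X = (X - X.mean(axis=0)) / sd
    elif scaling == "center":
        X = X - X.mean(axis=0)
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("zero-variance matrix; PC1 undefined")
    pca = PCA(n_components=1, svd_solver="full")
    scores = pca.fit_transform(X)[:, 0]
    return GeneSetScore(
        scores=pd.Series(scores, index=frame.columns, name="pc1"),
        loadings=pd.Series(pca.components_[0], index=frame.index, name="loading"),
        variance_explained=float(pca.explained_variance_ratio_[0]),
        scaling=scaling,
    )


def orient_and_diagnose(score: GeneSetScore, expr_sub) -> GeneSetScore:
    """Fix the PC1 sign and fill per-gene correlation diagnostics.

    Per-gene Spearman correlations between expression and PC1 are computed;
    if the majority are positive the component is flipped so that most
    genes correlate negatively (lower PC1 = higher expression).  An exact
    50/50 split is broken by flipping when the correlations sum positive.
    Orientation changes signs only, never magnitudes.
    """
    frame = _expr_frame(expr_sub).loc[score.loadings.index]
    corr = _gene_score_spearman(frame, score.scores)
    n_neg = int((corr < 0).sum())
    n_pos = int((corr > 0).sum())
    flip = n_pos > n_neg or (n_pos == n_neg and corr.sum() > 0)
    if flip:
        score = GeneSetScore(
            scores=-score.scores,
            loadings=-score.loadings,
            variance_explained=score.variance_explained,
            scaling=score.scaling,
        )
        corr = -corr
    score.gene_pc1_corr = corr
    score.oriented = True
    return score


def _gene_score_spearman(frame: pd.DataFrame, scores: pd.Series) -> pd.Series:
    """Spearman R of each gene's expression with the score vector."""
    s = scores.reindex(frame.columns).to_numpy(dtype=float)
    rs = sps.rankdata(s)
    rs = (rs - rs.mean()) / rs.std()
    X = sps.rankdata(frame.to_numpy(dtype=float), axis=1)
    sd = X.std(axis=1)
    sd[sd == 0] = np.nan
    Xc = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    r = (Xc @ rs) / len(s)
    return pd.Series(r, index=frame.index, name="spearman_r")


def associate_score_traits(
    score: GeneSetScore,
    clinical: pd.DataFrame,
    binary_traits: Sequence[str] = BINARY_TRAITS,
    numeric_traits: Sequence[str] = NUMERIC_TRAITS,
) -> pd.DataFrame:
    """Associate the PC1 score with clinical traits.

    Binary traits (viral infection, AKI, prognosis) are compared by
    Wilcoxon rank-sum; numeric traits (PaCO2, PaO2/FiO2, age, NEUT%) by
    Spearman correlation.  Returns one row per trait with raw p-values;
    constant traits are reported with missing statistics.
    """
    rows = []
    clin = clinical.reindex(score.scores.index)
    for trait in binary_traits:
        if trait not in clin.columns:
            continue
        labels = clin[trait].dropna()
        if labels.nunique() != 2:
            logger.warning("binary trait %s lacks 2 levels; skipped", trait)
            continue
        res = compare_burden_groups(score.scores, labels)
        rows.append((trait, "wilcoxon", res.statistic, res.pvalue, res.n))
    for trait in numeric_traits:
        if trait not in clin.columns:
            continue
        try:
            res = correlate_burden_trait(score.scores, clin[trait])
        except ValueError:
            continue
        rows.append((trait, "spearman", res.statistic, res.pvalue, res.n))
    return pd.DataFrame(rows, columns=["trait", "test", "statistic", "pvalue", "n"])


def gene_trait_correlation_scan(
    expr,
    gene_set: Sequence[str],
    trait: pd.Series,
) -> pd.DataFrame:
    """Per-gene Spearman correlation between FPKM and a numeric trait.

    Returns one (R, p) row per gene sorted by p-value (missing last);
    constant genes or genes with fewer than 3 complete pairs are reported
    as missing.
    """
    frame = _expr_frame(expr)
    rows = []
    for gene in dict.fromkeys(gene_set):
        if gene not in frame.index:
            logger.warning("gene %s absent from expression matrix; skipped", gene)
            continue
        aligned = pd.concat([frame.loc[gene], trait], axis=1, join="inner").dropna()
        if len(aligned) < 3:
            rows.append((gene, np.nan, np.nan, len(aligned)))
            continue
        res = spearman(aligned.iloc[:, 0], aligned.iloc[:, 1])
        rows.append((gene, res.statistic, res.pvalue, res.n))
    out = pd.DataFrame(rows, columns=["gene_id", "spearman_r", "pvalue", "n"])
    return out.sort_values("pvalue", na_position="last", kind="stable").reset_index(
        drop=True
    )
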