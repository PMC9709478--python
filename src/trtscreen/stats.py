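"""Burden statistics and clinical-trait association tests.

Read-through *burden* is the per-patient count of pairs called positive,
kept separately for cis and trans pairs; the total counts each unordered
gene pair once even when both directions of a convergent pair are called.

Tests follow the conventions of the source analyses: two-sided Wilcoxon
rank-sum for group comparisons (exact enumeration for small tie-free
groups, tie-corrected normal approximation otherwise), Spearman rank
correlation for numeric traits (exact permutation p for n <= 9, t
approximation otherwise), and Pearson chi-square for 2x2 contingency
tables (Yates correction off by default).  No multiple-testing correction
is applied to trait scans; raw p-values are reported.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "spearman",
    "wilcoxon_rank_sum",
    "chi_square_2x2",
    "trt_burden",
    "fc_correlation_per_pair",
    "compare_burden_groups",
    "correlate_burden_trait",
    "load_clinical_table",
    "burden_trait_tests",
]

EXACT_SPEARMAN_MAX_N = 9
EXACT_WILCOXON_MAX_N = 10

BINARY_TRAITS = ("prognosis", "virus", "aki")
NUMERIC_TRAITS = ("neut_pct", "paco2", "pao2_fio2", "age")


class TestResult(NamedTuple):
    statistic: float
    pvalue: float
    n: int


# ---------------------------------------------------------------------------
# Primitive tests


def _drop_incomplete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def spearman(x, y, exact: Optional[bool] = None) -> TestResult:
    """Spearman rank correlation with average ranks.

    Missing values are dropped pairwise.  The p-value comes from exact
    permutation enumeration for n <= 9 (unless ``exact=False``) and from
    the t approximation otherwise.  Constant input yields (nan, nan).
    """
    x, y = _drop_incomplete(x, y)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(np.nan, np.nan, n)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if exact is None:
        exact = n <= EXACT_SPEARMAN_MAX_N
    if exact:
        p = _spearman_exact_p(rx, ry, rho)
    else:
        p = _spearman_t_p(rho, n)
    return TestResult(rho, p, n)


def _spearman_t_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2 * sps.t.sf(abs(t), n - 2))


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Permutation null of rho, conditional on the observed (tied) ranks."""
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
    rho_perm = (ry_c @ rx_c) / denom
    return float(np.mean(np.abs(rho_perm) >= abs(rho_obs) - 1e-12))


def wilcoxon_rank_sum(
    x,
    y,
    exact: Optional[bool] = None,
    continuity: bool = True,
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when both groups have <= 10 observations and there
    are no ties across the pooled sample; otherwise the tie-corrected
    normal approximation (with continuity correction by default, matching
    common R practice).  The returned statistic is the Mann-Whitney U of
    the first group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if exact is None:
        exact = (
            len(x) <= EXACT_WILCOXON_MAX_N
            and len(y) <= EXACT_WILCOXON_MAX_N
            and not has_ties
        )
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=continuity
    )
    return TestResult(float(res.statistic), float(res.pvalue), len(x) + len(y))


def chi_square_2x2(table, correction: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 count table, uncorrected by default."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("table has a zero marginal")
    stat, p, _, _ = sps.chi2_contingency(arr, correction=correction)
    return TestResult(float(stat), float(p), int(arr.sum()))


# ---------------------------------------------------------------------------
# Burden


def trt_burden(
    cis_calls: pd.DataFrame,
    trans_calls: pd.DataFrame,
    pair_keys: Optional[dict] = None,
) -> pd.DataFrame:
    """Per-patient TRT burden: cis count, trans count, and their union.

    ``pair_keys`` maps pair_id to a direction-free identity; by default the
    id is split on ``"__"`` and the gene ids sorted, so the two directions
    of a convergent pair collapse to one unordered pair in the total.
    """
    if list(cis_calls.columns) != list(trans_calls.columns):
        raise ValueError("cis and trans call matrices must share patient columns")

    def default_key(pair_id: str):
        return tuple(sorted(pair_id.split("__")))

    keys = pair_keys or {}
    patients = list(cis_calls.columns)
    cis_n = cis_calls.sum(axis=0).astype(int)
    trans_n = trans_calls.sum(axis=0).astype(int)
    total = {}
    for p in patients:
        called = list(cis_calls.index[cis_calls[p]]) + list(
            trans_calls.index[trans_calls[p]]
        )
        total[p] = len({keys.get(pid, default_key(pid)) for pid in called})
    out = pd.DataFrame(
        {"cis": cis_n, "trans": trans_n, "total": pd.Series(total, dtype=int)}
    )
    out.index.name = "patient_id"
    return out


def fc_correlation_per_pair(
    diagnostics: pd.DataFrame,
    pair_ids: Optional[Sequence[str]] = None,
    min_patients: int = 3,
) -> pd.DataFrame:
    """Per-pair Spearman correlation between intergenic FC and downstream
    FC across patients.

    Operates on the long diagnostics table from the screen; non-finite fold
    changes (zero control means) are dropped pairwise.  Pairs with fewer
    than ``min_patients`` complete values or constant FC vectors are
    reported with missing R.
    """
    df = diagnostics
    if pair_ids is not None:
        df = df[df["pair_id"].isin(set(pair_ids))]
    rows = []
    for pair_id, sub in df.groupby("pair_id", sort=True):
        ifc = sub["intergenic_fc"].to_numpy(dtype=float)
        dfc = sub["downstream_fc"].to_numpy(dtype=float)
        ok = np.isfinite(ifc) & np.isfinite(dfc)
        n = int(ok.sum())
        if n < min_patients or np.ptp(ifc[ok]) == 0 or np.ptp(dfc[ok]) == 0:
            rows.append((pair_id, np.nan, np.nan, n))
            continue
        res = spearman(ifc[ok], dfc[ok], exact=False)
        rows.append((pair_id, res.statistic, res.pvalue, n))
    return pd.DataFrame(rows, columns=["pair_id", "spearman_r", "pvalue", "n"])


def compare_burden_groups(burden: pd.Series, labels: pd.Series) -> TestResult:
    """Wilcoxon rank-sum of burden between the two levels of ``labels``."""
    aligned = pd.concat([burden, labels], axis=1, join="inner").dropna()
    values, labs = aligned.iloc[:, 0], aligned.iloc[:, 1]
    levels = pd.unique(labs)
    if len(levels) != 2:
        raise ValueError(f"labels must have exactly 2 levels, got {list(levels)}")
    x = values[labs == levels[0]].to_numpy(dtype=float)
    y = values[labs == levels[1]].to_numpy(dtype=float)
    return wilcoxon_rank_sum(x, y)


def correlate_burden_trait(burden: pd.Series, trait: pd.Series) -> TestResult:
    """Spearman correlation between burden and a numeric trait (pairwise
    deletion of missing values)."""
    aligned = pd.concat([burden, trait], axis=1, join="inner").dropna()
    if len(aligned) < 3:
        raise ValueError("fewer than 3 complete (burden, trait) pairs")
    return spearman(aligned.iloc[:, 0], aligned.iloc[:, 1])


# ---------------------------------------------------------------------------
# Clinical table


_BINARY_VOCAB = {
    "group": {"patient", "control"},
    "prognosis": {"death", "remission"},
    "virus": {"yes", "no"},
    "aki": {"yes", "no"},
}


def load_clinical_table(path: str) -> pd.DataFrame:
    """Load and validate the clinical traits TSV (indexed by sample_id).

    Categorical columns must use the stated vocabularies (missing values
    allowed); numeric trait columns must be numeric or missing.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: clinical table needs a sample_id column")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    df = df.set_index("sample_id")
    for col, vocab in _BINARY_VOCAB.items():
        if col in df.columns:
            bad = set(df[col].dropna().unique()) - vocab
            if bad:
                raise ValueError(
                    f"{path}: column {col!r} has values {sorted(bad)}; allowed {sorted(vocab)}"
                )
    for col in df.columns:
        if col in _BINARY_VOCAB:
            continue
        df[col] = pd.to_numeric(df[col], errors="raise")
    return df


def burden_trait_tests(
    burden: pd.DataFrame,
    clinical: pd.DataFrame,
    binary_traits: Sequence[str] = BINARY_TRAITS,
    numeric_traits: Sequence[str] = NUMERIC_TRAITS,
) -> pd.DataFrame:
    """Burden-vs-trait association scan for each burden class.

    Binary traits get a Wilcoxon rank-sum test, numeric traits a Spearman
    correlation; one row per (class, trait) with raw p-values.
    """
    rows = []
    clin = clinical.reindex(burden.index)
    for cls in burden.columns:
        b = burden[cls]
        for trait in binary_traits:
            if trait not in clin.columns:
                continue
            labels = clin[trait].dropna()
            if labels.nunique() != 2:
                logger.warning("trait %s does not have 2 levels; skipped", trait)
                continue
            res = compare_burden_groups(b, labels)
            rows.append((cls, trait, "wilcoxon", res.statistic, res.pvalue, res.n))
        for trait in numeric_traits:
            if trait not in clin.columns:
                continue
            try:
                res = correlate_burden_trait(b, clin[trait])
            except ValueError:
                continue
            rows.append((cls, trait, "spearman", res.statistic, res.pvalue, res.n))
    return pd.DataFrame(
        rows, columns=["burden_class", "trait", "test", "statistic", "pvalue", "n"]
    )
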