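"""Patient-specific transcriptional read-through calling.

The screen is a conjunction of four steps, evaluated per gene pair and
patient against a healthy-control baseline (FPKM*, the mean FPKM across
control samples):

1. candidate adjacent gene pairs are enumerated (annotation module);
2. the upstream gene must be actively expressed in the patient — its FPKM
   strictly above a percentile (default 25th) of upstream-gene FPKM over all
   candidate pairs in that same patient;
3. the intergenic fold change (patient intergenic FPKM / intergenic FPKM*)
   must exceed a threshold (default 5), evidence that transcription ran past
   the upstream TTS;
4. the downstream gene must respond: FPKM above an absolute floor (default
   1.5) when the control mean is zero, otherwise fold change above a
   threshold (default 1.5).

A pair is *recurrent* when it is called in strictly more than a configured
fraction of patients (default 30%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .annotation import GenePair, pairs_to_frame
from .quantify import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenParams",
    "TRTCallResult",
    "control_baseline",
    "step2_expressed_upstream",
    "step3_intergenic_fc",
    "step4_downstream_effect",
    "call_trt",
    "recurrent_pairs",
]


@dataclass(frozen=True)
class ScreenParams:
    """All thresholds of the four-step screen.

    ``zero_mean_epsilon`` > 0 switches the zero-control-mean intergenic
    policy to a pseudocount: FC = patient / (FPKM* + epsilon) everywhere.
    With epsilon = 0 (default), a pair whose control intergenic mean is zero
    passes step 3 only when the patient FPKM exceeds ``intergenic_fc_min``
    times the smallest nonzero control intergenic mean over all pairs (the
    "fallback unit"); zero patient signal always fails.
    """

    upstream_percentile: float = 25.0
    intergenic_fc_min: float = 5.0
    downstream_abs_min: float = 1.5
    downstream_fc_min: float = 1.5
    recurrence_min_frac: float = 0.30
    zero_mean_epsilon: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.upstream_percentile <= 100:
            raise ValueError("upstream_percentile must be in [0, 100]")
        for name in ("intergenic_fc_min", "downstream_abs_min", "downstream_fc_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.recurrence_min_frac <= 1:
            raise ValueError("recurrence_min_frac must be in (0, 1]")
        if self.zero_mean_epsilon < 0:
            raise ValueError("zero_mean_epsilon must be >= 0")


def _as_pairs_frame(pairs) -> pd.DataFrame:
    if isinstance(pairs, pd.DataFrame):
        return pairs
    return pairs_to_frame(pairs)


def _pair_fields(pair) -> tuple[str, str, str]:
    """(pair_id, upstream gene id, downstream gene id) from GenePair or table row."""
    if isinstance(pair, GenePair):
        return pair.pair_id, pair.upstream.gene_id, pair.downstream.gene_id
    return pair["pair_id"], pair["upstream_gene"], pair["downstream_gene"]


def control_baseline(expr: ExpressionMatrix, control_ids: Sequence[str]) -> pd.Series:
    """Per-feature mean FPKM over healthy controls (FPKM*)."""
    control_ids = list(control_ids)
    if not control_ids:
        raise ValueError("control set is empty")
    missing = set(control_ids) - set(expr.sample_ids)
    if missing:
        raise KeyError(f"unknown control samples: {sorted(missing)}")
    return expr.fpkm[control_ids].mean(axis=1)


def step2_expressed_upstream(
    pairs, expr: ExpressionMatrix, patient_id: str, params: ScreenParams
) -> list[str]:
    """Pair ids whose upstream-gene FPKM in this patient is strictly above
    the configured percentile of upstream-gene FPKM across all candidate
    pairs in the same patient."""
    frame = _as_pairs_frame(pairs)
    if patient_id not in expr.fpkm.columns:
        raise KeyError(f"unknown sample {patient_id!r}")
    up = expr.fpkm.loc[frame["upstream_gene"], patient_id].to_numpy()
    threshold = np.percentile(up, params.upstream_percentile)
    return list(frame.loc[up > threshold, "pair_id"])


def step3_intergenic_fc(
    pair,
    expr: ExpressionMatrix,
    patient_id: str,
    baseline: pd.Series,
    params: ScreenParams,
    fallback_unit: Optional[float] = None,
) -> tuple[bool, float]:
    """Intergenic fold-change test for one pair and patient.

    ``fallback_unit`` is the smallest nonzero control intergenic mean across
    all pairs; :func:`call_trt` supplies it.  Without one, a zero control
    mean fails unless ``zero_mean_epsilon`` > 0.
    """
    pair_id, _, _ = _pair_fields(pair)
    patient_fpkm = float(expr.fpkm.at[pair_id, patient_id])
    mean = float(baseline[pair_id])
    eps = params.zero_mean_epsilon
    if eps > 0:
        fc = patient_fpkm / (mean + eps)
        return fc > params.intergenic_fc_min, fc
    if mean > 0:
        fc = patient_fpkm / mean
        return fc > params.intergenic_fc_min, fc
    if patient_fpkm == 0:
        return False, np.nan
    if fallback_unit is None or not np.isfinite(fallback_unit):
        return False, np.inf
    return patient_fpkm > params.intergenic_fc_min * fallback_unit, np.inf


def step4_downstream_effect(
    pair,
    expr: ExpressionMatrix,
    patient_id: str,
    baseline: pd.Series,
    params: ScreenParams,
) -> tuple[bool, float, str]:
    """Downstream-gene response test: absolute FPKM floor when the control
    mean is zero, fold change otherwise."""
    _, _, down = _pair_fields(pair)
    patient_fpkm = float(expr.fpkm.at[down, patient_id])
    mean = float(baseline[down])
    if mean == 0:
        return patient_fpkm > params.downstream_abs_min, patient_fpkm, "absolute"
    fc = patient_fpkm / mean
    return fc > params.downstream_fc_min, fc, "fold"


@dataclass
class TRTCallResult:
    """Boolean pair x patient call matrix with per-cell diagnostics.

    ``calls`` rows are pair ids, columns patient ids; a cell is True iff
    steps 2-4 all passed (step 1 being candidate enumeration).  ``pairs``
    retains pair metadata including ``pair_class`` so cis and trans calls
    stay distinguishable; ``diagnostics`` is a long table with the per-step
    values behind every cell.
    """

    calls: pd.DataFrame
    pairs: pd.DataFrame
    diagnostics: pd.DataFrame
    baseline: pd.Series
    params: ScreenParams
    fallback_unit: float

    def _class_calls(self, pair_class: str) -> pd.DataFrame:
        ids = self.pairs.loc[self.pairs["pair_class"] == pair_class, "pair_id"]
        return self.calls.loc[ids]

    @property
    def cis_calls(self) -> pd.DataFrame:
        return self._class_calls("cis")

    @property
    def trans_calls(self) -> pd.DataFrame:
        return self._class_calls("trans")

    @property
    def recurrence(self) -> pd.Series:
        """Fraction of patients in which each pair is called."""
        return self.calls.mean(axis=1)

    def recurrent_pairs(self, pair_class: Optional[str] = None) -> list[str]:
        calls = self.calls if pair_class is None else self._class_calls(pair_class)
        return recurrent_pairs(calls, self.params)

    def heatmap_matrix(self, pair_class: Optional[str] = None) -> pd.DataFrame:
        """Call matrix with pairs sorted by recurrence and patients by burden."""
        calls = self.calls if pair_class is None else self._class_calls(pair_class)
        pair_order = calls.mean(axis=1).sort_values(ascending=False, kind="stable").index
        patient_order = calls.sum(axis=0).sort_values(ascending=False, kind="stable").index
        return calls.loc[pair_order, patient_order]


def call_trt(
    pairs,
    expr: ExpressionMatrix,
    patient_ids: Sequence[str],
    control_ids: Sequence[str],
    params: ScreenParams = ScreenParams(),
) -> TRTCallResult:
    """Run the four-step screen for every pair x patient cell.

    Diagnostics are recorded for all cells, including pairs failing early,
    to support heatmap output and fold-change correlation analyses.
    """
    frame = _as_pairs_frame(pairs).reset_index(drop=True)
    patient_ids, control_ids = list(patient_ids), list(control_ids)
    if not patient_ids:
        raise ValueError("no patients given")
    overlap = set(patient_ids) & set(control_ids)
    if overlap:
        raise ValueError(f"patients and controls overlap: {sorted(overlap)}")
    unknown = (set(patient_ids) | set(control_ids)) - set(expr.sample_ids)
    if unknown:
        raise KeyError(f"unknown samples: {sorted(unknown)}")
    needed = set(frame["pair_id"]) | set(frame["upstream_gene"]) | set(frame["downstream_gene"])
    missing = needed - set(expr.feature_ids)
    if missing:
        raise KeyError(f"expression matrix lacks features: {sorted(missing)[:5]}")

    baseline = control_baseline(expr, control_ids)

    up_ids = frame["upstream_gene"].to_numpy()
    down_ids = frame["downstream_gene"].to_numpy()
    pair_ids = frame["pair_id"].to_numpy()

    up = expr.fpkm.loc[up_ids, patient_ids].to_numpy(dtype=float)
    inter = expr.fpkm.loc[pair_ids, patient_ids].to_numpy(dtype=float)
    down = expr.fpkm.loc[down_ids, patient_ids].to_numpy(dtype=float)
    base_inter = baseline[pair_ids].to_numpy(dtype=float)[:, None]
    base_down = baseline[down_ids].to_numpy(dtype=float)[:, None]

    # step 2: per-patient percentile over upstream FPKM of all candidate pairs
    thresholds = np.percentile(up, params.upstream_percentile, axis=0)
    s2 = up > thresholds[None, :]

    # step 3: intergenic fold change against FPKM*
    eps = params.zero_mean_epsilon
    with np.errstate(divide="ignore", invalid="ignore"):
        if eps > 0:
            inter_fc = inter / (base_inter + eps)
            s3 = inter_fc > params.intergenic_fc_min
            fallback_unit = np.nan
        else:
            inter_fc = np.where(
                base_inter > 0,
                inter / np.where(base_inter > 0, base_inter, 1.0),
                np.where(inter > 0, np.inf, np.nan),
            )
            nonzero = base_inter[base_inter > 0]
            fallback_unit = float(nonzero.min()) if nonzero.size else np.nan
            s3 = np.where(
                base_inter > 0,
                inter_fc > params.intergenic_fc_min,
                np.isfinite(fallback_unit)
                & (inter > params.intergenic_fc_min * fallback_unit),
            )

    # step 4: downstream response, absolute or fold branch
    with np.errstate(divide="ignore", invalid="ignore"):
        down_fc = np.where(base_down > 0, down / np.where(base_down > 0, base_down, 1.0), np.nan)
    abs_branch = base_down == 0
    s4 = np.where(
        abs_branch, down > params.downstream_abs_min, down_fc > params.downstream_fc_min
    )

    calls_arr = s2 & s3 & s4
    step_passed = 1 + s2.astype(int) + (s2 & s3).astype(int) + calls_arr.astype(int)

    calls = pd.DataFrame(calls_arr, index=pd.Index(pair_ids, name="pair_id"), columns=patient_ids)

    n_pairs, n_pat = calls_arr.shape
    diagnostics = pd.DataFrame(
        {
            "pair_id": np.repeat(pair_ids, n_pat),
            "patient_id": np.tile(patient_ids, n_pairs),
            "upstream_fpkm": up.ravel(),
            "intergenic_fpkm": inter.ravel(),
            "intergenic_fc": inter_fc.ravel(),
            "downstream_fpkm": down.ravel(),
            "downstream_fc": down_fc.ravel(),
            "downstream_branch": np.broadcast_to(
                np.where(abs_branch, "absolute", "fold"), (n_pairs, n_pat)
            ).ravel(),
            "step2": s2.ravel(),
            "step3": s3.ravel(),
            "step4": s4.ravel(),
            "call": calls_arr.ravel(),
            "step_passed": step_passed.ravel(),
        }
    )
    return TRTCallResult(
        calls=calls,
        pairs=frame,
        diagnostics=diagnostics,
        baseline=baseline,
        params=params,
        fallback_unit=fallback_unit,
    )


def recurrent_pairs(calls, params: ScreenParams = ScreenParams()) -> list[str]:
    """Pairs called in strictly more than ``recurrence_min_frac`` of patients."""
    if isinstance(calls, TRTCallResult):
        calls = calls.calls
    if calls.empty:
        return []
    frac = calls.mean(axis=1)
    return list(frac.index[frac > params.recurrence_min_frac])
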