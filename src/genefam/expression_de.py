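"""Replicate-aware expression analysis of RMA-normalized intensities.

Two analyses are provided:

* high-expression calls: a gene/sample is "highly expressed" when its log2
  intensity strictly exceeds a threshold (default 14);
* differential expression between a control and a treatment condition with
  index-paired replicates: per-gene replicate means, fold change as the
  ratio of raw means, and a one-tailed paired t-test (treatment > control,
  df = n - 1) on the raw intensities. Induction is called on fold alone
  (fold >= 1.5, inclusive); p-values are reported, not filtered on.

Table output is rounded half-up to 2 decimals; full precision is retained
internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "DEResult",
    "round_half_up",
    "log2_matrix",
    "call_high_expression",
    "differential_expression",
    "de_table",
    "select_induced",
    "union_induced",
    "export_heatmap_matrix",
]

DEFAULT_FOLD_THRESHOLD = 1.5
DEFAULT_HIGH_LOG2 = 14.0


@dataclass
class DEResult:
    gene_id: str
    mean_control: float
    mean_treatment: float
    fold: float
    p_value: float
    induced: bool
    zero_variance: bool = False


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (the convention of printed intensity tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def log2_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2; intensities must be strictly positive."""
    values = matrix.to_numpy(float)
    if (values <= 0).any():
        raise ValueError("nonpositive intensity in expression matrix")
    return pd.DataFrame(np.log2(values), index=matrix.index, columns=matrix.columns)


def call_high_expression(
    log2_values: pd.DataFrame, threshold: float = DEFAULT_HIGH_LOG2
) -> pd.DataFrame:
    """Boolean gene x sample flags: log2 value strictly greater than threshold."""
    return log2_values.gt(threshold)


def differential_expression(
    gene_id: str,
    control_reps,
    treatment_reps,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    alternative: str = "greater",
) -> DEResult:
    """Fold change and paired t-test for one gene.

    Replicates are paired by index (treatment replicate i derives from
    control replicate i). With zero-variance differences the t statistic is
    undefined; p is reported as 0 when the mean difference is positive and
    1 otherwise, with a flag.
    """
    control = np.asarray(control_reps, float)
    treatment = np.asarray(treatment_reps, float)
    if control.shape != treatment.shape or control.size < 2:
        raise ValueError("need equal replicate counts, n >= 2, paired by index")
    mean_c = float(control.mean())
    mean_t = float(treatment.mean())
    fold = mean_t / mean_c
    diffs = treatment - control
    zero_var = bool(np.allclose(diffs, diffs[0]))
    if zero_var and not np.allclose(diffs, 0):
        p = 0.0 if diffs.mean() > 0 else 1.0
        logger.warning("%s: zero-variance differences, degenerate p-value", gene_id)
    elif zero_var:
        p = 1.0
        logger.warning("%s: treatment equals control in every replicate", gene_id)
    else:
        p = float(sps.ttest_rel(treatment, control, alternative=alternative).pvalue)
    return DEResult(
        gene_id=gene_id,
        mean_control=mean_c,
        mean_treatment=mean_t,
        fold=fold,
        p_value=p,
        induced=fold >= fold_threshold and mean_t > mean_c,
        zero_variance=zero_var,
    )


def de_table(results: list[DEResult], rounded: bool = True) -> pd.DataFrame:
    """DE results as a printable table (means, fold, p to 2 decimals)."""
    fmt = (lambda x: round_half_up(x, 2)) if rounded else (lambda x: x)
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "mean_control": fmt(r.mean_control),
                "mean_treatment": fmt(r.mean_treatment),
                "fold": fmt(r.fold),
                "p_value": fmt(r.p_value),
                "induced": r.induced,
            }
            for r in results
        ]
    )


def select_induced(
    results: list[DEResult], fold_threshold: float = DEFAULT_FOLD_THRESHOLD
) -> list[str]:
    """Genes with fold >= threshold (inclusive) and a positive shift."""
    return sorted(
        r.gene_id
        for r in results
        if r.fold >= fold_threshold and r.mean_treatment > r.mean_control
    )


def union_induced(per_timepoint: list[list[str]]) -> list[str]:
    """Distinct genes induced at any timepoint, canonically sorted."""
    if not per_timepoint:
        raise ValueError("need at least one induced-gene list")
    out: set[str] = set()
    for lst in per_timepoint:
        out.update(lst)
    return sorted(out)


def export_heatmap_matrix(
    matrix: pd.DataFrame, gene_order: list[str], scale: str = "raw"
) -> pd.DataFrame:
    """Genes x samples table in raw or log2 scale for external heatmap tools."""
    unknown = [g for g in gene_order if g not in matrix.index]
    if unknown:
        raise KeyError(f"genes not in matrix: {unknown[:5]}")
    sub = matrix.loc[gene_order]
    if scale == "log2":
        return log2_matrix(sub)
    if scale == "raw":
        return sub.copy()
    raise ValueError(f"unknown scale {scale!r}")
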