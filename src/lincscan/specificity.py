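"""Tissue-specificity scoring: the TSI (tau) and the min-ratio score.

TSI: tau = sum_i(1 - x_i) / (N - 1), with x_i the per-tissue expression
summary normalized by the maximum over the N tissues. 0 for housekeeping
genes, 1 for single-tissue expression.

Min-ratio score: 1 - min_i(M(i)/E(i)) where E(i) is tissue i's expression
summary and M(i) the maximum summary over the other tissues; tissues with
E(i)=0 contribute an infinite ratio. 1 when expression is confined to one
tissue, 0 when uniform.

Calling rules: TSI path uses per-group max FPKM summaries and calls a gene
specific at tau >= 0.95, assigned to its argmax group; the min-ratio path
uses per-group max of log2(FPKM+1) and calls at score >= 0.75.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import ExpressionMatrix, ValidationError


def tsi(values: np.ndarray) -> float:
    """Tissue specificity index tau of one gene's per-tissue summaries.

    Returns NaN for an all-zero gene (undefined)."""
    v = np.asarray(values, float)
    if v.ndim != 1 or len(v) < 2:
        raise ValidationError("tsi needs >=2 per-tissue values")
    if np.any(v < 0):
        raise ValidationError("negative expression summary")
    m = v.max()
    if m == 0:
        return float("nan")
    x = v / m
    return float(np.sum(1.0 - x) / (len(v) - 1))


def minratio_score(values: np.ndarray) -> float:
    """1 - min_i(M(i)/E(i)), clamped to [0, 1]; NaN for all-zero genes."""
    v = np.asarray(values, float)
    if v.ndim != 1 or len(v) < 2:
        raise ValidationError("minratio_score needs >=2 per-tissue values")
    if np.any(v < 0):
        raise ValidationError("negative expression summary")
    if v.max() == 0:
        return float("nan")
    n = len(v)
    ratios = np.empty(n)
    with np.errstate(over="ignore"):
        for i in range(n):
            others = np.delete(v, i)
            m_i = others.max()
            ratios[i] = m_i / v[i] if v[i] > 0 else np.inf
    score = 1.0 - ratios.min()
    return float(min(1.0, max(0.0, score)))


def score_matrix(matrix: ExpressionMatrix, method: str = "tsi",
                 summary: str = "max") -> pd.DataFrame:
    """Per-gene specificity scores; columns score, argmax_tissue."""
    if len(matrix.group_names) < 2:
        raise ValidationError("need >=2 tissue groups")
    if method == "tsi":
        summ = matrix.group_summary(how=summary)
    elif method == "minratio":
        summ = matrix.group_summary(how=summary,
                                    transform=lambda d: np.log2(d + 1.0))
    else:
        raise ValidationError(f"unknown method {method!r}")
    scorer = tsi if method == "tsi" else minratio_score
    arr = summ.to_numpy(float)
    scores = np.array([scorer(row) for row in arr])
    argmax = summ.columns.to_numpy()[np.argmax(arr, axis=1)]
    return pd.DataFrame(
        {"score": scores, "argmax_tissue": argmax}, index=summ.index
    )


DEFAULT_THRESHOLDS = {"tsi": 0.95, "minratio": 0.75}


def call_specific(matrix: ExpressionMatrix, method: str = "tsi",
                  threshold: float | None = None,
                  summary: str = "max") -> pd.DataFrame:
    """Genes called tissue-specific: score >= threshold, assigned to the
    group attaining the maximal summary. Returns gene-indexed DataFrame with
    columns score, tissue."""
    if threshold is None:
        threshold = DEFAULT_THRESHOLDS[method]
    scored = score_matrix(matrix, method=method, summary=summary)
    called = scored[scored["score"] >= threshold].copy()
    called = called.rename(columns={"argmax_tissue": "tissue"})
    return called


def containment_fraction(minratio_calls: pd.Index, tsi_calls: pd.Index) -> float:
    """Fraction of min-ratio-called genes also in the TSI-called set
    (reported, not asserted)."""
    if len(minratio_calls) == 0:
        return float("nan")
    return len(minratio_calls.intersection(tsi_calls)) / len(minratio_calls)
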