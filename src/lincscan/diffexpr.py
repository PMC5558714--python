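"""Two-condition differential expression of lincRNAs.

Student's t-test on log2(FPKM+1) per gene, Benjamini-Hochberg adjustment
over all tested genes, and a call rule requiring adjusted p < alpha, a raw
fold change > 2 or < 0.5, and a mean FPKM > 1 in at least one condition.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import ExpressionMatrix, ValidationError


def de_test(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    fc_high: float = 2.0,
    fc_low: float = 0.5,
    min_mean_fpkm: float = 1.0,
    adjust: bool = True,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-gene DE results between two conditions.

    Columns: mean_fpkm_a, mean_fpkm_b, fold_change (= mean_a/mean_b on raw
    FPKM; +inf when mean_b = 0), p_raw, p_adjusted, is_de. Genes with zero
    within-group variance in both groups and equal means get p = 1.
    `adjust=False` gates on the raw p-value instead of the BH-adjusted one.
    """
    sa = matrix.samples_in_group(group_a)
    sb = matrix.samples_in_group(group_b)
    for g, s in ((group_a, sa), (group_b, sb)):
        if len(s) == 0:
            raise ValidationError(f"condition group {g!r} not found")
        if len(s) < 2:
            raise ValidationError(f"group {g!r}: need >=2 samples for a t-test")
        if len(s) < 4:
            warnings.warn(
                f"group {g!r} has {len(s)} samples; <4 biological replicates",
                stacklevel=2,
            )

    a = matrix.values[sa].to_numpy(float)
    b = matrix.values[sb].to_numpy(float)
    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(la, lb, axis=1, equal_var=equal_var)
        p_raw = np.asarray(res.pvalue, float)
    # constant gene in both groups: nan from the t-test -> p=1 (no evidence)
    p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)

    p_adj = multipletests(p_raw, method="fdr_bh")[1]

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_b > 0, mean_a / np.where(mean_b > 0, mean_b, 1.0),
                      np.where(mean_a > 0, np.inf, np.nan))

    gate_p = p_adj if adjust else p_raw
    with np.errstate(invalid="ignore"):
        fc_pass = (fc > fc_high) | (fc < fc_low)
    is_de = (gate_p < alpha) & fc_pass & (np.maximum(mean_a, mean_b) > min_mean_fpkm)

    return pd.DataFrame(
        {
            "mean_fpkm_a": mean_a,
            "mean_fpkm_b": mean_b,
            "fold_change": fc,
            "p_raw": p_raw,
            "p_adjusted": p_adj,
            "is_de": is_de,
        },
        index=matrix.genes,
    )


def de_recovery_report(results: pd.DataFrame, planted_de_ids) -> dict[str, float]:
    """Sensitivity and false-discovery fraction of DE calls against planted
    ground truth. With zero calls the false-discovery fraction is reported as
    0 with the `no_calls` flag set."""
    planted = set(planted_de_ids)
    called = set(results.index[results["is_de"]])
    sensitivity = (len(called & planted) / len(planted)) if planted else float("nan")
    if called:
        fdf = len(called - planted) / len(called)
        no_calls = False
    else:
        fdf, no_calls = 0.0, True
    return {
        "sensitivity": sensitivity,
        "false_discovery_fraction": fdf,
        "n_called": len(called),
        "no_calls": no_calls,
    }
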