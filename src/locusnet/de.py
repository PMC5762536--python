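"""Fold-change / t-test differential-expression screening and summaries.

The screen mirrors common two-colour microarray practice: group means and
fold changes are computed on the linear intensity scale, the Student
t-test runs on log2-transformed values, and a feature is called
significant when both the fold-change and raw-p thresholds are met.
Benjamini-Hochberg q values are always reported alongside.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import CASE, CONTROL, DE_COLUMNS, ExpressionMatrix, LocusnetError

log = logging.getLogger(__name__)

#: Fold-change magnitude bins used for the DE histograms, closed-left/open-right.
FC_BINS = [(2.0, 5.0), (5.0, 10.0), (10.0, 50.0), (50.0, 100.0), (100.0, np.inf)]

_TINY_P = float(np.finfo(float).tiny)


def differential_expression(
    matrix: ExpressionMatrix,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Screen every feature for differential expression between groups.

    Returns a DataFrame with one row per feature and columns
    ``feature_id, mean_case, mean_control, fc, direction, p, q, significant``.

    fc is the magnitude ratio larger-mean / smaller-mean (>= 1) of the
    linear group means; a zero group mean is floored at half the smallest
    positive value in the matrix before the ratio. The two-sided t-test
    (Student by default, Welch with ``equal_var=False``) runs on log2
    values; q is BH-adjusted over all features in the matrix.
    """
    if fc_threshold <= 1.0:
        raise LocusnetError("fc_threshold must exceed 1")
    case_ids = matrix.sample_ids(CASE)
    control_ids = matrix.sample_ids(CONTROL)

    linear = matrix.values if matrix.scale == "linear" else 2.0 ** matrix.values
    log2m = matrix.log2().values

    mean_case = linear[case_ids].mean(axis=1).to_numpy()
    mean_control = linear[control_ids].mean(axis=1).to_numpy()

    eps = ExpressionMatrix(linear, dict(matrix.groups), "linear").epsilon_floor()
    floored_case = np.maximum(mean_case, eps)
    floored_control = np.maximum(mean_control, eps)
    n_floored = int(((mean_case == 0) | (mean_control == 0)).sum())
    if n_floored:
        log.info("fold change: floored %d zero group means at eps=%g", n_floored, eps)

    ratio = floored_case / floored_control
    fc = np.where(ratio >= 1.0, ratio, 1.0 / ratio)
    direction = np.where(mean_case > mean_control, "up", "down")

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant rows trigger a precision warning; the degenerate
        # cases are handled explicitly below
        warnings.filterwarnings("ignore", message="Precision loss")
        result = stats.ttest_ind(
            log2m[case_ids].to_numpy(),
            log2m[control_ids].to_numpy(),
            axis=1,
            equal_var=equal_var,
        )
    p = np.asarray(result.pvalue, dtype=float)
    # zero variance in both groups: equal means -> no evidence, p = 1;
    # p == 0 from infinite t is clipped into (0, 1]
    p = np.where(np.isnan(p), 1.0, p)
    n_clipped = int((p == 0).sum())
    if n_clipped:
        log.info("t-test: clipped %d zero p values to %g", n_clipped, _TINY_P)
    p = np.maximum(p, _TINY_P)

    q = multipletests(p, method="fdr_bh")[1]
    significant = (fc >= fc_threshold) & (p < p_threshold)

    return pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "mean_case": mean_case,
            "mean_control": mean_control,
            "fc": fc,
            "direction": direction,
            "p": p,
            "q": q,
            "significant": significant,
        },
        columns=DE_COLUMNS,
    )


def direction_counts(records: pd.DataFrame) -> dict[str, int]:
    """Counts of significant up/down features and their total."""
    sig = records[records["significant"]]
    n_up = int((sig["direction"] == "up").sum())
    n_down = int((sig["direction"] == "down").sum())
    return {"up": n_up, "down": n_down, "total": n_up + n_down}


def bin_fold_changes(records: pd.DataFrame) -> pd.DataFrame:
    """Tabulate significant features into fold-change magnitude bins.

    Bins are [2,5), [5,10), [10,50), [50,100), [100,inf), split by
    direction; counts per direction sum to that direction's significant
    total.
    """
    sig = records[records["significant"]] if len(records) else records
    rows = []
    for low, high in FC_BINS:
        label = f"[{low:g},{'inf' if np.isinf(high) else f'{high:g}'})"
        row = {"bin": label}
        for direction in ("up", "down"):
            if len(sig):
                mask = (
                    (sig["direction"] == direction)
                    & (sig["fc"] >= low)
                    & (sig["fc"] < high)
                )
                row[direction] = int(mask.sum())
            else:
                row[direction] = 0
        rows.append(row)
    return pd.DataFrame(rows, columns=["bin", "up", "down"])


def volcano_table(records: pd.DataFrame) -> pd.DataFrame:
    """Volcano-plot coordinates: signed log2 fc vs -log10 p per feature."""
    signed = np.where(
        records["direction"] == "up",
        np.log2(records["fc"]),
        -np.log2(records["fc"]),
    )
    return pd.DataFrame(
        {
            "feature_id": records["feature_id"],
            "log2_fc": signed,
            "neg_log10_p": -np.log10(records["p"]),
            "significant": records["significant"],
        }
    )
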