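"""Relative quantification by the 2^-ddCt method and array concordance.

dCt = mean(Ct_target) - mean(Ct_reference) per group;
ddCt = dCt_case - dCt_control; fold change = 2^-ddCt, reported as a
magnitude >= 1 plus a direction. Amplification efficiency is fixed at 2
(the standard ddCt model); Ct replicates aggregate by arithmetic mean.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import LocusnetError


def ddct_fold_change(
    ct_target_case: Sequence[float],
    ct_ref_case: Sequence[float],
    ct_target_control: Sequence[float],
    ct_ref_control: Sequence[float],
) -> tuple[float, str]:
    """Fold change (magnitude >= 1) and direction from four Ct replicate lists."""
    arms = [ct_target_case, ct_ref_case, ct_target_control, ct_ref_control]
    if any(len(arm) == 0 for arm in arms):
        raise LocusnetError("ddct_fold_change: empty Ct replicate list")
    arms = [np.asarray(arm, dtype=float) for arm in arms]
    if any(not np.isfinite(arm).all() for arm in arms):
        raise LocusnetError("ddct_fold_change: non-finite Ct value")
    dct_case = arms[0].mean() - arms[1].mean()
    dct_control = arms[2].mean() - arms[3].mean()
    ddct = dct_case - dct_control
    fold = float(2.0 ** (-ddct))
    if fold >= 1.0:
        return fold, "up"
    return 1.0 / fold, "down"


def ddct_from_table(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Per-feature fold changes from a long-format Ct table.

    Expected columns: feature_id, sample_id, group, target_ct, ref_ct.
    Also reports a two-sample t-test on the per-sample dCt values between
    groups.
    """
    required = {"feature_id", "sample_id", "group", "target_ct", "ref_ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise LocusnetError(f"Ct table missing columns: {sorted(missing)}")
    rows = []
    for fid, sub in ct_table.groupby("feature_id", sort=True):
        case = sub[sub["group"] == "case"]
        control = sub[sub["group"] == "control"]
        fold, direction = ddct_fold_change(
            case["target_ct"].to_numpy(),
            case["ref_ct"].to_numpy(),
            control["target_ct"].to_numpy(),
            control["ref_ct"].to_numpy(),
        )
        dct_case = (case["target_ct"] - case["ref_ct"]).to_numpy()
        dct_control = (control["target_ct"] - control["ref_ct"]).to_numpy()
        if len(dct_case) >= 2 and len(dct_control) >= 2 and (
            np.std(dct_case) > 0 or np.std(dct_control) > 0
        ):
            p = float(stats.ttest_ind(dct_case, dct_control).pvalue)
        else:
            p = float("nan")
        rows.append(
            {"feature_id": fid, "fold_change": fold, "direction": direction, "p": p}
        )
    return pd.DataFrame(rows, columns=["feature_id", "fold_change", "direction", "p"])


def concordance(qpcr_results: pd.DataFrame, de_records: pd.DataFrame) -> pd.DataFrame:
    """Direction agreement between qPCR fold changes and the array screen.

    Returns one row per shared feature with both directions and an
    ``agree`` flag; the fraction concordant is ``result["agree"].mean()``.
    """
    array = de_records.set_index("feature_id")
    rows = []
    for row in qpcr_results.itertuples(index=False):
        if row.feature_id not in array.index:
            continue
        array_direction = array.loc[row.feature_id, "direction"]
        rows.append(
            {
                "feature_id": row.feature_id,
                "qpcr_direction": row.direction,
                "array_direction": array_direction,
                "qpcr_fold_change": row.fold_change,
                "array_fc": float(array.loc[row.feature_id, "fc"]),
                "agree": row.direction == array_direction,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id",
            "qpcr_direction",
            "array_direction",
            "qpcr_fold_change",
            "array_fc",
            "agree",
        ],
    )
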