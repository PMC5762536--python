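"""Quantile normalization of linear-scale intensity matrices.

Classic across-array quantile normalization: every column is forced onto
the common reference distribution obtained by averaging the per-column
order statistics. After normalization the sorted values of every column
are identical, which removes array-to-array intensity distribution
differences while preserving within-array ranks.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .types import ExpressionMatrix, LocusnetError


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize a linear-scale matrix across its sample columns.

    Rank each column; replace the value at rank k everywhere by the mean of
    the k-th order statistics of all columns. Ties within a column receive
    the mean of the reference values their rank range spans, so the
    operation is well defined and symmetric for tied inputs.
    """
    if matrix.scale != "linear":
        raise LocusnetError("quantile normalization expects a linear-scale matrix")
    if matrix.n_samples < 2:
        raise LocusnetError("quantile normalization needs >= 2 samples")

    values = matrix.values.to_numpy(float)
    reference = np.sort(values, axis=0).mean(axis=1)
    # prefix sums let a tie spanning ranks [lo, hi] take mean(ref[lo-1:hi])
    prefix = np.concatenate([[0.0], np.cumsum(reference)])

    out = np.empty_like(values)
    for j in range(values.shape[1]):
        lo = rankdata(values[:, j], method="min").astype(int)
        hi = rankdata(values[:, j], method="max").astype(int)
        out[:, j] = (prefix[hi] - prefix[lo - 1]) / (hi - lo + 1)

    frame = matrix.values.copy()
    frame.loc[:, :] = out
    return ExpressionMatrix(frame, dict(matrix.groups), "linear")
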