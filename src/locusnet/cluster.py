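"""Hierarchical clustering of samples or features by expression profile.

Distance is 1 - Pearson correlation on log2 values with average linkage,
the usual display choice for microarray heat maps. Constant items have an
undefined correlation; their distance to everything defaults to 1.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .types import ExpressionMatrix, LinkageResult, LocusnetError

log = logging.getLogger(__name__)


def hierarchical_cluster(
    matrix: ExpressionMatrix,
    axis: str = "samples",
    method: str = "average",
) -> LinkageResult:
    """Agglomeratively cluster samples or features.

    ``axis='samples'`` clusters the sample columns (the case/control
    separation check); ``axis='features'`` clusters feature rows.
    """
    if axis not in ("samples", "features"):
        raise LocusnetError(f"unknown clustering axis {axis!r}")
    log2m = matrix.log2().values
    if axis == "samples":
        data = log2m.to_numpy().T
        labels = list(log2m.columns)
    else:
        data = log2m.to_numpy()
        labels = list(log2m.index)
    if data.shape[0] < 3:
        raise LocusnetError("clustering needs >= 3 items on the chosen axis")

    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data)
    dist = 1.0 - corr
    n_undefined = int(np.isnan(dist).sum())
    if n_undefined:
        log.info(
            "clustering: %d undefined correlations (constant items) set to distance 1",
            n_undefined,
        )
        dist = np.where(np.isnan(dist), 1.0, dist)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # enforce symmetry

    merge = scipy_linkage(squareform(dist, checks=False), method=method)
    return LinkageResult(
        linkage=merge, labels=labels, metric="1-pearson", method=method
    )
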