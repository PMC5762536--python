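"""lncRNA-mRNA co-expression network construction.

All pairs of differentially expressed lncRNAs and mRNAs are scored with
the Pearson correlation of their log2 expression across the shared
samples; an edge is kept when |r| clears the correlation threshold and
the (BH-adjusted by default) p value clears the significance threshold.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import EDGE_COLUMNS, ExpressionMatrix, LocusnetError

log = logging.getLogger(__name__)


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r and its two-sided p from the t transform.

    p comes from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise LocusnetError("pearson_with_p expects two equal-length vectors")
    n = x.size
    if n < 3:
        raise LocusnetError("pearson_with_p needs >= 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise LocusnetError("non-finite values in correlation input")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise LocusnetError("zero variance in correlation input")
    r = float(np.clip((xc @ yc) / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, p


def _pairwise_correlation(
    lnc_values: np.ndarray, mrna_values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised all-pairs Pearson r and two-sided p between two row sets."""
    n = lnc_values.shape[1]
    lc = lnc_values - lnc_values.mean(axis=1, keepdims=True)
    mc = mrna_values - mrna_values.mean(axis=1, keepdims=True)
    lnorm = np.sqrt((lc * lc).sum(axis=1))
    mnorm = np.sqrt((mc * mc).sum(axis=1))
    r = (lc @ mc.T) / np.outer(lnorm, mnorm)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) == 1.0] = 0.0
    return r, p


def build_edges(
    lnc_matrix: ExpressionMatrix,
    mrna_matrix: ExpressionMatrix,
    de_lnc_ids: Sequence[str],
    de_mrna_ids: Sequence[str],
    r_min: float = 0.90,
    q_max: float = 0.01,
    use_q: bool = True,
) -> pd.DataFrame:
    """Score all DE-lncRNA x DE-mRNA pairs and keep the strong, significant ones.

    Correlations run on log2 values over the shared sample order. BH q is
    computed over every scored pair; an edge survives iff |r| >= r_min and
    q < q_max (raw p with ``use_q=False``). Zero-variance features are
    skipped with a logged count. Returns an edge table sorted by
    (lncrna_id, mrna_id).
    """
    if lnc_matrix.sample_ids() != mrna_matrix.sample_ids():
        raise LocusnetError("lncRNA and mRNA matrices must share samples in order")

    log2_lnc = lnc_matrix.log2().values
    log2_mrna = mrna_matrix.log2().values
    lnc_ids = [f for f in de_lnc_ids if f in log2_lnc.index]
    mrna_ids = [f for f in de_mrna_ids if f in log2_mrna.index]
    lv = log2_lnc.loc[lnc_ids].to_numpy()
    mv = log2_mrna.loc[mrna_ids].to_numpy()

    keep_l = lv.std(axis=1) > 0
    keep_m = mv.std(axis=1) > 0
    n_skipped = int((~keep_l).sum() + (~keep_m).sum())
    if n_skipped:
        log.info("build_edges: skipped %d zero-variance features", n_skipped)
    lnc_ids = [f for f, k in zip(lnc_ids, keep_l) if k]
    mrna_ids = [f for f, k in zip(mrna_ids, keep_m) if k]
    lv, mv = lv[keep_l], mv[keep_m]

    if lv.size == 0 or mv.size == 0:
        return pd.DataFrame(columns=EDGE_COLUMNS)

    r, p = _pairwise_correlation(lv, mv)
    q = multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)
    crit = q if use_q else p
    keep = (np.abs(r) >= r_min) & (crit < q_max)

    li, mi = np.nonzero(keep)
    edges = pd.DataFrame(
        {
            "lncrna_id": [lnc_ids[i] for i in li],
            "mrna_id": [mrna_ids[j] for j in mi],
            "r": r[li, mi],
            "p": p[li, mi],
            "q": q[li, mi],
            "sign": np.where(r[li, mi] >= 0, "positive", "negative"),
        },
        columns=EDGE_COLUMNS,
    )
    return edges.sort_values(["lncrna_id", "mrna_id"]).reset_index(drop=True)


def gene_neighborhood(
    edges: pd.DataFrame,
    gene_id: str,
    feature_to_gene: Mapping[str, str],
) -> pd.DataFrame:
    """Edges incident to one coding gene, labelled by lncRNA gene of origin.

    ``feature_to_gene`` maps transcript/feature ids to gene ids for both
    edge endpoints, so multi-transcript lncRNA genes group together (the
    multi-isoform partner view). Unknown gene ids yield an empty result
    with a logged warning.
    """
    if edges.empty:
        return pd.DataFrame(columns=list(edges.columns) + ["lncrna_gene"])
    mrna_genes = edges["mrna_id"].map(lambda f: feature_to_gene.get(f, f))
    hit = edges[mrna_genes == gene_id].copy()
    if hit.empty:
        log.warning("gene_neighborhood: no edges incident to %r", gene_id)
        return pd.DataFrame(columns=list(edges.columns) + ["lncrna_gene"])
    hit["lncrna_gene"] = hit["lncrna_id"].map(lambda f: feature_to_gene.get(f, f))
    return hit.sort_values(["sign", "lncrna_gene", "lncrna_id"]).reset_index(drop=True)
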