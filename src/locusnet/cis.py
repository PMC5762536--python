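"""Cis-regulation pairing: dysregulated lncRNAs vs nearby coding genes.

The procedure selects the most dysregulated lncRNAs, pairs each with the
coding genes whose locus lies within a genomic window (300 kb by default)
up- or downstream, and keeps the pairs whose expression correlation is
significant. Distances are gaps between closest interval edges on the
0-based half-open convention, boundary inclusive; overlap means distance
zero.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .network import pearson_with_p
from .types import (
    CIS_COLUMNS,
    ExpressionMatrix,
    FeatureAnnotation,
    LocusnetError,
    interval_gap,
)

log = logging.getLogger(__name__)


def select_top_lncrnas(records: pd.DataFrame, n: int = 200) -> list[str]:
    """Ids of the n significant lncRNAs with the largest fold-change magnitude.

    Ties break by smaller p, then lexicographic feature id. If fewer than n
    records are significant, all of them are returned with a logged note.
    """
    sig = records[records["significant"]]
    if len(sig) < n:
        log.info("select_top_lncrnas: only %d significant records for n=%d", len(sig), n)
    ordered = sig.sort_values(
        ["fc", "p", "feature_id"], ascending=[False, True, True]
    )
    return ordered["feature_id"].head(n).tolist()


def _relation(lnc: FeatureAnnotation, mrna: FeatureAnnotation) -> str:
    """Position of the mRNA relative to the lncRNA, on the lncRNA's strand."""
    if lnc.start < mrna.end and mrna.start < lnc.end:
        return "overlapping"
    mrna_is_left = mrna.end <= lnc.start
    if lnc.strand == "+":
        return "upstream" if mrna_is_left else "downstream"
    return "downstream" if mrna_is_left else "upstream"


def find_cis_pairs(
    lnc_ids: Sequence[str],
    annotation: Mapping[str, FeatureAnnotation],
    lnc_matrix: ExpressionMatrix,
    mrna_matrix: ExpressionMatrix,
    mrna_ids: Sequence[str] | None = None,
    window: int = 300_000,
    p_max: float = 0.05,
    edges: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pair each selected lncRNA with correlated coding genes within the window.

    ``mrna_ids`` restricts the candidate coding universe (the pipeline
    passes the DE coding genes); ``edges`` optionally restricts candidates
    further to pairs that already passed the co-expression network gate.
    Window membership is purely positional (strand-blind); the strand only
    names the up/downstream relation. Returns a cis-pair table sorted by
    (lncrna_id, mrna_id).
    """
    if lnc_matrix.sample_ids() != mrna_matrix.sample_ids():
        raise LocusnetError("lncRNA and mRNA matrices must share samples in order")
    if mrna_ids is None:
        mrna_ids = [
            f for f, a in annotation.items()
            if a.biotype == "coding" and f in mrna_matrix.values.index
        ]
    unannotated = [f for f in list(lnc_ids) + list(mrna_ids) if f not in annotation]
    if unannotated:
        raise LocusnetError(f"unannotated feature ids: {sorted(set(unannotated))[:10]}")

    allowed_pairs: set[tuple[str, str]] | None = None
    if edges is not None:
        allowed_pairs = set(zip(edges["lncrna_id"], edges["mrna_id"]))

    trees: dict[str, IntervalTree] = {}
    for mid in mrna_ids:
        ann = annotation[mid]
        trees.setdefault(ann.chrom, IntervalTree()).addi(ann.start, ann.end, mid)

    log2_lnc = lnc_matrix.log2().values
    log2_mrna = mrna_matrix.log2().values

    rows = []
    for lid in lnc_ids:
        lnc = annotation[lid]
        tree = trees.get(lnc.chrom)
        if tree is None:
            continue
        # query envelope is 1 bp wider on both sides so that a gap of
        # exactly `window` (boundary inclusive) is still retrieved
        for hit in tree.overlap(lnc.start - window - 1, lnc.end + window + 1):
            mid = hit.data
            mrna = annotation[mid]
            distance = interval_gap(lnc.start, lnc.end, mrna.start, mrna.end)
            if distance > window:
                continue
            if allowed_pairs is not None and (lid, mid) not in allowed_pairs:
                continue
            try:
                r, p = pearson_with_p(
                    log2_lnc.loc[lid].to_numpy(), log2_mrna.loc[mid].to_numpy()
                )
            except LocusnetError as exc:
                log.info("find_cis_pairs: skipped pair (%s, %s): %s", lid, mid, exc)
                continue
            rows.append(
                {
                    "lncrna_id": lid,
                    "mrna_id": mid,
                    "r": r,
                    "p": p,
                    "q": np.nan,
                    "sign": "positive" if r >= 0 else "negative",
                    "distance_bp": distance,
                    "relation": _relation(lnc, mrna),
                }
            )
    scored = pd.DataFrame(rows, columns=CIS_COLUMNS)
    if len(scored):
        from statsmodels.stats.multitest import multipletests

        # q over every scored window pair, reported for reference; the
        # retention rule itself is the raw-p criterion
        scored["q"] = multipletests(scored["p"], method="fdr_bh")[1]
        scored = scored[scored["p"] < p_max]
    return scored.sort_values(["lncrna_id", "mrna_id"]).reset_index(drop=True)


def count_localized(lnc_ids: Sequence[str], pairs: pd.DataFrame) -> int:
    """Number of selected lncRNAs participating in at least one cis pair."""
    if pairs.empty:
        return 0
    paired = set(pairs["lncrna_id"])
    return sum(1 for lid in lnc_ids if lid in paired)
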