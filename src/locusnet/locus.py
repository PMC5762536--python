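"""Imprinted-locus miRNA silencing summary.

miRNAs whose annotated interval intersects a genomic locus are classified
up/down/unchanged by the two-fold rule — fold-change magnitude at least 2
in the respective direction, with no p-value gate — and summarised as
counts plus percentages (half-up rounding to two decimals).
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .types import FeatureAnnotation, LocusSummary, LocusnetError


def parse_locus(spec: str) -> tuple[str, int, int]:
    """Parse a ``chrom:start-end`` locus string (0-based half-open)."""
    try:
        chrom, span = spec.split(":")
        start_s, end_s = span.replace(",", "").split("-")
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise LocusnetError(f"cannot parse locus {spec!r}; want chrom:start-end") from exc
    if start >= end:
        raise LocusnetError(f"locus {spec!r}: start must be < end")
    return chrom, start, end


def classify_locus_mirnas(
    mirna_de: pd.DataFrame,
    locus: tuple[str, int, int],
    annotation: Mapping[str, FeatureAnnotation],
    fc_threshold: float = 2.0,
    p_threshold: float | None = None,
) -> dict[str, str]:
    """Status (up/down/unchanged) for every annotated miRNA inside the locus.

    Membership is interval intersection with the locus. The default rule is
    fold-change-only (threshold inclusive); pass ``p_threshold`` to add a
    raw-p gate on top.
    """
    chrom, start, end = locus
    members = [
        fid
        for fid in mirna_de["feature_id"]
        if fid in annotation
        and annotation[fid].biotype == "miRNA"
        and annotation[fid].chrom == chrom
        and annotation[fid].start < end
        and start < annotation[fid].end
    ]
    if not members:
        raise LocusnetError(f"locus {chrom}:{start}-{end} contains no annotated miRNAs")

    indexed = mirna_de.set_index("feature_id")
    statuses: dict[str, str] = {}
    for fid in members:
        row = indexed.loc[fid]
        changed = row["fc"] >= fc_threshold
        if p_threshold is not None:
            changed = changed and row["p"] < p_threshold
        statuses[fid] = row["direction"] if changed else "unchanged"
    return statuses


def locus_summary(statuses: Mapping[str, str]) -> LocusSummary:
    """Counts and percentages of up/down/unchanged miRNAs in the locus."""
    return LocusSummary.from_statuses(statuses)


def status_table(statuses: Mapping[str, str]) -> pd.DataFrame:
    return pd.DataFrame(
        sorted(statuses.items()), columns=["mirna_id", "status"]
    )
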