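"""Strand-aware positional classification of lncRNAs against coding genes.

Each lncRNA is assigned exactly one of five conventional positional
classes relative to the coding annotation, by a fixed decision cascade:

1. intronic      - wholly inside a same-strand coding gene without touching
                   any of its exons (needs an exon model; without one this
                   class collapses into sense)
2. sense         - overlapping a same-strand coding gene (its exons, when
                   an exon model is given)
3. antisense     - overlapping an opposite-strand coding gene
4. bidirectional - no overlap, divergently oriented head-to-head with a
                   coding gene, 5' starts within a small window (1 kb)
5. intergenic    - none of the above
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .types import FeatureAnnotation, LocusnetError, interval_gap

CLASSES = ("sense", "antisense", "bidirectional", "intergenic", "intronic")

ExonModel = Mapping[str, Sequence[tuple[int, int]]]


def _overlaps(a: FeatureAnnotation, start: int, end: int) -> bool:
    return a.start < end and start < a.end


def _is_divergent(lnc: FeatureAnnotation, coding: FeatureAnnotation) -> bool:
    """Head-to-head orientation: 5' ends adjacent, transcription pointing apart."""
    if lnc.strand == coding.strand:
        return False
    if lnc.strand == "-" and coding.strand == "+":
        return lnc.end <= coding.start
    return lnc.start >= coding.end  # lnc '+', coding '-'


def classify_lncrna(
    lncrna: FeatureAnnotation,
    coding_set: Sequence[FeatureAnnotation],
    coding_exons: ExonModel | None = None,
    bidir_window: int = 1000,
) -> str:
    """Classify one lncRNA against the coding annotation.

    Total function over stranded lncRNAs: exactly one class is returned.
    """
    if lncrna.biotype != "lncRNA":
        raise LocusnetError(f"{lncrna.feature_id}: not a lncRNA feature")
    if lncrna.strand not in ("+", "-"):
        raise LocusnetError(f"{lncrna.feature_id}: lncRNA strand undefined")

    same_chrom = [c for c in coding_set if c.biotype == "coding" and c.chrom == lncrna.chrom]
    overlapping = [c for c in same_chrom if _overlaps(c, lncrna.start, lncrna.end)]

    # intronic: wholly inside a same-strand gene, clear of all its exons
    if coding_exons is not None:
        for coding in overlapping:
            if coding.strand != lncrna.strand:
                continue
            if not (coding.start <= lncrna.start and lncrna.end <= coding.end):
                continue
            exons = coding_exons.get(coding.gene_id, ())
            if exons and not any(
                lncrna.start < ex_end and ex_start < lncrna.end
                for ex_start, ex_end in exons
            ):
                return "intronic"

    for coding in overlapping:
        if coding.strand != lncrna.strand:
            continue
        if coding_exons is not None and coding_exons.get(coding.gene_id):
            if any(
                lncrna.start < ex_end and ex_start < lncrna.end
                for ex_start, ex_end in coding_exons[coding.gene_id]
            ):
                return "sense"
        else:
            return "sense"

    if any(c.strand != lncrna.strand for c in overlapping):
        return "antisense"

    for coding in same_chrom:
        if _overlaps(coding, lncrna.start, lncrna.end):
            continue
        if _is_divergent(lncrna, coding) and abs(lncrna.tss - coding.tss) <= bidir_window:
            return "bidirectional"

    return "intergenic"


def classify_all(
    lncrnas: Sequence[FeatureAnnotation],
    coding_set: Sequence[FeatureAnnotation],
    coding_exons: ExonModel | None = None,
    bidir_window: int = 1000,
) -> pd.DataFrame:
    """Classify many lncRNAs; adds nearest coding gene and its distance."""
    coding = [c for c in coding_set if c.biotype == "coding"]
    rows = []
    for lnc in lncrnas:
        label = classify_lncrna(lnc, coding, coding_exons, bidir_window)
        nearest, distance = None, None
        candidates = [c for c in coding if c.chrom == lnc.chrom]
        if candidates:
            gaps = [
                (interval_gap(lnc.start, lnc.end, c.start, c.end), c.gene_id)
                for c in candidates
            ]
            distance, nearest = min(gaps)
        rows.append(
            {
                "lncrna_id": lnc.feature_id,
                "class": label,
                "nearest_coding_gene": nearest if nearest is not None else "",
                "distance_bp": distance if distance is not None else -1,
            }
        )
    return pd.DataFrame(rows, columns=["lncrna_id", "class", "nearest_coding_gene", "distance_bp"])


def subgroup_counts(
    de_records: pd.DataFrame, classifications: Mapping[str, str]
) -> pd.DataFrame:
    """5 x 2 table of significant lncRNAs per positional class and direction."""
    sig = de_records[de_records["significant"]]
    missing = [f for f in sig["feature_id"] if f not in classifications]
    if missing:
        raise LocusnetError(f"unclassified DE lncRNAs: {missing[:5]}")
    rows = []
    for cls in CLASSES:
        row = {"class": cls}
        for direction in ("up", "down"):
            row[direction] = int(
                sum(
                    1
                    for fid, d in zip(sig["feature_id"], sig["direction"])
                    if classifications[fid] == cls and d == direction
                )
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=["class", "up", "down"])
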