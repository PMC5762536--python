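"""Readers and writers for the text formats the pipeline touches.

Expression matrices and group maps are tab-separated text; annotation comes
in as BED6 (name field ``feature_id|gene_id|biotype``) or GFF3 (attributes
``feature_id``/``gene_id``/``biotype``); gene sets as GMT; networks go out
as Cytoscape-compatible SIF and as TSV.

Coordinates are 0-based half-open internally. GFF3 (1-based closed) is
converted at this boundary and nowhere else.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .types import (
    EDGE_COLUMNS,
    ExpressionMatrix,
    FeatureAnnotation,
    GeneSet,
    GeneSetCollection,
    LocusnetError,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping sample id to case/control."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "group"],
                        dtype=str, comment="#")
    if frame["sample_id"].duplicated().any():
        raise LocusnetError(f"{path}: duplicate sample ids in group map")
    return dict(zip(frame["sample_id"], frame["group"]))


def read_expression_matrix(
    path: str | Path,
    groups_path: str | Path,
    scale: str = "linear",
) -> ExpressionMatrix:
    """Load a feature-by-sample TSV plus its sample group map.

    The first column holds feature ids, the header row sample ids. Rows
    containing any missing value are dropped (with a logged count) before
    validation; all other contract violations raise.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise LocusnetError(f"{path}: duplicate feature ids: {dups[:5]}")
    n_missing = int(frame.isna().any(axis=1).sum())
    if n_missing:
        log.info("%s: dropped %d feature rows with missing values", path, n_missing)
        frame = frame.dropna(axis=0)
    groups = read_groups(groups_path)
    absent = [s for s in frame.columns if s not in groups]
    if absent:
        raise LocusnetError(
            f"{path}: samples missing from group map {groups_path}: {absent}"
        )
    groups = {s: groups[s] for s in frame.columns}
    return ExpressionMatrix(frame.astype(float), groups, scale)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")


def write_groups(groups: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as handle:
        for sample, group in groups.items():
            handle.write(f"{sample}\t{group}\n")


# ---------------------------------------------------------------------------
# genomic annotation
# ---------------------------------------------------------------------------

def _parse_bed_line(line: str, path, lineno: int) -> FeatureAnnotation:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise LocusnetError(f"{path}:{lineno}: BED6 needs 6 columns, got {len(fields)}")
    chrom, start, end, name, _score, strand = fields[:6]
    parts = name.split("|")
    if len(parts) != 3:
        raise LocusnetError(
            f"{path}:{lineno}: BED name must be 'feature_id|gene_id|biotype'"
        )
    feature_id, gene_id, biotype = parts
    try:
        return FeatureAnnotation(
            feature_id=feature_id,
            gene_id=gene_id,
            chrom=chrom,
            start=int(start),
            end=int(end),
            strand=strand,
            biotype=biotype,
        )
    except LocusnetError as exc:
        raise LocusnetError(f"{path}:{lineno}: {exc}") from exc


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for item in text.strip().rstrip(";").split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def _parse_gff3_line(line: str, path, lineno: int) -> FeatureAnnotation:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 9:
        raise LocusnetError(f"{path}:{lineno}: GFF3 needs 9 columns, got {len(fields)}")
    chrom, _source, _type, start, end, _score, strand, _phase, attr_text = fields
    attrs = _parse_gff3_attributes(attr_text)
    for key in ("feature_id", "gene_id", "biotype"):
        if key not in attrs:
            raise LocusnetError(f"{path}:{lineno}: GFF3 attribute {key!r} missing")
    try:
        return FeatureAnnotation(
            feature_id=attrs["feature_id"],
            gene_id=attrs["gene_id"],
            chrom=chrom,
            start=int(start) - 1,  # 1-based closed -> 0-based half-open
            end=int(end),
            strand=strand,
            biotype=attrs["biotype"],
        )
    except LocusnetError as exc:
        raise LocusnetError(f"{path}:{lineno}: {exc}") from exc


def read_annotation(path: str | Path) -> list[FeatureAnnotation]:
    """Read BED6 or GFF3 annotation into a list of FeatureAnnotation.

    Format is chosen by extension (.bed vs .gff/.gff3). Feature ids must be
    unique across the file.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".bed":
        parse = _parse_bed_line
    elif suffix in (".gff", ".gff3"):
        parse = _parse_gff3_line
    else:
        raise LocusnetError(f"{path}: unknown annotation format {suffix!r}")
    records: list[FeatureAnnotation] = []
    seen: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            record = parse(line, path, lineno)
            if record.feature_id in seen:
                raise LocusnetError(
                    f"{path}:{lineno}: duplicate feature_id {record.feature_id}"
                )
            seen.add(record.feature_id)
            records.append(record)
    return records


def write_annotation_bed(
    annotations: Iterable[FeatureAnnotation], path: str | Path
) -> None:
    with open(path, "w") as handle:
        for ann in annotations:
            name = f"{ann.feature_id}|{ann.gene_id}|{ann.biotype}"
            handle.write(
                f"{ann.chrom}\t{ann.start}\t{ann.end}\t{name}\t0\t{ann.strand}\n"
            )


def read_exon_table(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read a gene_id/start/end TSV into an exon model (0-based half-open)."""
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    model: dict[str, list[tuple[int, int]]] = {}
    for row in frame.itertuples(index=False):
        if row.start >= row.end:
            raise LocusnetError(f"{path}: exon with start >= end for {row.gene_id}")
        model.setdefault(row.gene_id, []).append((int(row.start), int(row.end)))
    return model


def write_exon_table(
    model: dict[str, list[tuple[int, int]]], path: str | Path
) -> None:
    with open(path, "w") as handle:
        handle.write("gene_id\tstart\tend\n")
        for gene_id in sorted(model):
            for start, end in sorted(model[gene_id]):
                handle.write(f"{gene_id}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: set id, description, then member ids, tab-separated."""
    collection = GeneSetCollection()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise LocusnetError(
                    f"{path}:{lineno}: GMT line needs >= 3 fields, got {len(fields)}"
                )
            set_id, name, *members = fields
            members = tuple(dict.fromkeys(m for m in members if m))
            if not members:
                raise LocusnetError(f"{path}:{lineno}: gene set {set_id} is empty")
            try:
                collection.add(GeneSet(set_id=set_id, name=name, members=members))
            except LocusnetError as exc:
                raise LocusnetError(f"{path}:{lineno}: {exc}") from exc
    return collection


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as handle:
        for gene_set in collection:
            handle.write(
                "\t".join([gene_set.set_id, gene_set.name, *gene_set.members]) + "\n"
            )


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

def write_network(
    edges: pd.DataFrame, path: str | Path, format: str = "sif"
) -> None:
    """Write correlation edges as Cytoscape SIF or as a TSV with statistics.

    Output is sorted by (lncrna_id, mrna_id) regardless of input order.
    """
    ordered = edges.sort_values(["lncrna_id", "mrna_id"]).reset_index(drop=True)
    if format == "sif":
        with open(path, "w") as handle:
            for row in ordered.itertuples(index=False):
                interaction = "pos" if row.sign == "positive" else "neg"
                handle.write(f"{row.lncrna_id} {interaction} {row.mrna_id}\n")
    elif format == "tsv":
        cols = [c for c in EDGE_COLUMNS if c in ordered.columns]
        extra = [c for c in ordered.columns if c not in cols]
        ordered[cols + extra].to_csv(path, sep="\t", index=False, float_format="%.6g")
    else:
        raise LocusnetError(f"unknown network format {format!r}")


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV table writer used by all pipeline outputs."""
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
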