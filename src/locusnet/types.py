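"""Core domain types shared by every pipeline stage.

The heavy tabular currencies of the pipeline (differential-expression
tables, correlation edges, cis pairs, enrichment results) are plain
:class:`pandas.DataFrame` objects with documented column sets; the light
structured values live here as dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"
GROUPS = (CASE, CONTROL)

BIOTYPES = ("coding", "lncRNA", "miRNA")
STRANDS = ("+", "-")

#: Columns of a differential-expression table (one row per feature).
DE_COLUMNS = [
    "feature_id",
    "mean_case",
    "mean_control",
    "fc",
    "direction",
    "p",
    "q",
    "significant",
]

#: Columns of a correlation-edge table (one row per lncRNA-mRNA pair).
EDGE_COLUMNS = ["lncrna_id", "mrna_id", "r", "p", "q", "sign"]

#: Columns of a cis-pair table (edge columns plus genomic context).
CIS_COLUMNS = EDGE_COLUMNS + ["distance_bp", "relation"]

#: Columns of an enrichment table (one row per gene set tested).
ENRICHMENT_COLUMNS = ["set_id", "name", "k", "m", "n", "N", "p", "fdr", "significant"]


class LocusnetError(ValueError):
    """Base class for malformed-input and contract violations."""


@dataclass(frozen=True)
class FeatureAnnotation:
    """Genomic record for one feature, 0-based half-open coordinates."""

    feature_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise LocusnetError(
                f"feature {self.feature_id}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.biotype not in BIOTYPES:
            raise LocusnetError(
                f"feature {self.feature_id}: unknown biotype {self.biotype!r}"
            )
        if self.strand not in STRANDS:
            if self.biotype in ("coding", "lncRNA"):
                raise LocusnetError(
                    f"feature {self.feature_id}: strand required for "
                    f"{self.biotype} features"
                )

    @property
    def tss(self) -> int:
        """5' end of the feature on its own strand."""
        return self.start if self.strand == "+" else self.end


def annotation_by_id(
    annotations: Sequence[FeatureAnnotation],
) -> dict[str, FeatureAnnotation]:
    index: dict[str, FeatureAnnotation] = {}
    for ann in annotations:
        if ann.feature_id in index:
            raise LocusnetError(f"duplicate feature_id in annotation: {ann.feature_id}")
        index[ann.feature_id] = ann
    return index


def interval_gap(start1: int, end1: int, start2: int, end2: int) -> int:
    """Gap in bp between two half-open intervals; 0 when they intersect or touch."""
    if end1 <= start2:
        return start2 - end1
    if end2 <= start1:
        return start1 - end2
    return 0


@dataclass
class ExpressionMatrix:
    """Feature x sample intensity table with group labels.

    ``values`` is indexed by feature id with sample ids as columns.
    ``scale`` records whether intensities are linear or log2; stages that
    need the other scale convert explicitly.
    """

    values: pd.DataFrame
    groups: Mapping[str, str]
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise LocusnetError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise LocusnetError(f"duplicate feature ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            raise LocusnetError("duplicate sample ids")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise LocusnetError(f"samples without a group label: {missing}")
        bad = {s: g for s, g in self.groups.items() if g not in GROUPS}
        if bad:
            raise LocusnetError(f"unknown group labels: {bad}")
        for grp in GROUPS:
            if len(self.sample_ids(grp)) < 2:
                raise LocusnetError(f"group {grp!r} needs >= 2 samples")
        if self.values.isna().any().any():
            raise LocusnetError("missing values in expression matrix")
        if self.scale == "linear" and (self.values.to_numpy() < 0).any():
            raise LocusnetError("negative intensities on linear scale")

    # -- accessors -------------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    def sample_ids(self, group: str | None = None) -> list[str]:
        if group is None:
            return list(self.values.columns)
        return [s for s in self.values.columns if self.groups[s] == group]

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    # -- transforms ------------------------------------------------------

    def epsilon_floor(self) -> float:
        """Half the smallest positive value; the floor used in place of zeros."""
        vals = self.values.to_numpy(float)
        positive = vals[vals > 0]
        if positive.size == 0:
            return 0.5
        return float(positive.min()) / 2.0

    def log2(self) -> "ExpressionMatrix":
        """Return a log2-scale copy (zeros floored at epsilon_floor)."""
        if self.scale == "log2":
            return ExpressionMatrix(self.values.copy(), dict(self.groups), "log2")
        eps = self.epsilon_floor()
        vals = np.log2(np.maximum(self.values.to_numpy(float), eps))
        frame = pd.DataFrame(vals, index=self.values.index, columns=self.values.columns)
        return ExpressionMatrix(frame, dict(self.groups), "log2")

    def subset(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(feature_ids)], dict(self.groups), self.scale
        )

    def swap_groups(self) -> "ExpressionMatrix":
        flipped = {
            s: (CONTROL if g == CASE else CASE) for s, g in self.groups.items()
        }
        return ExpressionMatrix(self.values.copy(), flipped, self.scale)


def _round_half_up(x: float, ndigits: int = 2) -> float:
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LocusSummary:
    """Up/down/unchanged composition of the miRNAs inside one locus."""

    n_total: int
    n_up: int
    n_down: int
    n_unchanged: int
    pct_up: float
    pct_down: float
    pct_unchanged: float

    @classmethod
    def from_counts(cls, n_up: int, n_down: int, n_unchanged: int) -> "LocusSummary":
        n_total = n_up + n_down + n_unchanged
        if n_total == 0:
            raise LocusnetError("empty locus: no miRNA statuses to summarise")
        pct = lambda k: _round_half_up(100.0 * k / n_total)  # noqa: E731
        return cls(
            n_total=n_total,
            n_up=n_up,
            n_down=n_down,
            n_unchanged=n_unchanged,
            pct_up=pct(n_up),
            pct_down=pct(n_down),
            pct_unchanged=pct(n_unchanged),
        )

    @classmethod
    def from_statuses(cls, statuses: Mapping[str, str]) -> "LocusSummary":
        vals = list(statuses.values())
        unknown = sorted(set(vals) - {"up", "down", "unchanged"})
        if unknown:
            raise LocusnetError(f"unknown miRNA statuses: {unknown}")
        return cls.from_counts(
            vals.count("up"), vals.count("down"), vals.count("unchanged")
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "status": ["up", "down", "unchanged", "total"],
                "n": [self.n_up, self.n_down, self.n_unchanged, self.n_total],
                "pct": [self.pct_up, self.pct_down, self.pct_unchanged, 100.0],
            }
        )


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """Named gene sets keyed by set id (GMT semantics)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.set_id in self.sets:
            raise LocusnetError(f"duplicate gene-set id: {gene_set.set_id}")
        if not gene_set.members:
            raise LocusnetError(f"gene set {gene_set.set_id} has no members")
        self.sets[gene_set.set_id] = gene_set

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]


@dataclass
class LinkageResult:
    """Merge history of agglomerative clustering over samples or features."""

    linkage: np.ndarray  # scipy (n-1) x 4 merge table
    labels: list[str]
    metric: str
    method: str

    @property
    def n_merges(self) -> int:
        return self.linkage.shape[0]

    def cut(self, n_clusters: int) -> dict[str, int]:
        from scipy.cluster.hierarchy import fcluster

        assignment = fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assignment)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage, columns=["item_a", "item_b", "height", "size"]
        )
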