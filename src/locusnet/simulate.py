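"""Synthetic paired case/control datasets with known ground truth.

The generator emulates the structure of a small two-group microarray
study of a tumour against a developmental control tissue: three case and
three control samples, three feature classes (coding transcripts,
lncRNAs, miRNAs), log-normal intensity noise, a planted fraction of
differential features at fixed fold changes, and one imprinted-locus
surrogate — a single coding gene co-silenced with eight partner lncRNA
transcripts from two genes within 300 kb, plus two clusters totalling 49
locus miRNAs of which a stated majority is down-regulated at least
two-fold.

Every planted effect is recorded in a :class:`SyntheticTruth` so each
downstream stage can be scored against construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .types import (
    ExpressionMatrix,
    FeatureAnnotation,
    GeneSet,
    GeneSetCollection,
    LocusnetError,
    interval_gap,
)

CIS_WINDOW = 300_000

#: classes the generator can deliberately plant for the classifier
PLANTED_CLASSES = ("sense", "antisense", "bidirectional", "intronic")


@dataclass
class LocusSpec:
    """Planted imprinted-locus surrogate: topology of a DLK1-MEG3-like domain."""

    chrom: str = "chr14"
    start: int = 100_000_000
    end: int = 100_400_000
    coding_gene: str = "DLK1L"
    lnc_genes: tuple[str, ...] = ("MEG3L", "MEG8L")
    transcripts_per_gene: tuple[int, ...] = (5, 3)
    n_mirna: int = 49
    fraction_down: float = 30 / 49
    fraction_up: float = 3 / 49
    fc: float = 2771.79  # shared fold change of the co-silenced coding + lncRNAs
    direction: str = "down"
    mirna_down_fc: float = 8.0
    mirna_up_fc: float = 4.0
    #: locus genes are strongly expressed in the control tissue, so their
    #: baselines sit high in the intensity range (the coding gene must stay
    #: inside the detection range even after an ~11 log2-unit silencing)
    baseline_log2_range: tuple[float, float] = (14.0, 15.5)
    mirna_baseline_log2_range: tuple[float, float] = (8.0, 14.0)

    @property
    def n_down(self) -> int:
        return round(self.fraction_down * self.n_mirna)

    @property
    def n_up(self) -> int:
        return round(self.fraction_up * self.n_mirna)


@dataclass
class SimulationConfig:
    """Generator settings; the defaults are the study conditions."""

    n_case: int = 3
    n_control: int = 3
    n_coding: int = 1000
    n_lncrna: int = 1000
    n_mirna: int = 500
    frac_de: float = 0.1
    fc_grid: tuple[float, ...] = (2.0, 5.0, 10.0, 100.0)
    #: sampling weights over fc_grid; most differential features carry
    #: modest fold changes and only a sliver exceeds 100-fold, matching the
    #: fold-change composition microarray screens typically report
    fc_weights: tuple[float, ...] = (0.60, 0.25, 0.13, 0.02)
    frac_cis: float = 0.1
    noise_sd_log2: float = 0.25
    #: fraction of the noise variance that members of a co-regulated unit
    #: (a planted cis pair, the locus gene group) share per sample; cis
    #: regulation couples expression across samples, not just across groups
    shared_noise_frac: float = 0.64
    baseline_log2_range: tuple[float, float] = (2.0, 16.0)
    plant_subgroups: int = 2  # lncRNAs planted per positional class
    locus: LocusSpec = field(default_factory=LocusSpec)
    seed: int = 7

    def validate(self) -> None:
        if not 0.0 <= self.frac_de <= 1.0:
            raise LocusnetError("frac_de must lie in [0, 1]")
        if not 0.0 <= self.frac_cis <= 1.0:
            raise LocusnetError("frac_cis must lie in [0, 1]")
        if any(f <= 1.0 for f in self.fc_grid):
            raise LocusnetError("all planted fold changes must exceed 1")
        if len(self.fc_weights) != len(self.fc_grid):
            raise LocusnetError("fc_weights must match fc_grid in length")
        if not 0.0 <= self.shared_noise_frac < 1.0:
            raise LocusnetError("shared_noise_frac must lie in [0, 1)")
        if self.locus.fc < 1.0:
            raise LocusnetError("locus fold change must be >= 1 (1 plants no change)")
        if self.n_mirna < self.locus.n_mirna:
            raise LocusnetError("n_mirna smaller than the locus miRNA count")
        if self.locus.n_down + self.locus.n_up > self.locus.n_mirna:
            raise LocusnetError("locus up+down counts exceed locus miRNA count")


@dataclass
class SyntheticTruth:
    """Ground truth of every planted effect."""

    de_features: dict[str, tuple[float, str]]
    cis_pairs_true: list[tuple[str, str]]
    locus_mirna_status: dict[str, str]
    subgroup_classes: dict[str, str]
    locus_coding_gene: str
    locus_lnc_transcripts: dict[str, list[str]]


@dataclass
class SimulatedDataset:
    coding: ExpressionMatrix
    lncrna: ExpressionMatrix
    mirna: ExpressionMatrix
    annotations: list[FeatureAnnotation]
    exons: dict[str, list[tuple[int, int]]]
    gene_sets: GeneSetCollection
    truth: SyntheticTruth
    config: SimulationConfig

    @property
    def annotation_index(self) -> dict[str, FeatureAnnotation]:
        from .types import annotation_by_id

        return annotation_by_id(self.annotations)

    @property
    def locus_interval(self) -> tuple[str, int, int]:
        return (self.config.locus.chrom, self.config.locus.start, self.config.locus.end)


class _Placer:
    """Sequential genome placement with slots far wider than the cis window."""

    def __init__(self, chroms: int = 8, start: int = 1_000_000, step: int = 700_000):
        self.chroms = [f"chr{i}" for i in range(1, chroms + 1)]
        self.cursor = {c: start for c in self.chroms}
        self.step = step
        self._next = 0

    def slot(self) -> tuple[str, int]:
        chrom = self.chroms[self._next % len(self.chroms)]
        self._next += 1
        pos = self.cursor[chrom]
        self.cursor[chrom] += self.step
        return chrom, pos


def _build_matrix(
    feature_ids: list[str],
    effects: dict[str, tuple[float, str]],
    sample_ids: list[str],
    groups: dict[str, str],
    rng: np.random.Generator,
    config: SimulationConfig,
    baseline_overrides: dict[str, tuple[float, float]] | None = None,
    shared_dev: dict[str, np.ndarray] | None = None,
) -> ExpressionMatrix:
    """Sample one linear-scale matrix: uniform log2 baseline + group shift + noise.

    ``baseline_overrides`` narrows the baseline range for selected features;
    ``shared_dev`` adds a precomputed per-sample deviation shared within a
    co-regulated unit, with the independent noise shrunk so the marginal
    per-cell noise SD stays at ``noise_sd_log2``.
    """
    baseline_overrides = baseline_overrides or {}
    shared_dev = shared_dev or {}
    low, high = config.baseline_log2_range
    n_features, n_samples = len(feature_ids), len(sample_ids)
    baseline = rng.uniform(low, high, size=n_features)
    for i, fid in enumerate(feature_ids):
        if fid in baseline_overrides:
            b_low, b_high = baseline_overrides[fid]
            baseline[i] = rng.uniform(b_low, b_high)
    log2_values = np.tile(baseline[:, None], (1, n_samples))
    if config.noise_sd_log2 > 0:
        indep_sd_shared = config.noise_sd_log2 * np.sqrt(1.0 - config.shared_noise_frac)
        noise = rng.normal(0.0, config.noise_sd_log2, size=(n_features, n_samples))
        for i, fid in enumerate(feature_ids):
            if fid in shared_dev:
                noise[i] = (
                    noise[i] / config.noise_sd_log2 * indep_sd_shared + shared_dev[fid]
                )
        log2_values = log2_values + noise
    case_mask = np.array([groups[s] == "case" for s in sample_ids])
    for i, fid in enumerate(feature_ids):
        if fid in effects:
            fc, direction = effects[fid]
            shift = np.log2(fc) if direction == "up" else -np.log2(fc)
            log2_values[i, case_mask] += shift
    frame = pd.DataFrame(2.0 ** log2_values, index=feature_ids, columns=sample_ids)
    return ExpressionMatrix(frame, groups, "linear")


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate the full synthetic dataset for one configuration."""
    config = config if config is not None else SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    locus = config.locus

    sample_ids = [f"case_{i+1}" for i in range(config.n_case)] + [
        f"control_{i+1}" for i in range(config.n_control)
    ]
    groups = {
        s: ("case" if s.startswith("case") else "control") for s in sample_ids
    }

    placer = _Placer()
    annotations: list[FeatureAnnotation] = []
    exons: dict[str, list[tuple[int, int]]] = {}

    coding_ids = [f"G{i+1:04d}" for i in range(config.n_coding)]
    lnc_ids = [f"L{i+1:04d}" for i in range(config.n_lncrna)]

    # ----- differential assignments -----------------------------------
    n_de_coding = round(config.frac_de * config.n_coding)
    n_de_lnc = round(config.frac_de * config.n_lncrna)
    de_coding = list(rng.choice(coding_ids, size=n_de_coding, replace=False))
    de_lnc = list(rng.choice(lnc_ids, size=n_de_lnc, replace=False))

    weights = np.asarray(config.fc_weights, dtype=float)
    weights = weights / weights.sum()
    effects: dict[str, tuple[float, str]] = {}
    for fid in de_coding + de_lnc:
        effects[fid] = (
            float(rng.choice(config.fc_grid, p=weights)),
            str(rng.choice(["up", "down"])),
        )

    # ----- planted cis pairs: shared strong shift, nearby placement ----
    # a true cis pair is strongly co-regulated by construction, so its
    # shared fold change comes from the top of the grid
    strong_fcs = [f for f in config.fc_grid if f >= 10.0] or [max(config.fc_grid)]
    n_cis = round(config.frac_cis * n_de_lnc)
    cis_lnc = de_lnc[:n_cis]
    cis_coding = de_coding[:n_cis]
    cis_pairs_true: list[tuple[str, str]] = []
    placed: dict[str, FeatureAnnotation] = {}
    for lid, gid in zip(cis_lnc, cis_coding):
        shared = (float(rng.choice(strong_fcs)), str(rng.choice(["up", "down"])))
        effects[lid] = shared
        effects[gid] = shared
        chrom, pos = placer.slot()
        gene = FeatureAnnotation(gid, gid, chrom, pos, pos + 10_000, "+", "coding")
        offset = int(rng.integers(20_000, 250_000))
        lnc = FeatureAnnotation(
            lid, lid, chrom, gene.end + offset, gene.end + offset + 2_000, "+", "lncRNA"
        )
        placed[gid] = gene
        placed[lid] = lnc
        cis_pairs_true.append((lid, gid))

    # ----- planted positional subgroups (non-DE hosts) -----------------
    subgroup_classes: dict[str, str] = {}
    non_de_coding = [g for g in coding_ids if g not in effects]
    plantable_lnc = [l for l in de_lnc[n_cis:]]
    host_iter = iter(non_de_coding)
    plant_iter = iter(plantable_lnc)
    for cls in PLANTED_CLASSES:
        for _ in range(config.plant_subgroups):
            try:
                gid, lid = next(host_iter), next(plant_iter)
            except StopIteration as exc:
                raise LocusnetError(
                    "not enough features to plant the requested subgroups"
                ) from exc
            effects[lid] = (4.0, "up")
            chrom, s = placer.slot()
            host = FeatureAnnotation(gid, gid, chrom, s, s + 10_000, "+", "coding")
            exons[gid] = [(s, s + 2_000), (s + 8_000, s + 10_000)]
            if cls == "sense":
                lnc = FeatureAnnotation(lid, lid, chrom, s + 500, s + 2_500, "+", "lncRNA")
            elif cls == "intronic":
                lnc = FeatureAnnotation(lid, lid, chrom, s + 3_000, s + 5_000, "+", "lncRNA")
            elif cls == "antisense":
                lnc = FeatureAnnotation(lid, lid, chrom, s + 4_000, s + 6_000, "-", "lncRNA")
            else:  # bidirectional: divergent, 5' starts 500 bp apart
                lnc = FeatureAnnotation(lid, lid, chrom, s - 2_500, s - 500, "-", "lncRNA")
            placed[gid] = host
            placed[lid] = lnc
            subgroup_classes[lid] = cls

    # ----- everything else gets its own distant slot --------------------
    for gid in coding_ids:
        if gid not in placed:
            chrom, pos = placer.slot()
            placed[gid] = FeatureAnnotation(gid, gid, chrom, pos, pos + 10_000, "+", "coding")
    for lid in lnc_ids:
        if lid not in placed:
            chrom, pos = placer.slot()
            placed[lid] = FeatureAnnotation(lid, lid, chrom, pos, pos + 2_000, "+", "lncRNA")

    # ----- the imprinted-locus surrogate --------------------------------
    locus_coding = FeatureAnnotation(
        locus.coding_gene, locus.coding_gene, locus.chrom,
        locus.start, locus.start + 10_000, "+", "coding",
    )
    annotations_locus: list[FeatureAnnotation] = [locus_coding]
    locus_planted = locus.fc > 1.0
    if locus_planted:
        effects[locus.coding_gene] = (locus.fc, locus.direction)

    locus_lnc_transcripts: dict[str, list[str]] = {}
    anchor = locus.start + 80_000
    for gi, (gene, n_tx) in enumerate(zip(locus.lnc_genes, locus.transcripts_per_gene)):
        locus_lnc_transcripts[gene] = []
        gene_anchor = anchor + gi * 60_000
        for ti in range(n_tx):
            tid = f"{gene}_T{ti+1}"
            start = gene_anchor + ti * 2_000
            end = gene_anchor + 35_000
            tx = FeatureAnnotation(tid, gene, locus.chrom, start, end, "+", "lncRNA")
            if interval_gap(tx.start, tx.end, locus_coding.start, locus_coding.end) > CIS_WINDOW:
                raise LocusnetError(
                    f"locus transcript {tid} farther than {CIS_WINDOW} bp from "
                    f"{locus.coding_gene}"
                )
            annotations_locus.append(tx)
            locus_lnc_transcripts[gene].append(tid)
            if locus_planted:
                effects[tid] = (locus.fc, locus.direction)
                cis_pairs_true.append((tid, locus.coding_gene))

    mirna_ids = [f"M{i+1:03d}" for i in range(config.n_mirna)]
    locus_mirna_ids = mirna_ids[: locus.n_mirna]
    n_cluster_a = locus.n_mirna // 2
    for i, mid in enumerate(locus_mirna_ids):
        if i < n_cluster_a:
            start = locus.start + 200_000 + i * 2_000
        else:
            start = locus.start + 300_000 + (i - n_cluster_a) * 2_000
        if start + 80 > locus.end:
            raise LocusnetError("locus span too small for the requested miRNA clusters")
        annotations_locus.append(
            FeatureAnnotation(mid, mid, locus.chrom, start, start + 80, "+", "miRNA")
        )
    for mid in mirna_ids[locus.n_mirna:]:
        chrom, pos = placer.slot()
        annotations_locus.append(
            FeatureAnnotation(mid, mid, chrom, pos, pos + 80, "+", "miRNA")
        )

    statuses = (
        ["down"] * locus.n_down
        + ["up"] * locus.n_up
        + ["unchanged"] * (locus.n_mirna - locus.n_down - locus.n_up)
    )
    statuses = [statuses[i] for i in rng.permutation(len(statuses))]
    locus_mirna_status = dict(zip(locus_mirna_ids, statuses))
    for mid, status in locus_mirna_status.items():
        if status == "down" and locus.mirna_down_fc > 1.0:
            effects[mid] = (locus.mirna_down_fc, "down")
        elif status == "up" and locus.mirna_up_fc > 1.0:
            effects[mid] = (locus.mirna_up_fc, "up")

    lnc_feature_ids = lnc_ids + [
        t for gene in locus.lnc_genes for t in locus_lnc_transcripts[gene]
    ]
    coding_feature_ids = coding_ids + [locus.coding_gene]

    annotations = [placed[f] for f in coding_ids + lnc_ids] + annotations_locus

    # ----- co-regulated units share a per-sample expression deviation ----
    locus_tx_ids = [t for gene in locus.lnc_genes for t in locus_lnc_transcripts[gene]]
    coreg_units: list[list[str]] = [[lid, gid] for lid, gid in zip(cis_lnc, cis_coding)]
    coreg_units.append([locus.coding_gene] + locus_tx_ids)
    shared_dev: dict[str, np.ndarray] = {}
    shared_sd = config.noise_sd_log2 * np.sqrt(config.shared_noise_frac)
    n_samples = len(sample_ids)
    for unit in coreg_units:
        dev = rng.normal(0.0, shared_sd, size=n_samples) if shared_sd > 0 else np.zeros(n_samples)
        for fid in unit:
            shared_dev[fid] = dev

    baseline_overrides: dict[str, tuple[float, float]] = {}
    for fid in [locus.coding_gene] + locus_tx_ids:
        baseline_overrides[fid] = locus.baseline_log2_range
    for mid in locus_mirna_ids:
        baseline_overrides[mid] = locus.mirna_baseline_log2_range
    # planted cis-pair members stay clear of the detection floor/ceiling in
    # their high tissue: a pair below the floor would not be observable
    low, high = config.baseline_log2_range
    for fid in list(cis_lnc) + list(cis_coding):
        fc, direction = effects[fid]
        shift = np.log2(fc)
        if direction == "down":
            baseline_overrides[fid] = (min(low + shift + 1.0, high - 1.0), high - 1.0)
        else:
            baseline_overrides[fid] = (low + 1.0, max(high - shift - 1.0, low + 1.0))

    # ----- matrices ------------------------------------------------------
    coding_matrix = _build_matrix(
        coding_feature_ids, effects, sample_ids, groups, rng, config,
        baseline_overrides, shared_dev,
    )
    lnc_matrix = _build_matrix(
        lnc_feature_ids, effects, sample_ids, groups, rng, config,
        baseline_overrides, shared_dev,
    )
    mirna_matrix = _build_matrix(
        mirna_ids, effects, sample_ids, groups, rng, config,
        baseline_overrides, shared_dev,
    )

    # ----- gene sets: one set enriched in planted DE coding genes --------
    gene_sets = GeneSetCollection()
    de_pool = sorted(set(de_coding) | {locus.coding_gene})
    enriched = sorted(rng.choice(de_pool, size=min(40, len(de_pool)), replace=False))
    gene_sets.add(GeneSet("SET_PLANTED", "planted dysregulated pathway", tuple(enriched)))
    set_size = min(40, len(coding_feature_ids))
    for i in range(4):
        members = sorted(rng.choice(coding_feature_ids, size=set_size, replace=False))
        gene_sets.add(GeneSet(f"SET_RANDOM{i+1}", f"random background set {i+1}", tuple(members)))

    de_features = {
        fid: effects[fid]
        for fid in effects
        if effects[fid][0] > 1.0
    }
    truth = SyntheticTruth(
        de_features=de_features,
        cis_pairs_true=sorted(cis_pairs_true),
        locus_mirna_status=locus_mirna_status,
        subgroup_classes=subgroup_classes,
        locus_coding_gene=locus.coding_gene,
        locus_lnc_transcripts=locus_lnc_transcripts,
    )
    return SimulatedDataset(
        coding=coding_matrix,
        lncrna=lnc_matrix,
        mirna=mirna_matrix,
        annotations=annotations,
        exons=exons,
        gene_sets=gene_sets,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# qPCR fixtures
# ---------------------------------------------------------------------------

def qpcr_fixture(
    truth: SyntheticTruth,
    feature_id: str,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    ct_ref: float = 20.0,
    ct_target_base: float = 25.0,
) -> pd.DataFrame:
    """Construct a Ct table whose 2^-ddCt recovers the feature's true fold change.

    Ct_target in the case group is shifted by -log2(fc) for an up-regulated
    feature (+log2(fc) for down); the reference gene is flat. With
    ``noise_sd`` > 0, independent Gaussian noise is added to every Ct.
    """
    if feature_id in truth.de_features:
        fc, direction = truth.de_features[feature_id]
    elif feature_id in truth.locus_mirna_status:
        fc, direction = 1.0, "unchanged"
    else:
        raise LocusnetError(f"feature {feature_id!r} not present in the truth")
    shift = -np.log2(fc) if direction == "up" else np.log2(fc)

    rows = []
    for group, target_shift in (("case", shift), ("control", 0.0)):
        for i in range(n_replicates):
            rows.append(
                {
                    "feature_id": feature_id,
                    "sample_id": f"{group}_{i+1}",
                    "group": group,
                    "target_ct": ct_target_base + target_shift,
                    "ref_ct": ct_ref,
                }
            )
    table = pd.DataFrame(rows)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        table["target_ct"] += rng.normal(0.0, noise_sd, size=len(table))
        table["ref_ct"] += rng.normal(0.0, noise_sd, size=len(table))
    return table


def qpcr_panel(
    truth: SyntheticTruth,
    feature_ids: list[str],
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Concatenate qPCR fixtures for a validation panel of features."""
    return pd.concat(
        [qpcr_fixture(truth, fid, n_replicates, noise_sd, rng) for fid in feature_ids],
        ignore_index=True,
    )


# ---------------------------------------------------------------------------
# on-disk export
# ---------------------------------------------------------------------------

def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write matrices, annotation, gene sets, truth tables and a qPCR panel."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / fname for name, fname in [
        ("coding", "coding.tsv"),
        ("lncrna", "lncrna.tsv"),
        ("mirna", "mirna.tsv"),
        ("groups", "groups.tsv"),
        ("annotation", "annotation.bed"),
        ("exons", "exons.tsv"),
        ("gene_sets", "gene_sets.gmt"),
        ("qpcr", "qpcr_panel.tsv"),
        ("truth_de", "truth_de.tsv"),
        ("truth_cis", "truth_cis.tsv"),
        ("truth_locus", "truth_locus_mirna.tsv"),
        ("truth_subgroups", "truth_subgroups.tsv"),
    ]}
    lio.write_expression_matrix(dataset.coding, paths["coding"])
    lio.write_expression_matrix(dataset.lncrna, paths["lncrna"])
    lio.write_expression_matrix(dataset.mirna, paths["mirna"])
    lio.write_groups(dict(dataset.coding.groups), paths["groups"])
    lio.write_annotation_bed(dataset.annotations, paths["annotation"])
    lio.write_exon_table(dataset.exons, paths["exons"])
    lio.write_gene_sets(dataset.gene_sets, paths["gene_sets"])

    truth = dataset.truth
    panel_ids = sorted(truth.de_features)[:5]
    lio.write_table(qpcr_panel(truth, panel_ids), paths["qpcr"])
    lio.write_table(
        pd.DataFrame(
            [(fid, fc, d) for fid, (fc, d) in sorted(truth.de_features.items())],
            columns=["feature_id", "fc", "direction"],
        ),
        paths["truth_de"],
    )
    lio.write_table(
        pd.DataFrame(truth.cis_pairs_true, columns=["lncrna_id", "mrna_id"]),
        paths["truth_cis"],
    )
    lio.write_table(
        pd.DataFrame(
            sorted(truth.locus_mirna_status.items()), columns=["mirna_id", "status"]
        ),
        paths["truth_locus"],
    )
    lio.write_table(
        pd.DataFrame(
            sorted(truth.subgroup_classes.items()), columns=["lncrna_id", "class"]
        ),
        paths["truth_subgroups"],
    )
    return paths


def default_pipeline_config(dataset: SimulatedDataset, outdir: str | Path) -> dict:
    """Pipeline configuration dictionary pointing at a written dataset."""
    outdir = Path(outdir)
    locus = dataset.config.locus
    return {
        "coding": str(outdir / "coding.tsv"),
        "lncrna": str(outdir / "lncrna.tsv"),
        "mirna": str(outdir / "mirna.tsv"),
        "groups": str(outdir / "groups.tsv"),
        "annotation": str(outdir / "annotation.bed"),
        "exons": str(outdir / "exons.tsv"),
        "gene_sets": str(outdir / "gene_sets.gmt"),
        "qpcr": str(outdir / "qpcr_panel.tsv"),
        "fc": 2.0,
        "p": 0.05,
        "r_min": 0.90,
        "edge_q": 0.01,
        "cis_window": CIS_WINDOW,
        "cis_p": 0.05,
        "top_n": 200,
        "locus_interval": f"{locus.chrom}:{locus.start}-{locus.end}",
        "locus_fc": 2.0,
        "enrichment_lnc_genes": list(locus.lnc_genes),
        "seed": dataset.config.seed,
    }


def config_to_dict(config: SimulationConfig) -> dict:
    as_dict = dataclasses.asdict(config)
    return as_dict


def config_from_dict(data: dict) -> SimulationConfig:
    data = dict(data)
    if "locus" in data and isinstance(data["locus"], dict):
        locus = dict(data["locus"])
        for key in ("lnc_genes", "transcripts_per_gene"):
            if key in locus:
                locus[key] = tuple(locus[key])
        data["locus"] = LocusSpec(**locus)
    for key in ("fc_grid", "baseline_log2_range"):
        if key in data:
            data[key] = tuple(data[key])
    config = SimulationConfig(**data)
    config.validate()
    return config
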