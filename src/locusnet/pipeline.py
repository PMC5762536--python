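"""End-to-end pipeline: normalize -> DE -> classify -> network -> cis ->
locus summary -> enrichment, with deterministic TSV outputs and a run log.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from . import io as lio
from .cis import count_localized, find_cis_pairs, select_top_lncrnas
from .de import bin_fold_changes, differential_expression
from .enrichment import fisher_enrichment, genes_correlated_with
from .locus import classify_locus_mirnas, locus_summary, parse_locus, status_table
from .network import build_edges, gene_neighborhood
from .normalize import quantile_normalize
from .qpcr import concordance, ddct_from_table
from .subgroups import classify_all, subgroup_counts
from .types import LocusnetError, annotation_by_id

log = logging.getLogger(__name__)

REQUIRED_KEYS = [
    "coding", "lncrna", "mirna", "groups", "annotation",
    "fc", "p", "r_min", "edge_q", "cis_window", "cis_p", "top_n",
    "locus_interval", "locus_fc", "seed",
]
OPTIONAL_KEYS = {
    "gene_sets": None,
    "exons": None,
    "qpcr": None,
    "enrichment_lnc_genes": (),
    "use_q_for_edges": True,
    "equal_var": True,
}


def load_config(path: str | Path) -> dict:
    with open(path) as handle:
        config = yaml.safe_load(handle)
    return validate_config(config)


def validate_config(config: dict) -> dict:
    missing = [key for key in REQUIRED_KEYS if key not in config]
    if missing:
        raise LocusnetError(f"missing config keys: {missing}")
    if config["fc"] <= 1.0:
        raise LocusnetError("config key 'fc': fold-change threshold must exceed 1")
    if config["locus_fc"] <= 1.0:
        raise LocusnetError("config key 'locus_fc': threshold must exceed 1")
    merged = dict(OPTIONAL_KEYS)
    merged.update(config)
    return merged


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict[str, Path]:
    """Run every stage on the configured inputs; write result tables.

    Returns a name -> path map of the written outputs. Given identical
    inputs and configuration the run is fully deterministic.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    annotations = lio.read_annotation(config["annotation"])
    ann_index = annotation_by_id(annotations)
    feature_to_gene = {f: a.gene_id for f, a in ann_index.items()}
    exons = lio.read_exon_table(config["exons"]) if config["exons"] else None

    matrices = {}
    de_tables = {}
    for cls in ("coding", "lncrna", "mirna"):
        raw = lio.read_expression_matrix(config[cls], config["groups"], scale="linear")
        norm = quantile_normalize(raw)
        matrices[cls] = norm
        de_tables[cls] = differential_expression(
            norm,
            fc_threshold=config["fc"],
            p_threshold=config["p"],
            equal_var=config["equal_var"],
        )
        outputs[f"de_{cls}"] = outdir / f"de_{cls}.tsv"
        lio.write_table(de_tables[cls], outputs[f"de_{cls}"])
        outputs[f"fc_bins_{cls}"] = outdir / f"fc_bins_{cls}.tsv"
        lio.write_table(bin_fold_changes(de_tables[cls]), outputs[f"fc_bins_{cls}"])

    # positional subgroups of the DE lncRNAs
    de_lnc = de_tables["lncrna"]
    sig_lnc_ids = de_lnc[de_lnc["significant"]]["feature_id"].tolist()
    lnc_annotations = [ann_index[f] for f in sig_lnc_ids if f in ann_index]
    class_table = classify_all(lnc_annotations, annotations, exons)
    classifications = dict(zip(class_table["lncrna_id"], class_table["class"]))
    counts = subgroup_counts(
        de_lnc[de_lnc["feature_id"].isin(classifications)], classifications
    )
    outputs["subgroup_counts"] = outdir / "subgroup_counts.tsv"
    lio.write_table(counts, outputs["subgroup_counts"])

    # co-expression network over DE lncRNAs x DE coding genes
    de_coding = de_tables["coding"]
    sig_coding_ids = de_coding[de_coding["significant"]]["feature_id"].tolist()
    edges = build_edges(
        matrices["lncrna"],
        matrices["coding"],
        sig_lnc_ids,
        sig_coding_ids,
        r_min=config["r_min"],
        q_max=config["edge_q"],
        use_q=config["use_q_for_edges"],
    )
    outputs["edges_tsv"] = outdir / "edges.tsv"
    outputs["edges_sif"] = outdir / "edges.sif"
    lio.write_network(edges, outputs["edges_tsv"], format="tsv")
    lio.write_network(edges, outputs["edges_sif"], format="sif")

    # cis pairing of the most dysregulated lncRNAs
    top_lnc = select_top_lncrnas(de_lnc, n=config["top_n"])
    cis_pairs = find_cis_pairs(
        top_lnc,
        ann_index,
        matrices["lncrna"],
        matrices["coding"],
        mrna_ids=sig_coding_ids,
        window=config["cis_window"],
        p_max=config["cis_p"],
    )
    outputs["cis_pairs"] = outdir / "cis_pairs.tsv"
    lio.write_table(cis_pairs, outputs["cis_pairs"])
    n_localized = count_localized(top_lnc, cis_pairs)

    # locus miRNA silencing summary
    locus = parse_locus(config["locus_interval"])
    statuses = classify_locus_mirnas(
        de_tables["mirna"], locus, ann_index, fc_threshold=config["locus_fc"]
    )
    summary = locus_summary(statuses)
    outputs["locus_summary"] = outdir / "locus_summary.tsv"
    lio.write_table(summary.to_frame(), outputs["locus_summary"])
    outputs["locus_status"] = outdir / "locus_mirna_status.tsv"
    lio.write_table(status_table(statuses), outputs["locus_status"])

    # enrichment of the genes correlated with the configured lncRNA genes
    if config["gene_sets"]:
        sets = lio.read_gene_sets(config["gene_sets"])
        lnc_genes = list(config["enrichment_lnc_genes"])
        source = cis_pairs if lnc_genes else edges
        query = genes_correlated_with(source, lnc_genes, feature_to_gene) \
            if lnc_genes else sorted(set(edges["mrna_id"]))
        background = matrices["coding"].feature_ids
        if query:
            table = fisher_enrichment(query, sets, background, p_max=config["p"])
        else:
            log.warning("enrichment: empty query list; writing empty table")
            table = pd.DataFrame(
                columns=["set_id", "name", "k", "m", "n", "N", "p", "fdr", "significant"]
            )
        outputs["enrichment"] = outdir / "enrichment.tsv"
        lio.write_table(table, outputs["enrichment"])

    # qPCR validation of the array calls
    if config["qpcr"]:
        ct_table = pd.read_csv(config["qpcr"], sep="\t")
        qpcr_results = ddct_from_table(ct_table)
        combined_de = pd.concat(de_tables.values(), ignore_index=True)
        agreement = concordance(qpcr_results, combined_de)
        outputs["qpcr"] = outdir / "qpcr_concordance.tsv"
        lio.write_table(agreement, outputs["qpcr"])

    # run log with every threshold echoed
    outputs["run_log"] = outdir / "run_log.txt"
    with open(outputs["run_log"], "w") as handle:
        handle.write("locusnet pipeline run\n")
        for key in sorted(k for k in config if config[k] is not None):
            handle.write(f"{key}: {config[key]}\n")
        handle.write(f"n_significant_coding: {len(sig_coding_ids)}\n")
        handle.write(f"n_significant_lncrna: {len(sig_lnc_ids)}\n")
        handle.write(f"n_edges: {len(edges)}\n")
        handle.write(f"n_cis_pairs: {len(cis_pairs)}\n")
        handle.write(f"n_top_lncrnas_localized: {n_localized}\n")
        handle.write(
            f"locus_summary: down={summary.n_down} ({summary.pct_down}%), "
            f"up={summary.n_up} ({summary.pct_up}%), "
            f"unchanged={summary.n_unchanged} ({summary.pct_unchanged}%)\n"
        )
    return outputs


def write_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump(config, handle, sort_keys=True)
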