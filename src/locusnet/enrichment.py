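"""Gene-set over-representation analysis (KEGG-style).

Each set is tested with the one-sided Fisher exact test for
over-representation of the query list within the background: the p value
is the hypergeometric upper tail P(X >= k) for drawing k set members in a
query of size n from a background of size N containing m set members.
BH FDR is computed across the tested sets.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .types import ENRICHMENT_COLUMNS, GeneSetCollection, LocusnetError

log = logging.getLogger(__name__)


def fisher_enrichment(
    query: Sequence[str],
    sets: GeneSetCollection,
    background: Sequence[str],
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of ``query`` in each gene set against ``background``.

    Sets are intersected with the background before testing; sets with no
    member in the background are skipped with a log line. Returns one row
    per tested set, sorted by p then set id.
    """
    background_set = set(background)
    query_set = set(query)
    if not background_set:
        raise LocusnetError("empty background")
    if not query_set:
        raise LocusnetError("empty query list")
    stray = query_set - background_set
    if stray:
        raise LocusnetError(
            f"query genes missing from background: {sorted(stray)[:10]}"
        )

    N = len(background_set)
    n = len(query_set)
    rows = []
    for gene_set in sets:
        members = set(gene_set.members) & background_set
        m = len(members)
        if m == 0:
            log.info("enrichment: set %s has no background members; skipped",
                     gene_set.set_id)
            continue
        k = len(members & query_set)
        p = float(hypergeom.sf(k - 1, N, m, n))
        rows.append(
            {
                "set_id": gene_set.set_id,
                "name": gene_set.name,
                "k": k,
                "m": m,
                "n": n,
                "N": N,
                "p": min(p, 1.0),
            }
        )
    result = pd.DataFrame(rows)
    if len(result):
        result["fdr"] = multipletests(result["p"], method="fdr_bh")[1]
        result["significant"] = result["p"] < p_max
        result = result.sort_values(["p", "set_id"]).reset_index(drop=True)
    else:
        result = pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    return result[ENRICHMENT_COLUMNS]


def genes_correlated_with(
    edges: pd.DataFrame,
    lnc_gene_ids: Sequence[str],
    feature_to_gene: Mapping[str, str],
) -> list[str]:
    """Unique coding genes linked to any transcript of the named lncRNA genes.

    Works on either the network edge table or the cis-pair table (both
    carry lncrna_id/mrna_id). Output is sorted for determinism.
    """
    wanted = set(lnc_gene_ids)
    if edges.empty:
        return []
    lnc_genes = edges["lncrna_id"].map(lambda f: feature_to_gene.get(f, f))
    hit = edges[lnc_genes.isin(wanted)]
    genes = {feature_to_gene.get(m, m) for m in hit["mrna_id"]}
    return sorted(genes)
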