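import numpy as np
import pandas as pd
import pytest

from locusnet.subgroups import CLASSES, classify_all, classify_lncrna, subgroup_counts
from locusnet.types import FeatureAnnotation, LocusnetError


def lnc(start, end, strand="+", chrom="chr1", fid="L1"):
    return FeatureAnnotation(fid, fid, chrom, start, end, strand, "lncRNA")


def coding(start, end, strand="+", chrom="chr1", gid="G1"):
    return FeatureAnnotation(gid, gid, chrom, start, end, strand, "coding")


HOST = coding(10_000, 20_000, "+")
HOST_EXONS = {"G1": [(10_000, 12_000), (18_000, 20_000)]}


class TestClassifyCascade:
    def test_intronic_inside_same_strand_intron(self):
        label = classify_lncrna(lnc(13_000, 15_000, "+"), [HOST], HOST_EXONS)
        assert label == "intronic"

    def test_exonic_overlap_is_sense(self):
        label = classify_lncrna(lnc(11_000, 13_000, "+"), [HOST], HOST_EXONS)
        assert label == "sense"

    def test_same_strand_overlap_without_exon_model_is_sense(self):
        # without an exon model the intronic class collapses into sense
        label = classify_lncrna(lnc(13_000, 15_000, "+"), [HOST], None)
        assert label == "sense"

    def test_opposite_strand_overlap_is_antisense(self):
        label = classify_lncrna(lnc(13_000, 15_000, "-"), [HOST], HOST_EXONS)
        assert label == "antisense"

    def test_divergent_promoter_within_window_is_bidirectional(self):
        # lncRNA on '-' ending 500 bp upstream of the '+' coding gene start
        label = classify_lncrna(lnc(8_000, 9_500, "-"), [HOST], HOST_EXONS)
        assert label == "bidirectional"

    def test_same_orientation_nearby_is_not_bidirectional(self):
        label = classify_lncrna(lnc(8_000, 9_500, "+"), [HOST], HOST_EXONS)
        assert label == "intergenic"

    def test_distant_lncrna_is_intergenic(self):
        label = classify_lncrna(lnc(400_000, 401_000, "+"), [HOST], HOST_EXONS)
        assert label == "intergenic"

    def test_unstranded_lncrna_rejected(self):
        bad = FeatureAnnotation("L1", "L1", "chr1", 0, 10, "+", "lncRNA")
        object.__setattr__(bad, "strand", ".")
        with pytest.raises(LocusnetError, match="strand"):
            classify_lncrna(bad, [HOST])


def brute_force_classify(lncrna, coding_set, exons, window=1000):
    """Literal re-statement of the class definitions, scanning all pairs."""
    same = [c for c in coding_set if c.chrom == lncrna.chrom]
    overl = [c for c in same if c.start < lncrna.end and lncrna.start < c.end]
    for c in overl:
        if c.strand == lncrna.strand and c.start <= lncrna.start and lncrna.end <= c.end:
            ex = (exons or {}).get(c.gene_id, [])
            if ex and all(not (lncrna.start < e and s < lncrna.end) for s, e in ex):
                return "intronic"
    for c in overl:
        if c.strand == lncrna.strand:
            ex = (exons or {}).get(c.gene_id, [])
            if not ex or any(lncrna.start < e and s < lncrna.end for s, e in ex):
                return "sense"
    if any(c.strand != lncrna.strand for c in overl):
        return "antisense"
    for c in same:
        if c in overl or c.strand == lncrna.strand:
            continue
        divergent = (
            lncrna.end <= c.start
            if (lncrna.strand, c.strand) == ("-", "+")
            else lncrna.start >= c.end
        )
        if divergent and abs(lncrna.tss - c.tss) <= window:
            return "bidirectional"
    return "intergenic"


def test_agrees_with_brute_force_on_random_features():
    rng = np.random.default_rng(11)
    coding_set = [
        coding(int(s), int(s) + int(rng.integers(2_000, 20_000)),
               "+" if rng.random() < 0.5 else "-", gid=f"G{i}")
        for i, s in enumerate(rng.integers(0, 500_000, size=40))
    ]
    exons = {}
    for c in coding_set[::2]:
        third = (c.end - c.start) // 3
        exons[c.gene_id] = [(c.start, c.start + third), (c.end - third, c.end)]
    total = {cls: 0 for cls in CLASSES}
    for i in range(200):
        s = int(rng.integers(0, 520_000))
        item = lnc(s, s + int(rng.integers(200, 5_000)),
                   "+" if rng.random() < 0.5 else "-", fid=f"L{i}")
        got = classify_lncrna(item, coding_set, exons)
        want = brute_force_classify(item, coding_set, exons)
        assert got == want
        total[got] += 1
    assert sum(total.values()) == 200  # total function: one label each


def test_generator_planted_classes_recovered(default_dataset):
    ds = default_dataset
    ann = ds.annotation_index
    planted = [ann[f] for f in ds.truth.subgroup_classes]
    table = classify_all(planted, ds.annotations, ds.exons)
    got = dict(zip(table["lncrna_id"], table["class"]))
    assert got == ds.truth.subgroup_classes


class TestSubgroupCounts:
    def records(self):
        return pd.DataFrame(
            {
                "feature_id": ["L1", "L2", "L3"],
                "direction": ["up", "up", "down"],
                "fc": [4.0, 3.0, 2.5],
                "significant": [True, True, True],
            }
        )

    def test_tabulation(self):
        counts = subgroup_counts(
            self.records(), {"L1": "sense", "L2": "sense", "L3": "intergenic"}
        )
        table = counts.set_index("class")
        assert table.loc["sense", "up"] == 2
        assert table.loc["intergenic", "down"] == 1
        assert counts[["up", "down"]].to_numpy().sum() == 3

    def test_empty_input_zero_table(self):
        counts = subgroup_counts(self.records().iloc[0:0], {})
        assert (counts[["up", "down"]].to_numpy() == 0).all()

    def test_unclassified_rejected(self):
        with pytest.raises(LocusnetError, match="unclassified"):
            subgroup_counts(self.records(), {"L1": "sense"})
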