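import numpy as np
import pandas as pd
import pytest

from locusnet.cis import count_localized, find_cis_pairs, select_top_lncrnas
from locusnet.network import pearson_with_p
from locusnet.types import FeatureAnnotation, LocusnetError, interval_gap

from .conftest import make_matrix


def _de(rows):
    return pd.DataFrame(
        rows, columns=["feature_id", "fc", "p", "significant"]
    ).assign(direction="up")


class TestSelectTop:
    def test_top_by_fold_change(self):
        rng = np.random.default_rng(0)
        fcs = rng.uniform(2, 100, size=300)
        records = _de([(f"L{i}", fc, 0.01, True) for i, fc in enumerate(fcs)])
        top = select_top_lncrnas(records, n=200)
        cutoff = np.sort(fcs)[::-1][199]
        assert len(top) == 200
        assert min(records.set_index("feature_id").loc[top, "fc"]) >= cutoff

    def test_tie_broken_by_smaller_p(self):
        records = _de(
            [("A", 100.0, 0.01, True), ("B", 50.0, 0.04, True), ("C", 50.0, 0.01, True)]
        )
        assert select_top_lncrnas(records, n=2) == ["A", "C"]

    def test_fewer_than_n_returns_all(self, caplog):
        records = _de([(f"L{i}", 5.0 + i, 0.01, True) for i in range(150)])
        with caplog.at_level("INFO"):
            top = select_top_lncrnas(records, n=200)
        assert len(top) == 150


def _correlated_pair_matrices(lnc_id="L1", mrna_id="M1"):
    x = np.array([9.0, 9.1, 8.9, 6.0, 6.1, 5.9])
    lnc = make_matrix([2.0 ** x], feature_ids=[lnc_id])
    mrna = make_matrix([2.0 ** (x + 0.05)], feature_ids=[mrna_id])
    return lnc, mrna


class TestWindowBoundary:
    def annotation(self, gap):
        # lncRNA at [1_000_000, 1_002_000); coding gene ends `gap` bp before it
        lnc = FeatureAnnotation("L1", "L1", "chr5", 1_000_000, 1_002_000, "+", "lncRNA")
        gene = FeatureAnnotation(
            "M1", "M1", "chr5", 600_000, 1_000_000 - gap, "+", "coding"
        )
        return {"L1": lnc, "M1": gene}

    def test_exact_window_distance_retained(self):
        lnc, mrna = _correlated_pair_matrices()
        pairs = find_cis_pairs(["L1"], self.annotation(300_000), lnc, mrna,
                               mrna_ids=["M1"])
        assert len(pairs) == 1
        assert pairs.iloc[0]["distance_bp"] == 300_000
        assert pairs.iloc[0]["relation"] == "upstream"

    def test_one_bp_beyond_window_excluded(self):
        lnc, mrna = _correlated_pair_matrices()
        pairs = find_cis_pairs(["L1"], self.annotation(300_001), lnc, mrna,
                               mrna_ids=["M1"])
        assert pairs.empty

    def test_relation_flips_with_lncrna_strand(self):
        lnc, mrna = _correlated_pair_matrices()
        ann = self.annotation(10_000)
        ann["L1"] = FeatureAnnotation("L1", "L1", "chr5", 1_000_000, 1_002_000, "-", "lncRNA")
        pairs = find_cis_pairs(["L1"], ann, lnc, mrna, mrna_ids=["M1"])
        assert pairs.iloc[0]["relation"] == "downstream"

    def test_overlapping_gene_distance_zero(self):
        lnc, mrna = _correlated_pair_matrices()
        ann = self.annotation(0)
        ann["M1"] = FeatureAnnotation("M1", "M1", "chr5", 999_000, 1_001_000, "+", "coding")
        pairs = find_cis_pairs(["L1"], ann, lnc, mrna, mrna_ids=["M1"])
        assert pairs.iloc[0]["distance_bp"] == 0
        assert pairs.iloc[0]["relation"] == "overlapping"

    def test_unannotated_id_rejected(self):
        lnc, mrna = _correlated_pair_matrices()
        with pytest.raises(LocusnetError, match="unannotated"):
            find_cis_pairs(["L1"], {"M1": self.annotation(0)["M1"]}, lnc, mrna,
                           mrna_ids=["M1"])


def brute_force_cis(lnc_ids, annotation, lnc_matrix, mrna_matrix, mrna_ids,
                    window=300_000, p_max=0.05):
    """O(n^2) scan over all lncRNA x coding pairs, literal window rule."""
    log_l = lnc_matrix.log2().values
    log_m = mrna_matrix.log2().values
    found = set()
    for lid in lnc_ids:
        for mid in mrna_ids:
            a, b = annotation[lid], annotation[mid]
            if a.chrom != b.chrom:
                continue
            if interval_gap(a.start, a.end, b.start, b.end) > window:
                continue
            _, p = pearson_with_p(log_l.loc[lid].to_numpy(), log_m.loc[mid].to_numpy())
            if p < p_max:
                found.add((lid, mid))
    return found


def _random_fixture(seed, n_lnc=25, n_mrna=25):
    rng = np.random.default_rng(seed)
    annotation = {}
    for i in range(n_lnc):
        s = int(rng.integers(0, 3_000_000))
        annotation[f"L{i}"] = FeatureAnnotation(
            f"L{i}", f"L{i}", f"chr{rng.integers(1, 3)}", s, s + 2_000, "+", "lncRNA"
        )
    for i in range(n_mrna):
        s = int(rng.integers(0, 3_000_000))
        annotation[f"M{i}"] = FeatureAnnotation(
            f"M{i}", f"M{i}", f"chr{rng.integers(1, 3)}", s, s + 10_000, "+", "coding"
        )
    lnc = make_matrix(rng.lognormal(3, 1, size=(n_lnc, 6)),
                      feature_ids=[f"L{i}" for i in range(n_lnc)])
    mrna = make_matrix(rng.lognormal(3, 1, size=(n_mrna, 6)),
                       feature_ids=[f"M{i}" for i in range(n_mrna)])
    return annotation, lnc, mrna


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_matches_brute_force_oracle(seed):
    annotation, lnc, mrna = _random_fixture(seed)
    lnc_ids = [f"L{i}" for i in range(25)]
    mrna_ids = [f"M{i}" for i in range(25)]
    pairs = find_cis_pairs(lnc_ids, annotation, lnc, mrna, mrna_ids=mrna_ids)
    got = set(zip(pairs["lncrna_id"], pairs["mrna_id"]))
    want = brute_force_cis(lnc_ids, annotation, lnc, mrna, mrna_ids)
    assert got == want


def test_monotone_in_window_and_p():
    annotation, lnc, mrna = _random_fixture(9)
    lnc_ids = [f"L{i}" for i in range(25)]
    mrna_ids = [f"M{i}" for i in range(25)]
    args = (lnc_ids, annotation, lnc, mrna)
    base = find_cis_pairs(*args, mrna_ids=mrna_ids, window=200_000, p_max=0.05)
    wide = find_cis_pairs(*args, mrna_ids=mrna_ids, window=500_000, p_max=0.05)
    strict = find_cis_pairs(*args, mrna_ids=mrna_ids, window=200_000, p_max=0.01)
    as_set = lambda e: set(zip(e["lncrna_id"], e["mrna_id"]))  # noqa: E731
    assert as_set(base) <= as_set(wide)
    assert as_set(strict) <= as_set(base)
    assert (wide["distance_bp"] <= 500_000).all()


def test_count_localized():
    pairs = pd.DataFrame({"lncrna_id": ["L1", "L1", "L3"], "mrna_id": ["A", "B", "C"]})
    assert count_localized(["L1", "L2", "L3", "L4"], pairs) == 2
    assert count_localized(["L1"], pairs.iloc[0:0]) == 0


def test_planted_pairs_recovered_exactly(default_dataset, default_de):
    """On the default study all planted cis pairs — and only they — survive."""
    ds, de = default_dataset, default_de
    de_c = de["coding"]
    sig_c = de_c[de_c["significant"]]["feature_id"].tolist()
    top = select_top_lncrnas(de["lncrna"], n=200)
    pairs = find_cis_pairs(top, ds.annotation_index, ds.lncrna, ds.coding,
                           mrna_ids=sig_c)
    got = set(zip(pairs["lncrna_id"], pairs["mrna_id"]))
    assert got == set(ds.truth.cis_pairs_true)
    assert count_localized(top, pairs) == len({l for l, _ in got})
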