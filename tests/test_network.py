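import numpy as np
import pandas as pd
import pytest
from scipy.special import betainc

from locusnet.network import build_edges, gene_neighborhood, pearson_with_p
from locusnet.types import LocusnetError

from .conftest import make_matrix


def t_tail_pvalue(r, n):
    """Independent two-sided tail of the t transform via the incomplete beta."""
    df = n - 2
    t2 = r * r * df / (1.0 - r * r)
    return float(betainc(df / 2, 0.5, df / (df + t2)))


class TestPearsonWithP:
    def test_perfect_linear_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        r, p = pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0) and p == 0.0

    def test_orthogonal_vectors(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        r, p = pearson_with_p(x, y)
        assert r == pytest.approx(0.0, abs=1e-15)
        assert p == pytest.approx(1.0)

    def test_n6_r090_worked_example(self):
        # construct x, y with sample r exactly 0.90 at n = 6
        rng = np.random.default_rng(0)
        x = rng.normal(size=6)
        z = rng.normal(size=6)
        xs = (x - x.mean()) / x.std()
        zs = z - z.mean()
        zs -= zs @ xs / (xs @ xs) * xs  # orthogonalize
        zs /= zs.std()
        target_r = 0.90
        y = target_r * xs + np.sqrt(1 - target_r**2) * zs
        r, p = pearson_with_p(x, y)
        assert r == pytest.approx(0.90, abs=1e-12)
        assert p == pytest.approx(0.0145, abs=5e-5)
        assert p == pytest.approx(t_tail_pvalue(0.90, 6), abs=1e-12)

    def test_matches_t_tail_oracle_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for n in (4, 6, 10, 25):
            x, y = rng.normal(size=(2, n))
            r, p = pearson_with_p(x, y)
            assert p == pytest.approx(t_tail_pvalue(r, n), abs=1e-12)

    def test_affine_invariance_and_symmetry(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=(2, 8))
        r, p = pearson_with_p(x, y)
        r2, p2 = pearson_with_p(y, x)
        r3, _ = pearson_with_p(3.5 * x - 2.0, y)
        assert r == pytest.approx(r2) and p == pytest.approx(p2)
        assert r == pytest.approx(r3)

    def test_zero_variance_rejected(self):
        with pytest.raises(LocusnetError, match="zero variance"):
            pearson_with_p(np.ones(6), np.arange(6.0))


class TestBuildEdges:
    def test_shared_shift_without_noise_gives_perfect_edges(self):
        case = [64.0, 64.0, 64.0]
        control = [8.0, 8.0, 8.0]
        lnc = make_matrix(
            np.array([case + control, case + control]) * [[1.0], [2.0]],
            feature_ids=["L1", "L2"],
        )
        # jitter control so each feature has within-group variance
        rng = np.random.default_rng(0)
        lv = lnc.values.to_numpy() * np.exp(rng.normal(0, 0.01, lnc.values.shape))
        lnc.values.loc[:, :] = lv
        mrna = make_matrix([np.array(case + control) * 3.0], feature_ids=["M1"])
        mv = mrna.values.to_numpy() * np.exp(rng.normal(0, 0.01, mrna.values.shape))
        mrna.values.loc[:, :] = mv
        edges = build_edges(lnc, mrna, ["L1", "L2"], ["M1"], r_min=0.9, q_max=0.05)
        assert set(zip(edges["lncrna_id"], edges["mrna_id"])) == {
            ("L1", "M1"), ("L2", "M1"),
        }
        assert (edges["sign"] == "positive").all()

    def test_null_features_produce_no_edges(self):
        rng = np.random.default_rng(12)
        lnc = make_matrix(rng.lognormal(3, 1, size=(50, 6)),
                          feature_ids=[f"L{i}" for i in range(50)])
        mrna = make_matrix(rng.lognormal(3, 1, size=(40, 6)),
                           feature_ids=[f"M{i}" for i in range(40)])
        edges = build_edges(
            lnc, mrna, list(lnc.feature_ids), list(mrna.feature_ids),
            r_min=0.90, q_max=0.01,
        )
        assert len(edges) == 0  # 2000 independent pairs, none should survive

    def test_negative_correlation_sign(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        lnc = make_matrix([2.0 ** x], feature_ids=["L1"])
        mrna = make_matrix([2.0 ** (10 - x + 0.01 * x**2)], feature_ids=["M1"])
        edges = build_edges(lnc, mrna, ["L1"], ["M1"], r_min=0.9, q_max=0.05)
        assert len(edges) == 1 and edges.iloc[0]["sign"] == "negative"

    def test_edge_set_monotone_in_thresholds(self, default_dataset, default_de):
        ds, de = default_dataset, default_de
        sig_l = de["lncrna"][de["lncrna"]["significant"]]["feature_id"].tolist()
        sig_c = de["coding"][de["coding"]["significant"]]["feature_id"].tolist()
        loose = build_edges(ds.lncrna, ds.coding, sig_l, sig_c, r_min=0.90, q_max=0.05)
        tight_r = build_edges(ds.lncrna, ds.coding, sig_l, sig_c, r_min=0.95, q_max=0.05)
        tight_q = build_edges(ds.lncrna, ds.coding, sig_l, sig_c, r_min=0.90, q_max=0.001)
        as_set = lambda e: set(zip(e["lncrna_id"], e["mrna_id"]))  # noqa: E731
        assert as_set(tight_r) <= as_set(loose)
        assert as_set(tight_q) <= as_set(loose)

    def test_mismatched_samples_rejected(self):
        lnc = make_matrix(np.ones((2, 6)) + np.arange(12).reshape(2, 6))
        mrna = make_matrix(np.ones((2, 4)) + np.arange(8).reshape(2, 4), case=2, control=2)
        with pytest.raises(LocusnetError, match="share samples"):
            build_edges(lnc, mrna, ["F1"], ["F1"])


class TestGeneNeighborhood:
    def edges(self):
        return pd.DataFrame(
            {
                "lncrna_id": ["T2", "T1", "X1"],
                "mrna_id": ["G1", "G1", "G2"],
                "r": [0.99, 0.98, -0.95],
                "p": [1e-5, 1e-4, 1e-3],
                "q": [1e-4, 1e-3, 1e-2],
                "sign": ["positive", "positive", "negative"],
            }
        )

    F2G = {"T1": "MEGA", "T2": "MEGA", "X1": "X1", "G1": "G1", "G2": "G2"}

    def test_groups_transcripts_by_gene(self):
        hood = gene_neighborhood(self.edges(), "G1", self.F2G)
        assert list(hood["lncrna_id"]) == ["T1", "T2"]
        assert set(hood["lncrna_gene"]) == {"MEGA"}

    def test_unknown_gene_empty(self, caplog):
        with caplog.at_level("WARNING"):
            hood = gene_neighborhood(self.edges(), "NOPE", self.F2G)
        assert hood.empty

    def test_order_independent_of_input(self):
        a = gene_neighborhood(self.edges(), "G1", self.F2G)
        b = gene_neighborhood(self.edges().iloc[::-1].reset_index(drop=True), "G1", self.F2G)
        pd.testing.assert_frame_equal(a, b)
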