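"""Spot selection, per-gene statistics, FCS/SNS scoring and DEG calls."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import cofracnet as cf
from cofracnet.spatial import (call_degs, gene_stats, score_genes,
                               select_spots)
from cofracnet.synth import DEFAULT_MARKERS, SpotExpression, simulate_spots


def spot_table(rows, genes, obs_rows):
    counts = pd.DataFrame(rows, index=[r[0] for r in obs_rows], columns=genes)
    obs = pd.DataFrame([r[1:] for r in obs_rows],
                       index=[r[0] for r in obs_rows],
                       columns=["region", "group", "soma_flag"])
    return SpotExpression(counts, obs)


class TestSelectSpots:
    @staticmethod
    def six_spot_table():
        genes = ["G1"] + list(DEFAULT_MARKERS)
        rows = [
            [5, 3, 3, 3],   # s1 SN soma markers ok -> keep
            [5, 3, 3, 3],   # s2 SN no soma -> drop
            [5, 0, 3, 3],   # s3 SN soma, Th below floor -> drop
            [5, 3, 3, 3],   # s4 thalamus -> drop
            [5, 1, 1, 1],   # s5 SN soma markers at floor -> keep
            [5, 3, 3, 0],   # s6 SN soma, Vmat2 zero -> drop
        ]
        obs = [("s1", "SN", "WT", True), ("s2", "SN", "WT", False),
               ("s3", "SN", "HOM", True), ("s4", "thalamus", "WT", True),
               ("s5", "SN", "HOM", True), ("s6", "SN", "WT", True)]
        return spot_table(rows, genes, obs)

    def test_manual_rule_application(self):
        data = self.six_spot_table()
        selected, report = select_spots(data, "SN", marker_floor=1.0)
        assert list(selected.obs.index) == ["s1", "s5"]
        assert (report.n_input, report.n_wrong_region, report.n_no_soma,
                report.n_low_marker, report.n_selected) == (6, 1, 1, 2, 2)

    def test_soma_flag_false_removed(self):
        data = self.six_spot_table()
        selected, _ = select_spots(data, "SN", marker_floor=0.0)
        assert "s2" not in selected.obs.index

    def test_zero_floor_only_region_and_soma_act(self):
        data = self.six_spot_table()
        selected, _ = select_spots(data, "SN", marker_floor=0.0)
        assert list(selected.obs.index) == ["s1", "s3", "s5", "s6"]

    def test_nothing_survives_rejected_with_attrition(self):
        data = self.six_spot_table()
        with pytest.raises(ValueError, match="no spot survives"):
            select_spots(data, "SN", marker_floor=100.0)


class TestGeneStats:
    @staticmethod
    def two_group_table(values_a, values_b, gene="G1"):
        genes = [gene] + list(DEFAULT_MARKERS)
        rows, obs = [], []
        for i, v in enumerate(values_a):
            rows.append([v, 5, 5, 5])
            obs.append((f"a{i}", "SN", "WT", True))
        for i, v in enumerate(values_b):
            rows.append([v, 5, 5, 5])
            obs.append((f"b{i}", "SN", "HOM", True))
        return spot_table(rows, genes, obs)

    def test_identical_groups_null(self):
        data = self.two_group_table([1, 2, 3], [1, 2, 3])
        out = gene_stats(data, normalization="none")
        assert out.loc["G1", "mu_a"] == out.loc["G1", "mu_b"]
        assert out.loc["G1", "p"] == pytest.approx(1.0)

    def test_zero_variance_both_groups_p_one(self):
        data = self.two_group_table([0, 0, 0], [0, 0, 0])
        out = gene_stats(data, normalization="none")
        assert out.loc["G1", "p"] == 1.0

    def test_welch_matches_independent_computation(self):
        """(1,2,3) vs (4,5,6) against a from-scratch Welch t-test."""
        data = self.two_group_table([1, 2, 3], [4, 5, 6])
        out = gene_stats(data, normalization="none", test="welch")
        a, b = np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t = (b.mean() - a.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / 2 + vb ** 2 / 2)
        p = 2 * sps.t.sf(abs(t), df)
        assert out.loc["G1", "p"] == pytest.approx(p, abs=1e-12)
        assert out.loc["G1", "mu_b"] == pytest.approx(5.0)
        assert out.loc["G1", "sigma_a"] == pytest.approx(1.0)

    def test_single_spot_group_rejected(self):
        data = self.two_group_table([1], [2, 3, 4])
        with pytest.raises(ValueError, match=">= 2 spots"):
            gene_stats(data, normalization="none")


class TestScoreGenes:
    @staticmethod
    def table(mu_a, mu_b, sigma_a, sigma_b, p):
        return pd.DataFrame({"mu_a": [mu_a], "mu_b": [mu_b],
                             "sigma_a": [sigma_a], "sigma_b": [sigma_b],
                             "p": [p]}, index=["G"])

    def test_fcs_formula(self):
        out = score_genes(self.table(1.0, 4.0, 1.0, 1.0, 0.01))
        assert out.loc["G", "fcs"] == pytest.approx(4.0, abs=1e-12)

    def test_sns_formula(self):
        out = score_genes(self.table(2.0, 1.0, 0.5, 0.5, 0.1))
        assert out.loc["G", "sns"] == pytest.approx(-1.0, abs=1e-12)

    def test_equal_means_zero_scores(self):
        out = score_genes(self.table(3.0, 3.0, 1.0, 2.0, 0.001))
        assert out.loc["G", "fcs"] == 0.0
        assert out.loc["G", "sns"] == 0.0

    def test_pseudocount_keeps_scores_finite(self):
        out = score_genes(self.table(0.0, 4.0, 0.0, 0.0, 0.01))
        assert np.isfinite(out[["fcs", "sns"]].to_numpy()).all()
        assert out.loc["G", "fcs"] == pytest.approx(np.log2(5.0) * 2, abs=1e-12)

    def test_sign_coherence(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            mu_a, mu_b = rng.uniform(0.5, 9, 2)
            out = score_genes(self.table(mu_a, mu_b, rng.uniform(0.1, 2),
                                         rng.uniform(0.1, 2),
                                         rng.uniform(0.001, 0.5)))
            assert np.sign(out.loc["G", "fcs"]) == np.sign(out.loc["G", "sns"])


class TestCallDegs:
    @staticmethod
    def toy(n=10, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "fcs": rng.normal(size=n), "sns": rng.normal(size=n),
            "p": rng.uniform(0.001, 0.2, size=n),
        }, index=[f"G{i}" for i in range(n)])

    def test_rank_cutoff_ceiling(self):
        table = self.toy(10)
        table["p"] = 0.001
        degs = call_degs(table, top_frac=0.2)
        # cutoff = ceil(0.2*10) = 2 per score; conjunction can keep fewer
        assert len(degs) <= 2
        assert math.ceil(0.2 * 10) == 2

    def test_conjunction_both_scores_required(self):
        table = pd.DataFrame({
            "fcs": [10.0, 1.0, 0.5, 0.1, 0.2],
            "sns": [0.1, 10.0, 0.5, 0.3, 0.2],
            "p": [0.001] * 5,
        }, index=list("ABCDE"))
        assert call_degs(table, top_frac=0.2) == []

    def test_matches_exhaustive_manual_application(self):
        table = self.toy(10, seed=3)
        degs = call_degs(table, p_cut=0.05, top_frac=0.2)
        cutoff = 2
        expect = []
        fa, sa = table["fcs"].abs(), table["sns"].abs()
        for g in table.index:
            rank_f = 1 + (fa > fa[g]).sum()
            rank_s = 1 + (sa > sa[g]).sum()
            if table.loc[g, "p"] < 0.05 and rank_f <= cutoff and rank_s <= cutoff:
                expect.append(g)
        assert degs == expect

    def test_scale_invariance_of_full_arm(self):
        """Multiplying all counts by a constant leaves scores and calls
        unchanged (depth normalization absorbs the factor)."""
        data, _ = simulate_spots(n_genes=200, n_per_group=8, seed=6)
        t1, d1 = cf.deg_pipeline(data)
        scaled = SpotExpression(data.counts * 7, data.obs, data.marker_genes)
        t2, d2 = cf.deg_pipeline(scaled)
        assert d1 == d2
        assert np.allclose(t1[["fcs", "sns", "p"]], t2[["fcs", "sns", "p"]],
                           atol=1e-9)

    def test_planted_deg_recall(self):
        data, truth = simulate_spots(seed=4)
        _, degs = cf.deg_pipeline(data)
        recall = len(set(truth) & set(degs)) / len(truth)
        assert recall >= 0.7
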