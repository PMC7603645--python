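"""Stage binning, edge calling, consensus networks, modules, partners."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncage import (AnalysisError, bin_stages, coexpressed_partners,
                    consensus_network, detect_modules, export_graphml,
                    growth_metrics, stage_edges)
from lncage.network import ConsensusNetwork, correlation_matrix
from conftest import make_expression, make_meta

AGES = (8, 26, 60, 78, 104)


class TestStageBinning:
    def test_five_ages_five_reps_gives_ten_per_stage(self):
        meta = make_meta(["t"], AGES, 5)
        binning = bin_stages(meta, "t")
        assert set(binning.stages) == {1, 2, 3, 4}
        assert all(len(v) == 10 for v in binning.stages.values())

    def test_adjacent_stages_share_one_age(self):
        meta = make_meta(["t"], AGES, 3)
        binning = bin_stages(meta, "t")
        shared = set(binning.stages[1]) & set(binning.stages[2])
        expected = set(meta.loc[meta["age_weeks"] == 26, "sample_id"])
        assert shared == expected

    def test_non_canonical_age_rejected(self):
        meta = make_meta(["t"], (8, 26, 50, 78, 104), 2)
        with pytest.raises(AnalysisError, match="50"):
            bin_stages(meta, "t")

    def test_missing_age_rejected(self):
        meta = make_meta(["t"], (8, 26, 60, 78), 2)
        with pytest.raises(AnalysisError, match="104"):
            bin_stages(meta, "t")


class TestStageEdges:
    def test_perfect_copy_is_significant(self):
        rng = np.random.default_rng(0)
        profile = rng.normal(0, 1, 10)
        vals = np.vstack([profile, profile, rng.normal(0, 1, 10)])
        expr = make_expression(vals, gene_ids=["l1", "m1", "m2"])
        edges = stage_edges(expr, ["l1"], ["m1", "m2"], list(expr.samples))
        row = edges.set_index("mrna_id").loc["m1"]
        assert row["r"] == pytest.approx(1.0) and row["significant"]

    def test_zscoring_leaves_r_unchanged(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, (3, 12))
        b = rng.normal(0, 1, (4, 12))
        r, _ = correlation_matrix(a, b)
        r2, _ = correlation_matrix(a * 3.0 + 5.0, b * 0.1 - 2.0)
        assert np.allclose(r, r2)

    def test_r_matches_scipy_pairwise(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, (5, 9))
        b = rng.normal(0, 1, (6, 9))
        r, p = correlation_matrix(a, b)
        for i in range(5):
            for j in range(6):
                ref = stats.pearsonr(a[i], b[j])
                assert r[i, j] == pytest.approx(ref.statistic)
                assert p[i, j] == pytest.approx(ref.pvalue)

    def test_null_pairs_controlled_by_bh(self):
        """Independent-noise pairs: significant fraction stays at the BH
        nominal scale (n = 10 samples, 100 x 100 pairs)."""
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 1, (200, 10))
        ids = [f"l{i}" for i in range(100)] + [f"m{i}" for i in range(100)]
        expr = make_expression(vals, gene_ids=ids)
        edges = stage_edges(expr, ids[:100], ids[100:], list(expr.samples))
        assert edges["significant"].mean() <= 0.05

    def test_zero_variance_gene_pairs_skipped(self):
        vals = np.vstack([np.zeros(10), np.random.default_rng(4).normal(0, 1, 10)])
        expr = make_expression(vals, gene_ids=["l1", "m1"])
        edges = stage_edges(expr, ["l1"], ["m1"], list(expr.samples))
        assert edges.empty


def _edge_table(pairs_sig, all_pairs, r=0.95):
    rows = []
    for (l, m) in all_pairs:
        sig = (l, m) in pairs_sig
        rows.append((l, m, r if sig else 0.1, 1e-6 if sig else 0.5,
                     1e-5 if sig else 0.6, sig))
    return pd.DataFrame(rows, columns=["lnc_id", "mrna_id", "r", "p", "q",
                                       "significant"])


class TestConsensus:
    PAIRS = [("l1", "m1"), ("l1", "m2"), ("l2", "m1")]

    def _net(self, sig_by_stage, rule="union"):
        per_stage = {s: _edge_table(sig_by_stage.get(s, set()), self.PAIRS)
                     for s in (1, 2, 3, 4)}
        return consensus_network(per_stage, "t", {"l1", "l2"}, {"m1", "m2"},
                                 rule=rule)

    def test_stage4_only_edge_present(self):
        net = self._net({4: {("l1", "m1")}})
        assert net.n_edges == 1
        assert net.edges.loc[0, "sig_stages"] == "4"

    def test_never_significant_edge_absent(self):
        net = self._net({2: {("l1", "m1")}, 3: {("l1", "m2")}})
        assert net.n_edges == 0

    def test_intersection_rule(self):
        net = self._net({1: {("l1", "m1"), ("l1", "m2")}, 4: {("l1", "m1")}},
                        rule="intersection")
        assert net.n_edges == 1
        assert net.edges.loc[0, "mrna_id"] == "m1"

    def test_nodes_within_ar_sets(self):
        net = self._net({1: {("l1", "m1")}})
        assert net.node_ids() <= net.lnc_nodes | net.mrna_nodes


def _biclique_network(sizes, offset_labels=True):
    """Disconnected complete bipartite components of the given sizes."""
    rows = []
    lnc_nodes, mrna_nodes = set(), set()
    for k, size in enumerate(sizes):
        n_l = size // 2
        lnc = [f"c{k}l{i}" for i in range(n_l)]
        mrna = [f"c{k}m{i}" for i in range(size - n_l)]
        lnc_nodes |= set(lnc)
        mrna_nodes |= set(mrna)
        for l in lnc:
            for m in mrna:
                rows.append((l, m))
    edges = pd.DataFrame(rows, columns=["lnc_id", "mrna_id"])
    for s in (1, 2, 3, 4):
        edges[f"r{s}"] = 0.95
        edges[f"q{s}"] = 1e-4
    edges["sig_stages"] = "1,4"
    return ConsensusNetwork("t", lnc_nodes, mrna_nodes, edges)


class TestModules:
    def test_two_bicliques_match_component_oracle(self):
        net = _biclique_network([35, 35])
        modules = detect_modules(net)
        assert len(modules.module_ids) == 2
        sizes = sorted(len(modules.members(m)) for m in modules.module_ids)
        assert sizes == [35, 35]
        members = {frozenset(modules.members(m)) for m in modules.module_ids}
        expected = {frozenset(g for g in net.node_ids() if g.startswith("c0")),
                    frozenset(g for g in net.node_ids() if g.startswith("c1"))}
        assert members == expected

    def test_small_component_filtered(self):
        """A 20-node biclique fails the > 30 gene retention rule."""
        modules = detect_modules(_biclique_network([20]))
        assert modules.module_ids == []

    def test_boundary_size_filtered(self):
        """Exactly 30 genes is not 'more than 30'."""
        modules = detect_modules(_biclique_network([30]))
        assert modules.module_ids == []

    def test_membership_is_partition(self):
        net = _biclique_network([40, 32])
        modules = detect_modules(net)
        assert not modules.table["gene_id"].duplicated().any()

    def test_empty_network_zero_modules(self):
        net = ConsensusNetwork("t", set(), set(),
                               pd.DataFrame(columns=["lnc_id", "mrna_id"]))
        assert detect_modules(net).module_ids == []


class TestGrowthMetrics:
    def test_mean_abs_r_bounded(self):
        rng = np.random.default_rng(5)
        meta = make_meta(["t"], AGES, 3)
        expr = make_expression(rng.normal(0, 1, (10, 15)),
                               sample_ids=meta["sample_id"])
        binning = bin_stages(meta, "t")
        out = growth_metrics(expr, [f"g{i}" for i in range(5)],
                             [f"g{i}" for i in range(5, 10)], binning)
        assert ((out["mean_abs_r"] >= 0) & (out["mean_abs_r"] <= 1)).all()
        assert len(out) == 4

    def test_null_data_rarely_monotone(self):
        """Without planted coupling the strict-increase flag fires at a
        small null rate (< 1/2 by construction, checked over seeds)."""
        meta = make_meta(["t"], AGES, 3)
        binning = bin_stages(meta, "t")
        flags = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            expr = make_expression(rng.normal(0, 1, (12, 15)),
                                   sample_ids=meta["sample_id"])
            out = growth_metrics(expr, [f"g{i}" for i in range(6)],
                                 [f"g{i}" for i in range(6, 12)], binning)
            flags.append(bool(out["monotone"].iloc[0]))
        assert sum(flags) <= 2


class TestPartners:
    def test_perfect_copy_and_anticorrelated(self):
        rng = np.random.default_rng(6)
        profile = rng.normal(0, 1, 25)
        vals = np.vstack([profile, profile + rng.normal(0, 0.01, 25),
                          -profile, rng.normal(0, 1, 25)])
        expr = make_expression(vals, gene_ids=["l1", "mcopy", "manti", "mnoise"])
        out = coexpressed_partners("l1", expr, ["mcopy", "manti", "mnoise"],
                                   list(expr.samples))
        out = out.set_index("mrna_id")
        assert out.loc["mcopy", "partner"]
        # r = -1 fails the signed r > 0.8 rule
        assert not out.loc["manti", "partner"]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(0, 1, (40, 20))
        vals[1:10] += vals[0] * 1.5  # correlated block
        ids = ["lnc"] + [f"m{i}" for i in range(39)]
        expr = make_expression(vals, gene_ids=ids)
        out = coexpressed_partners("lnc", expr, ids[1:], list(expr.samples))
        from lncage import bh_adjust
        rs, ps = [], []
        for m in sorted(ids[1:]):
            res = stats.pearsonr(expr.log2.loc["lnc"], expr.log2.loc[m])
            rs.append(res.statistic)
            ps.append(res.pvalue)
        qs = bh_adjust(ps)
        expected = {m for m, r, q in zip(sorted(ids[1:]), rs, qs)
                    if r > 0.8 and q < 0.05}
        assert set(out.loc[out["partner"], "mrna_id"]) == expected
        assert expected  # the planted block must yield partners

    def test_undetectable_lnc_rejected(self):
        expr = make_expression(np.ones((2, 10)) * np.arange(10),
                               gene_ids=["a", "b"])
        with pytest.raises(AnalysisError):
            coexpressed_partners("zz", expr, ["a"], list(expr.samples))


def test_graphml_export_round_trip(tmp_path):
    import igraph as ig
    net = _biclique_network([12])
    path = tmp_path / "net.graphml"
    export_graphml(net, path)
    g = ig.Graph.Read_GraphML(str(path))
    assert g.vcount() == 12 and g.ecount() == net.n_edges
    assert set(g.vs["biotype"]) == {"lncRNA", "mRNA"}
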