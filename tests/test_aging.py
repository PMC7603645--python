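"""Aging correlation, differential expression and AR calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncage import (AnalysisError, aging_correlation, bh_adjust,
                    call_aging_regulated, compare_gene_features,
                    cross_tissue_overlap, differential_expression,
                    old_young_fold_change)
from lncage.aging import ARGeneSet, welch_t
from conftest import make_expression, make_meta

AGES = (8, 26, 60, 78, 104)


def _de_table(tissue, old_age, gene_ids, fc, p, fdr=None):
    fdr = bh_adjust(p) if fdr is None else fdr
    return pd.DataFrame({"gene_id": gene_ids, "tissue": tissue,
                         "old_age": old_age, "young_age": 8,
                         "log2fc": fc, "p": p, "fdr": fdr})


class TestAgingCorrelation:
    def test_log_linear_gene_has_r_one(self):
        meta = make_meta(["t"], AGES, 2)
        x = np.log2(meta["age_weeks"].to_numpy(float))
        values = np.vstack([3.0 + 0.5 * x, 10.0 - 2.0 * x])
        expr = make_expression(values, sample_ids=meta["sample_id"])
        res = aging_correlation(expr, meta, "t")
        assert res.loc[0, "r"] == pytest.approx(1.0)
        assert res.loc[0, "called"] and res.loc[0, "direction"] == "positive"
        assert res.loc[1, "r"] == pytest.approx(-1.0)
        assert res.loc[1, "direction"] == "negative"

    def test_linear_in_weeks_is_not_perfect(self):
        """The correlation axis is log2(weeks): a gene linear in raw weeks
        must not reach r = 1."""
        meta = make_meta(["t"], AGES, 2)
        w = meta["age_weeks"].to_numpy(float)
        expr = make_expression(w[None, :] / 10.0, sample_ids=meta["sample_id"])
        res = aging_correlation(expr, meta, "t")
        assert res.loc[0, "r"] < 1.0 - 1e-6

    def test_constant_gene_flagged_degenerate(self):
        meta = make_meta(["t"], AGES, 1)
        expr = make_expression(np.full((1, 5), 2.0), sample_ids=meta["sample_id"])
        res = aging_correlation(expr, meta, "t")
        assert res.loc[0, "degenerate"] and not res.loc[0, "called"]

    def test_p_matches_permutation_oracle(self):
        """t-transform p for a moderate correlation agrees with a
        permutation null within Monte-Carlo error."""
        rng = np.random.default_rng(0)
        meta = make_meta(["t"], AGES, 3)
        x = np.log2(meta["age_weeks"].to_numpy(float))
        y = 0.35 * x + rng.normal(0, 1.0, x.size)
        expr = make_expression(y[None, :], sample_ids=meta["sample_id"])
        res = aging_correlation(expr, meta, "t")
        n_perm = 100_000
        perm = np.array([np.corrcoef(y, rng.permutation(x))[0, 1]
                         for _ in range(n_perm)])
        p_perm = (1 + (np.abs(perm) >= abs(res.loc[0, "r"])).sum()) / (n_perm + 1)
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(res.loc[0, "p"] - p_perm) < max(4 * se, 0.01)

    def test_requires_three_ages(self):
        meta = make_meta(["t"], (8, 104), 3)
        expr = make_expression(np.ones((1, 6)), sample_ids=meta["sample_id"])
        with pytest.raises(AnalysisError):
            aging_correlation(expr, meta, "t")


class TestDifferentialExpression:
    def test_identical_groups_fc_zero(self):
        meta = make_meta(["t"], (8, 104), 4)
        vals = np.tile(np.arange(4.0), (3, 2))
        expr = make_expression(vals, sample_ids=meta["sample_id"])
        de = differential_expression(expr, meta, "t", 104)
        assert np.allclose(de["log2fc"], 0.0)

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, (40, 5))
        b = rng.normal(0.4, 2, (40, 6))
        diff, p = welch_t(a, b)
        ref = stats.ttest_ind(a, b, axis=1, equal_var=False)
        assert np.allclose(p, ref.pvalue)
        assert np.allclose(diff, a.mean(1) - b.mean(1))

    def test_planted_effect_power(self):
        """Delta = 2.0, sd 0.3, n = 5/5 passes |FC| > 0.75 & FDR < 0.1 in
        >= 95% of 200 simulated replicates (one planted gene among 50)."""
        rng = np.random.default_rng(2)
        meta = make_meta(["t"], (8, 104), 5)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            null = rng.normal(5, 0.3, (49, 10))
            planted = np.concatenate([rng.normal(7, 0.3, 5),
                                      rng.normal(5, 0.3, 5)])
            vals = np.vstack([planted, null])
            expr = make_expression(vals, sample_ids=meta["sample_id"])
            de = differential_expression(expr, meta, "t", 104)
            row = de.iloc[0]
            hits += bool(abs(row["log2fc"]) > 0.75 and row["fdr"] < 0.1)
        assert hits / n_rep >= 0.95

    def test_missing_group_is_error(self):
        meta = make_meta(["t"], (8, 104), 3)
        expr = make_expression(np.ones((2, 6)), sample_ids=meta["sample_id"])
        with pytest.raises(AnalysisError, match="60"):
            differential_expression(expr, meta, "t", 60)


class TestARCalling:
    def _tables(self, fcs, fdrs, genes=("g1",)):
        return {78: _de_table("t", 78, list(genes), [fcs[0]] * len(genes),
                              [0.001] * len(genes), [fdrs[0]] * len(genes)),
                104: _de_table("t", 104, list(genes), [fcs[1]] * len(genes),
                               [0.001] * len(genes), [fdrs[1]] * len(genes))}

    GENES = pd.DataFrame({"gene_id": ["g1"], "biotype": ["mRNA"],
                          "length_bp": [1000], "n_exons": [3], "n_isoforms": [1]})

    def test_larger_magnitude_fold_change_kept(self):
        """FCs (0.3, -2.0) -> log2FC(old/young) = -2.0 (sign preserved)."""
        ar = call_aging_regulated(self._tables((0.3, -2.0), (0.01, 0.01)),
                                  self.GENES)
        assert ar.table.loc[0, "log2fc_old_young"] == pytest.approx(-2.0)
        assert ar.table.loc[0, "direction"] == "down"

    def test_only_early_contrast_not_ar(self):
        """A gene differential only at 26w vs 8w is not aging-regulated."""
        tables = self._tables((0.1, 0.1), (0.9, 0.9))
        tables[26] = _de_table("t", 26, ["g1"], [3.0], [1e-8], [1e-7])
        ar = call_aging_regulated(tables, self.GENES)
        assert ar.members == set()

    def test_boundary_fc_excluded(self):
        """log2FC exactly 0.75 fails the strict > threshold."""
        ar = call_aging_regulated(self._tables((0.75, 0.0), (0.0001, 0.9)),
                                  self.GENES)
        assert ar.members == set()

    def test_discordant_directions_flagged(self):
        ar = call_aging_regulated(self._tables((1.5, -1.8), (0.01, 0.01)),
                                  self.GENES)
        assert ar.table.loc[0, "direction"] == "discordant"
        assert ar.table.loc[0, "log2fc_old_young"] == pytest.approx(-1.8)

    def test_matches_brute_force_threshold_rule(self):
        """AR membership equals re-evaluating the threshold rule row by row."""
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(300)]
        gt = pd.DataFrame({"gene_id": genes, "biotype": "mRNA",
                           "length_bp": 1000, "n_exons": 1, "n_isoforms": 1})
        tables = {}
        for age in (78, 104):
            fc = rng.normal(0, 1.2, 300)
            p = rng.uniform(0, 1, 300) ** 3
            tables[age] = _de_table("t", age, genes, fc, p)
        ar = call_aging_regulated(tables, gt)
        expected = set()
        for i, g in enumerate(genes):
            for age in (78, 104):
                row = tables[age].iloc[i]
                if abs(row["log2fc"]) > 0.75 and row["fdr"] < 0.1:
                    expected.add(g)
        assert ar.members == expected


class TestSharing:
    def _ar(self, tissue, gene_ids):
        t = pd.DataFrame({"gene_id": list(gene_ids), "biotype": "mRNA",
                          "direction": "up", "contrasts": "104",
                          "log2fc_old_young": 1.0})
        return ARGeneSet(tissue=tissue, table=t)

    def test_counts_and_single_organ_fraction(self):
        per_gene, summary = cross_tissue_overlap(
            [self._ar("T1", ["g1", "g2"]), self._ar("T2", ["g1"])])
        counts = per_gene.set_index("gene_id")["n_tissues"]
        assert counts["g1"] == 2 and counts["g2"] == 1
        pct = summary.set_index("n_tissues")["percent"]
        assert pct["1"] == pytest.approx(50.0)

    def test_disjoint_sets_all_single_organ(self):
        _, summary = cross_tissue_overlap(
            [self._ar("T1", ["a", "b"]), self._ar("T2", ["c"])])
        assert summary.set_index("n_tissues")["percent"]["1"] == 100.0

    def test_identical_sets_across_k_tissues(self):
        sets = [self._ar(f"T{i}", ["a", "b"]) for i in range(4)]
        per_gene, summary = cross_tissue_overlap(sets)
        assert (per_gene["n_tissues"] == 4).all()
        pct = summary.set_index("n_tissues")["percent"]
        assert pct["1"] == 0.0 and pct[">3"] == 100.0


class TestFeatureComparison:
    GENES = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(6)],
        "biotype": "lncRNA",
        "length_bp": [1, 2, 3, 4, 5, 6],
        "n_exons": [1, 2, 3, 4, 5, 6],
        "n_isoforms": [1, 2, 3, 4, 5, 6],
    })

    def test_identical_sets_p_one(self):
        out = compare_gene_features(self.GENES, {"g0", "g1", "g2"},
                                    {"g0", "g1", "g2"})
        assert np.allclose(out["p"].to_numpy(), 1.0)

    def test_exact_enumeration_example(self):
        """{1,2,3} vs {4,5,6}: exact two-sided Mann-Whitney p = 0.1."""
        out = compare_gene_features(self.GENES, {"g0", "g1", "g2"},
                                    {"g3", "g4", "g5"})
        assert out.set_index("feature").loc["length_bp", "p"] == pytest.approx(0.1)

    def test_p_decreases_with_shift(self):
        rng = np.random.default_rng(4)
        base = rng.integers(500, 5000, 24)
        prev = 1.1
        for shift in (0, 2000, 6000, 12000):
            genes = pd.DataFrame({
                "gene_id": [f"a{i}" for i in range(12)] + [f"b{i}" for i in range(12)],
                "biotype": "lncRNA",
                "length_bp": np.concatenate([base[:12] + shift, base[12:]]),
                "n_exons": 1, "n_isoforms": 1})
            out = compare_gene_features(genes, {f"a{i}" for i in range(12)},
                                        {f"b{i}" for i in range(12)},
                                        features=("length_bp",))
            p = out["p"].iloc[0]
            assert p <= prev + 1e-12
            prev = p


def test_old_young_fold_change_requires_both_contrasts():
    with pytest.raises(AnalysisError):
        old_young_fold_change({78: _de_table("t", 78, ["g"], [1.0], [0.5])})
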