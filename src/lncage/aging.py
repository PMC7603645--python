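"""Aging-correlated and aging-regulated (AR) gene calling.

Aging-correlated genes: Pearson correlation between log2 expression and
log2(age in weeks) over all samples of a tissue; a gene is called when
|r| > 0.9 and the two-sided p-value (t-transform, n-2 df) is < 0.05, with
positively and negatively correlated genes reported separately.

Aging-regulated genes: Welch t differential expression of each older group
against the 8-week group, BH-adjusted within (tissue, contrast); a gene is
AR when it passes |log2FC| > 0.75 and FDR < 0.1 in the 78w-vs-8w or
104w-vs-8w contrast. Its old/young fold change is the signed log2FC of
larger magnitude among those two contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust
from .errors import AnalysisError
from .expression import ExpressionMatrix

YOUNG_AGE = 8
OLD_AGES = (78, 104)


def _tissue_samples(meta: pd.DataFrame, tissue: str) -> pd.DataFrame:
    sub = meta[meta["tissue"] == tissue]
    if sub.empty:
        raise AnalysisError(f"no samples for tissue {tissue!r}")
    return sub


def pearson_with_pvalues(x: np.ndarray, values: np.ndarray):
    """Vectorized Pearson r of each row of ``values`` against ``x``, with
    two-sided p from t = r*sqrt((n-2)/(1-r^2)) on n-2 df.

    Returns (r, p, degenerate) where ``degenerate`` flags zero-variance rows
    (their r/p are NaN).
    """
    n = x.size
    if n < 3:
        raise AnalysisError("need at least 3 samples for correlation")
    xc = x - x.mean()
    vc = values - values.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc ** 2).sum())
    sv = np.sqrt((vc ** 2).sum(axis=1))
    degenerate = (sv == 0) | (sx == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (vc @ xc) / (sv * sx)
    r = np.clip(r, -1.0, 1.0)
    r[degenerate] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isinf(t), 0.0, p)
    p[degenerate] = np.nan
    return r, p, degenerate


def aging_correlation(expr: ExpressionMatrix, meta: pd.DataFrame, tissue: str,
                      r_min: float = 0.9, p_max: float = 0.05,
                      per_age_means: bool = False) -> pd.DataFrame:
    """Correlate each detectable gene with log2(age weeks) in one tissue.

    Returns a DataFrame (gene_id, tissue, r, p, direction, called,
    degenerate). ``direction`` is "positive"/"negative" by the sign of r.
    Zero-variance genes are flagged degenerate and never called.

    With ``per_age_means`` the correlation is computed on per-age replicate
    means instead of all samples.
    """
    sub = _tissue_samples(meta, tissue)
    if sub["age_weeks"].nunique() < 3:
        raise AnalysisError(f"tissue {tissue!r} has fewer than 3 distinct ages")
    values = expr.log2[sub["sample_id"]].to_numpy()
    ages = sub["age_weeks"].to_numpy(dtype=float)
    if per_age_means:
        ua = np.unique(ages)
        values = np.column_stack([values[:, ages == a].mean(axis=1) for a in ua])
        ages = ua
    r, p, degenerate = pearson_with_pvalues(np.log2(ages), values)
    out = pd.DataFrame({
        "gene_id": expr.genes, "tissue": tissue, "r": r, "p": p,
        "direction": np.where(np.isnan(r), "", np.where(r >= 0, "positive", "negative")),
        "degenerate": degenerate,
    })
    out["called"] = (~out["degenerate"]) & (out["r"].abs() > r_min) & (out["p"] < p_max)
    return out


def welch_t(a: np.ndarray, b: np.ndarray):
    """Row-wise Welch t-test of a (rows x n1) against b (rows x n2).

    Returns (diff_of_means a-b, p). Rows where both groups are constant and
    equal get p = 1; constant-but-different rows get p = 0.
    """
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise AnalysisError("need >= 2 replicates per group")
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    diff = m1 - m2
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    zero_noise = se2 == 0
    p = np.where(zero_noise, np.where(diff == 0, 1.0, 0.0), p)
    return diff, p


def differential_expression(expr: ExpressionMatrix, meta: pd.DataFrame, tissue: str,
                            old_age: int, young_age: int = YOUNG_AGE) -> pd.DataFrame:
    """Welch-t DE of ``old_age`` vs ``young_age`` on log2 expression.

    Returns (gene_id, tissue, old_age, young_age, log2fc, p, fdr); the BH
    adjustment spans all detectable genes of this (tissue, contrast).
    """
    sub = _tissue_samples(meta, tissue)
    groups = {}
    for age in (old_age, young_age):
        ids = sub.loc[sub["age_weeks"] == age, "sample_id"]
        if ids.empty:
            raise AnalysisError(f"tissue {tissue!r} has no samples at {age} weeks")
        groups[age] = expr.log2[ids].to_numpy()
    log2fc, p = welch_t(groups[old_age], groups[young_age])
    return pd.DataFrame({
        "gene_id": expr.genes, "tissue": tissue,
        "old_age": old_age, "young_age": young_age,
        "log2fc": log2fc, "p": p, "fdr": bh_adjust(p),
    })


def old_young_fold_change(de_tables: dict[int, pd.DataFrame]) -> pd.Series:
    """Per-gene signed log2FC(old/young): the larger-magnitude value among
    the 78w and 104w contrasts (sign preserved)."""
    for age in OLD_AGES:
        if age not in de_tables:
            raise AnalysisError(f"missing old contrast {age}w")
    a = de_tables[OLD_AGES[0]].set_index("gene_id")["log2fc"]
    b = de_tables[OLD_AGES[1]].set_index("gene_id")["log2fc"]
    b = b.reindex(a.index)
    return pd.Series(np.where(a.abs() >= b.abs(), a, b), index=a.index,
                     name="log2fc_old_young")


@dataclass
class ARGeneSet:
    """Aging-regulated genes of one tissue.

    ``table`` columns: gene_id, biotype, direction (up/down/discordant),
    contrasts (comma-joined qualifying old ages), log2fc_old_young.
    """

    tissue: str
    table: pd.DataFrame

    @property
    def members(self) -> set[str]:
        return set(self.table["gene_id"])

    def by_biotype(self, biotype: str) -> set[str]:
        return set(self.table.loc[self.table["biotype"] == biotype, "gene_id"])


def call_aging_regulated(de_tables: dict[int, pd.DataFrame], genes: pd.DataFrame,
                         fc_min: float = 0.75, fdr_max: float = 0.1,
                         old_ages: tuple[int, int] = OLD_AGES) -> ARGeneSet:
    """Call AR genes from the two old-age DE contrasts of one tissue.

    A gene is AR iff |log2fc| > fc_min (strict) and fdr < fdr_max (strict)
    in at least one of the two contrasts. Direction comes from the
    qualifying contrast's sign; genes qualifying in both contrasts with
    opposite signs are kept with direction "discordant".
    """
    for age in old_ages:
        if age not in de_tables:
            raise AnalysisError(f"missing old contrast {age}w")
    tissue = de_tables[old_ages[0]]["tissue"].iloc[0]
    fc = old_young_fold_change({a: de_tables[a] for a in old_ages})
    biotype = genes.set_index("gene_id")["biotype"]
    rows = []
    tabs = {a: de_tables[a].set_index("gene_id") for a in old_ages}
    passing = {a: (tabs[a]["log2fc"].abs() > fc_min) & (tabs[a]["fdr"] < fdr_max)
               for a in old_ages}
    for gid in tabs[old_ages[0]].index:
        quals = [a for a in old_ages if bool(passing[a].get(gid, False))]
        if not quals:
            continue
        signs = {np.sign(tabs[a].at[gid, "log2fc"]) for a in quals}
        direction = "discordant" if len(signs) > 1 else \
            ("up" if signs.pop() > 0 else "down")
        rows.append((gid, biotype.get(gid, "unknown"), direction,
                     ",".join(str(a) for a in quals), fc.at[gid]))
    table = pd.DataFrame(rows, columns=["gene_id", "biotype", "direction",
                                        "contrasts", "log2fc_old_young"])
    return ARGeneSet(tissue=tissue, table=table)


def cross_tissue_overlap(ar_sets: list[ARGeneSet]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tissue AR sharing.

    Returns (per_gene, summary): per_gene has (gene_id, biotype, n_tissues,
    tissues); summary gives, per biotype, the percentage of AR genes found
    in exactly 1, 2, 3 and >3 tissues.
    """
    if len(ar_sets) < 2:
        raise AnalysisError("need >= 2 tissues for sharing analysis")
    rows: dict[str, list[str]] = {}
    biotypes: dict[str, str] = {}
    for s in ar_sets:
        for r in s.table.itertuples(index=False):
            rows.setdefault(r.gene_id, []).append(s.tissue)
            biotypes[r.gene_id] = r.biotype
    per_gene = pd.DataFrame({
        "gene_id": list(rows),
        "biotype": [biotypes[g] for g in rows],
        "n_tissues": [len(v) for v in rows.values()],
        "tissues": [",".join(sorted(v)) for v in rows.values()],
    }).sort_values("gene_id").reset_index(drop=True)
    cats = {"1": lambda n: n == 1, "2": lambda n: n == 2,
            "3": lambda n: n == 3, ">3": lambda n: n > 3}
    sm = []
    for bt, grp in per_gene.groupby("biotype"):
        total = len(grp)
        for label, pred in cats.items():
            count = int(pred(grp["n_tissues"]).sum())
            sm.append((bt, label, count, 100.0 * count / total))
    summary = pd.DataFrame(sm, columns=["biotype", "n_tissues", "count", "percent"])
    return per_gene, summary


def compare_gene_features(genes: pd.DataFrame, set_a: set[str], set_b: set[str],
                          expr: ExpressionMatrix | None = None,
                          features: tuple[str, ...] = ("length_bp", "n_isoforms",
                                                       "n_exons")) -> pd.DataFrame:
    """Two-sided Mann-Whitney comparison of annotation features (and mean
    expression when ``expr`` is given) between two gene sets.

    Returns (feature, median_a, median_b, p).
    """
    if not set_a or not set_b:
        raise AnalysisError("both gene sets must be non-empty")
    missing = [f for f in features if f not in genes.columns]
    if missing:
        raise AnalysisError(f"missing features: {missing}")
    g = genes.set_index("gene_id")
    frames = {f: g[f] for f in features}
    if expr is not None:
        frames["mean_log2_expression"] = expr.log2.mean(axis=1)
    rows = []
    for name, values in frames.items():
        a = values.reindex(sorted(set_a)).dropna().to_numpy(dtype=float)
        b = values.reindex(sorted(set_b)).dropna().to_numpy(dtype=float)
        if a.size == 0 or b.size == 0:
            raise AnalysisError(f"feature {name!r} empty in one group")
        p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        rows.append((name, float(np.median(a)), float(np.median(b)), float(p)))
    return pd.DataFrame(rows, columns=["feature", "median_a", "median_b", "p"])
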