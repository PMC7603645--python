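"""Stage-binned AR-lncRNA ~ AR-mRNA co-expression networks.

Samples of one tissue are binned into four life stages by merging adjacent
age points (stage1: 8&26w, stage2: 26&60w, stage3: 60&78w, stage4:
78&104w). Within each stage, Pearson correlations between every
AR-lncRNA and AR-mRNA are tested (t-transform p, BH over all pairs of the
tissue x stage); an edge is significant when r > 0.9 (signed) and
q < 0.05. The consensus network unions edges significant in the youngest
or oldest stage, keeping the correlation at all four stages per edge so
that the growth of the network across life can be quantified. Modules are
walktrap communities (10-step random walks) with more than 30 genes.

Per-lncRNA partner lists (guilt-by-association annotation input) use all
samples of the tissue and the looser r > 0.8, q < 0.05 rule against every
detectable mRNA.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust
from .errors import AnalysisError
from .expression import ExpressionMatrix

CANONICAL_AGES = (8, 26, 60, 78, 104)


@dataclass
class StageBinning:
    """Stage index (1..4) -> sample ids of the two adjacent age points."""

    tissue: str
    stages: dict[int, list[str]]
    ages: dict[int, tuple[int, int]]


def bin_stages(meta: pd.DataFrame, tissue: str,
               ages: tuple[int, ...] = CANONICAL_AGES) -> StageBinning:
    """Bin one tissue's samples into adjacent-age stages."""
    sub = meta[meta["tissue"] == tissue]
    if sub.empty:
        raise AnalysisError(f"no samples for tissue {tissue!r}")
    present = set(sub["age_weeks"])
    stray = present - set(ages)
    if stray:
        raise AnalysisError(f"non-canonical age point(s) {sorted(stray)} "
                            f"in tissue {tissue!r}")
    missing = set(ages) - present
    if missing:
        raise AnalysisError(f"missing age point(s) {sorted(missing)} "
                            f"in tissue {tissue!r}")
    stages, stage_ages = {}, {}
    for s, (a1, a2) in enumerate(zip(ages, ages[1:]), start=1):
        ids = sub.loc[sub["age_weeks"].isin((a1, a2)), "sample_id"]
        stages[s] = list(ids)
        stage_ages[s] = (a1, a2)
    return StageBinning(tissue=tissue, stages=stages, ages=stage_ages)


def _zscore_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row z-scores; returns (z, degenerate_mask). Degenerate rows are 0."""
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    degenerate = (sd == 0).ravel()
    sd[sd == 0] = 1.0
    return (x - mu) / sd, degenerate


def correlation_matrix(a: np.ndarray, b: np.ndarray):
    """Pearson r of every row of ``a`` against every row of ``b`` (shared
    columns), with two-sided t-transform p-values.

    Rows with zero variance yield NaN r and p (their pairs are skipped by
    callers). Returns (r, p) of shape (len(a), len(b)).
    """
    n = a.shape[1]
    if n < 4:
        raise AnalysisError("need >= 4 samples for stage correlations")
    za, dega = _zscore_rows(a)
    zb, degb = _zscore_rows(b)
    r = (za @ zb.T) / n
    r = np.clip(r, -1.0, 1.0)
    r[dega, :] = np.nan
    r[:, degb] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isinf(t), 0.0, p)
    return r, p


def stage_edges(expr: ExpressionMatrix, lnc_ids: list[str], mrna_ids: list[str],
                stage_samples: list[str], r_min: float = 0.9,
                q_max: float = 0.05, signed: bool = True) -> pd.DataFrame:
    """Candidate edges between AR-lncRNAs and AR-mRNAs within one stage.

    Pearson r on per-gene z-scored stage expression (z-scoring leaves r
    unchanged); BH spans all tested lnc x mRNA pairs of this tissue x
    stage. ``significant`` requires r > r_min (or |r| > r_min when
    ``signed=False``) and q < q_max. Pairs involving a zero-variance gene
    are dropped.

    Returns (lnc_id, mrna_id, r, p, q, significant).
    """
    lnc_ids, mrna_ids = sorted(set(lnc_ids)), sorted(set(mrna_ids))
    if not lnc_ids or not mrna_ids:
        raise AnalysisError("both node sets must be non-empty")
    a = expr.log2.loc[lnc_ids, stage_samples].to_numpy()
    b = expr.log2.loc[mrna_ids, stage_samples].to_numpy()
    r, p = correlation_matrix(a, b)
    lnc_col = np.repeat(lnc_ids, len(mrna_ids))
    mrna_col = np.tile(mrna_ids, len(lnc_ids))
    out = pd.DataFrame({"lnc_id": lnc_col, "mrna_id": mrna_col,
                        "r": r.ravel(), "p": p.ravel()})
    out = out.dropna(subset=["r"]).reset_index(drop=True)
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    r_ok = out["r"] > r_min if signed else out["r"].abs() > r_min
    out["significant"] = r_ok & (out["q"] < q_max)
    return out


@dataclass
class ConsensusNetwork:
    """Bipartite AR-lncRNA ~ AR-mRNA consensus network of one tissue.

    ``edges`` columns: lnc_id, mrna_id, r1..r4, q1..q4, sig_stages
    (comma-joined stage indices where the edge passed the thresholds).
    """

    tissue: str
    lnc_nodes: set[str]
    mrna_nodes: set[str]
    edges: pd.DataFrame

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_ids(self) -> set[str]:
        if self.edges.empty:
            return set()
        return set(self.edges["lnc_id"]) | set(self.edges["mrna_id"])


def consensus_network(per_stage: dict[int, pd.DataFrame], tissue: str,
                      lnc_nodes: set[str], mrna_nodes: set[str],
                      consensus_stages: tuple[int, ...] = (1, 4),
                      rule: str = "union") -> ConsensusNetwork:
    """Combine per-stage edge tables into the consensus network.

    ``rule="union"`` (default) keeps edges significant in any consensus
    stage — the reading that lets late-emerging (growth) edges into the
    network; ``rule="intersection"`` requires significance in all of them.
    Every retained edge carries r and q at all four stages.
    """
    for s in (1, 2, 3, 4):
        if s not in per_stage:
            raise AnalysisError(f"missing stage {s} edge table")
    if rule not in ("union", "intersection"):
        raise AnalysisError(f"unknown consensus rule {rule!r}")
    sig = {}
    for s in (1, 2, 3, 4):
        t = per_stage[s]
        sig[s] = set(zip(t.loc[t["significant"], "lnc_id"],
                         t.loc[t["significant"], "mrna_id"]))
    chosen = [sig[s] for s in consensus_stages]
    keep = set.union(*chosen) if rule == "union" else set.intersection(*chosen)
    base = per_stage[1][["lnc_id", "mrna_id"]].copy()
    for s in (1, 2, 3, 4):
        t = per_stage[s].set_index(["lnc_id", "mrna_id"])
        idx = pd.MultiIndex.from_frame(base[["lnc_id", "mrna_id"]])
        base[f"r{s}"] = t["r"].reindex(idx).to_numpy()
        base[f"q{s}"] = t["q"].reindex(idx).to_numpy()
    pair = list(zip(base["lnc_id"], base["mrna_id"]))
    base["sig_stages"] = [
        ",".join(str(s) for s in (1, 2, 3, 4) if pm in sig[s]) for pm in pair
    ]
    mask = [pm in keep for pm in pair]
    edges = base.loc[mask].reset_index(drop=True)
    return ConsensusNetwork(tissue=tissue, lnc_nodes=set(lnc_nodes),
                            mrna_nodes=set(mrna_nodes), edges=edges)


def _network_graph(network: ConsensusNetwork, weight_stage: int | None = None) -> ig.Graph:
    nodes = sorted(network.node_ids())
    index = {g: i for i, g in enumerate(nodes)}
    g = ig.Graph(n=len(nodes))
    g.vs["name"] = nodes
    g.vs["biotype"] = ["lncRNA" if v in network.lnc_nodes else "mRNA" for v in nodes]
    pairs = [(index[l], index[m]) for l, m in
             zip(network.edges["lnc_id"], network.edges["mrna_id"])]
    g.add_edges(pairs)
    if weight_stage is not None:
        g.es["weight"] = network.edges[f"r{weight_stage}"].abs().tolist()
    return g


@dataclass
class ModuleSet:
    """Detected network modules: DataFrame (module_id, gene_id, biotype)."""

    table: pd.DataFrame
    method: str = "walktrap"
    steps: int = 10
    min_size: int = 30

    @property
    def module_ids(self) -> list[str]:
        return sorted(self.table["module_id"].unique())

    def members(self, module_id: str) -> set[str]:
        return set(self.table.loc[self.table["module_id"] == module_id, "gene_id"])


def detect_modules(network: ConsensusNetwork, steps: int = 10, min_size: int = 30,
                   weight_stage: int | None = None) -> ModuleSet:
    """Walktrap community detection on the consensus network.

    Runs ``steps``-step random walks on the unweighted graph (or weighted
    by |r| at ``weight_stage``) and retains communities with strictly more
    than ``min_size`` genes. An edgeless network yields zero modules.
    """
    if network.edges.empty:
        return ModuleSet(table=pd.DataFrame(columns=["module_id", "gene_id", "biotype"]),
                         steps=steps, min_size=min_size)
    g = _network_graph(network, weight_stage)
    weights = g.es["weight"] if weight_stage is not None else None
    clustering = g.community_walktrap(weights=weights, steps=steps).as_clustering()
    rows = []
    k = 0
    for community in sorted(clustering, key=lambda c: (-len(c), min(c))):
        if len(community) <= min_size:
            continue
        k += 1
        for v in sorted(community):
            rows.append((f"M{k}", g.vs[v]["name"], g.vs[v]["biotype"]))
    return ModuleSet(table=pd.DataFrame(rows, columns=["module_id", "gene_id", "biotype"]),
                     steps=steps, min_size=min_size)


def growth_metrics(expr: ExpressionMatrix, lnc_ids: list[str], mrna_ids: list[str],
                   binning: StageBinning, r_edge: float = 0.9,
                   modules: ModuleSet | None = None) -> pd.DataFrame:
    """Per-stage co-expression growth summary.

    For each stage: mean |r| over all lnc x mRNA pairs, the number of pairs
    with r > ``r_edge``, and (per detected module) the within-module mean
    |r|. The returned frame carries a ``monotone`` attribute-style column
    repeated per row: True when the overall mean |r| strictly increases
    from stage 1 to 4.
    """
    lnc_ids, mrna_ids = sorted(set(lnc_ids)), sorted(set(mrna_ids))
    if not lnc_ids or not mrna_ids:
        raise AnalysisError("both node sets must be non-empty")
    rows = []
    overall = []
    for s in sorted(binning.stages):
        a = expr.log2.loc[lnc_ids, binning.stages[s]].to_numpy()
        b = expr.log2.loc[mrna_ids, binning.stages[s]].to_numpy()
        r, _ = correlation_matrix(a, b)
        mean_abs = float(np.nanmean(np.abs(r)))
        n_strong = int(np.nansum(r > r_edge))
        overall.append(mean_abs)
        row = {"stage": s, "mean_abs_r": mean_abs, "n_pairs_strong": n_strong,
               "n_pairs": int(np.isfinite(r).sum())}
        if modules is not None:
            for mid in modules.module_ids:
                mem = modules.members(mid)
                li = [i for i, g in enumerate(lnc_ids) if g in mem]
                mi = [j for j, g in enumerate(mrna_ids) if g in mem]
                row[f"mean_abs_r_{mid}"] = (
                    float(np.nanmean(np.abs(r[np.ix_(li, mi)])))
                    if li and mi else np.nan)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["monotone"] = bool(np.all(np.diff(overall) > 0))
    return out


def module_stage_mean_abs_r(expr: ExpressionMatrix, member_lnc: list[str],
                            member_mrna: list[str], binning: StageBinning) -> list[float]:
    """Mean within-module |r| per stage for an explicit bipartite member
    split (used for planted-module diagnostics)."""
    means = []
    for s in sorted(binning.stages):
        a = expr.log2.loc[sorted(member_lnc), binning.stages[s]].to_numpy()
        b = expr.log2.loc[sorted(member_mrna), binning.stages[s]].to_numpy()
        r, _ = correlation_matrix(a, b)
        means.append(float(np.nanmean(np.abs(r))))
    return means


def coexpressed_partners(lnc_id: str, expr: ExpressionMatrix, mrna_ids: list[str],
                         sample_ids: list[str], r_min: float = 0.8,
                         q_max: float = 0.05) -> pd.DataFrame:
    """mRNA partners of one lncRNA over all samples of a tissue.

    Pearson r of the lncRNA against every detectable mRNA; BH over the
    scanned mRNAs; partners satisfy r > r_min (signed) and q < q_max.
    Returns the full scan (mrna_id, r, p, q, partner) sorted by r
    descending.
    """
    if lnc_id not in expr.log2.index:
        raise AnalysisError(f"lncRNA {lnc_id!r} is not detectable")
    mrna_ids = sorted(set(mrna_ids) - {lnc_id})
    if not mrna_ids:
        raise AnalysisError("no mRNAs to scan")
    a = expr.log2.loc[[lnc_id], sample_ids].to_numpy()
    b = expr.log2.loc[mrna_ids, sample_ids].to_numpy()
    r, p = correlation_matrix(a, b)
    out = pd.DataFrame({"mrna_id": mrna_ids, "r": r.ravel(), "p": p.ravel()})
    out = out.dropna(subset=["r"]).reset_index(drop=True)
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["partner"] = (out["r"] > r_min) & (out["q"] < q_max)
    return out.sort_values("r", ascending=False).reset_index(drop=True)


def export_graphml(network: ConsensusNetwork, path) -> None:
    """Write the consensus network as GraphML (igraph writer)."""
    g = _network_graph(network)
    for s in (1, 2, 3, 4):
        g.es[f"r{s}"] = network.edges[f"r{s}"].tolist()
    g.es["sig_stages"] = network.edges["sig_stages"].tolist()
    g.write_graphml(str(path))
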