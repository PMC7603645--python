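"""End-to-end orchestration: counts -> AR calls -> specificity ->
similarity -> networks -> enrichment, per tissue, with a run manifest.

Tissues are processed independently in alphabetical order; every output
table declares its generating thresholds in a leading comment line; the
whole run is deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aging import (ARGeneSet, aging_correlation, call_aging_regulated,
                    compare_gene_features, cross_tissue_overlap,
                    differential_expression, old_young_fold_change)
from .enrichment import enrich, read_gmt, recurrent_terms
from .errors import ConfigError, LncageError
from .expression import (ExpressionMatrix, compute_fpkm, filter_detectable,
                         tmm_normalization_factors)
from .io import load_inputs, write_tsv
from .network import (bin_stages, coexpressed_partners, consensus_network,
                      detect_modules, export_graphml, growth_metrics,
                      module_stage_mean_abs_r, stage_edges)
from .simulate import StudyConfig, SyntheticTruth, generate_study
from .specificity import (classify_specific, fractional_profile,
                          quantile_groups, regulation_shift)
from .similarity import abundance_matched_subsets, pairwise_similarity

log = logging.getLogger("lncage")

YOUNG_AGE = 8
CONTRAST_AGES = (26, 60, 78, 104)
OLD_AGES = (78, 104)


@dataclass
class PipelineConfig:
    """All pipeline thresholds (defaults = study values) plus input source.

    Exactly one of ``input paths`` (counts/samples/genes) or ``synthetic``
    must be provided.
    """

    counts_path: str | None = None
    samples_path: str | None = None
    genes_path: str | None = None
    gmt_path: str | None = None
    synthetic: StudyConfig | None = None
    outdir: str = "lncage_out"
    seed: int = 0
    # expression
    min_fpkm: float = 0.5
    min_sample_frac: float = 0.2
    pseudocount: float = 1.0
    detect_per_tissue: bool = True
    # aging correlation
    corr_r_min: float = 0.9
    corr_p_max: float = 0.05
    # AR calling
    fc_min: float = 0.75
    fdr_max: float = 0.1
    # specificity
    spec_thresholds: tuple[float, ...] = (0.25, 0.3, 0.35, 0.4, 0.45, 0.5)
    top_frac: float = 0.2
    bottom_frac: float = 0.2
    # networks
    edge_r_min: float = 0.9
    edge_q_max: float = 0.05
    edge_signed: bool = True
    consensus_rule: str = "union"
    walktrap_steps: int = 10
    module_min_size: int = 30
    partner_r_min: float = 0.8
    partner_q_max: float = 0.05
    # enrichment
    enrich_min_term: int = 10
    enrich_max_term: int = 400
    enrich_min_query: int = 5
    enrich_fdr_max: float = 0.1
    recurrence_min_tissues: int = 2

    def validate(self) -> None:
        has_paths = self.counts_path is not None
        if has_paths == (self.synthetic is not None):
            raise ConfigError("provide exactly one of input paths or a "
                              "synthetic study config")
        if has_paths and (self.samples_path is None or self.genes_path is None):
            raise ConfigError("counts, samples and genes paths are all required")
        for name in ("min_sample_frac", "top_frac", "bottom_frac"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} out of range: {v}")
        if self.top_frac + self.bottom_frac > 1:
            raise ConfigError("overlapping specificity quantiles")
        if self.consensus_rule not in ("union", "intersection"):
            raise ConfigError(f"unknown consensus rule {self.consensus_rule!r}")


@dataclass
class TissueResult:
    tissue: str
    expr: ExpressionMatrix
    correlation: pd.DataFrame
    de_tables: dict[int, pd.DataFrame]
    ar: ARGeneSet
    fold_changes: pd.Series
    network: object = None
    modules: object = None
    growth: pd.DataFrame | None = None
    partners: dict[str, pd.DataFrame] = field(default_factory=dict)
    enrichment: dict[str, pd.DataFrame] = field(default_factory=dict)
    age_profile: pd.DataFrame | None = None
    spec_groups: tuple[set[str], set[str]] | None = None
    spec_class: pd.DataFrame | None = None
    shift: object = None
    features: pd.DataFrame | None = None
    matched: tuple[list[str], list[str]] | None = None


@dataclass
class RunResult:
    config: PipelineConfig
    tissues: dict[str, TissueResult]
    sharing: tuple[pd.DataFrame, pd.DataFrame] | None
    similarity: dict[str, pd.DataFrame]
    specificity_scores: dict[int, pd.DataFrame]  # age -> tissue-axis profile
    recurrence: dict[str, pd.DataFrame]
    recovery: pd.DataFrame | None
    outdir: Path
    truth: SyntheticTruth | None = None


def _per_tissue_expression(counts, samples, genes, cfg: PipelineConfig,
                           factors) -> dict[str, ExpressionMatrix]:
    fpkm = compute_fpkm(counts, genes.set_index("gene_id")["length_bp"], factors)
    out = {}
    for tissue in sorted(samples["tissue"].unique()):
        ids = samples.loc[samples["tissue"] == tissue, "sample_id"]
        sub = fpkm[list(ids)] if cfg.detect_per_tissue else fpkm
        em = filter_detectable(sub, cfg.min_fpkm, cfg.min_sample_frac,
                               cfg.pseudocount,
                               tmm_factors=factors[list(sub.columns)])
        if cfg.detect_per_tissue:
            out[tissue] = em
        else:
            out[tissue] = em.subset_samples(list(ids))
        log.info("tissue %s: %d/%d genes detectable", tissue,
                 int(em.detectable.sum()), len(em.detectable))
    return out


def _stage_network(expr, samples, tissue, ar: ARGeneSet, cfg: PipelineConfig):
    binning = bin_stages(samples, tissue)
    lnc = sorted(ar.by_biotype("lncRNA") & set(expr.genes))
    mrna = sorted(ar.by_biotype("mRNA") & set(expr.genes))
    if not lnc or not mrna:
        log.warning("tissue %s: empty AR node set, skipping network", tissue)
        return binning, None, None, None
    per_stage = {s: stage_edges(expr, lnc, mrna, binning.stages[s],
                                cfg.edge_r_min, cfg.edge_q_max, cfg.edge_signed)
                 for s in binning.stages}
    net = consensus_network(per_stage, tissue, set(lnc), set(mrna),
                            rule=cfg.consensus_rule)
    if net.edges.empty:
        log.warning("tissue %s: consensus network has no edges", tissue)
    modules = detect_modules(net, cfg.walktrap_steps, cfg.module_min_size)
    growth = growth_metrics(expr, lnc, mrna, binning, cfg.edge_r_min, modules)
    return binning, net, modules, growth


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Run every stage and write all outputs under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    truth = None
    if config.synthetic is not None:
        study_cfg = dataclasses.replace(config.synthetic, seed=config.seed)
        counts, samples, genes, truth = generate_study(study_cfg)
    else:
        counts, samples, genes, _report = load_inputs(
            config.counts_path, config.samples_path, config.genes_path)

    stage = "normalization"
    try:
        factors = tmm_normalization_factors(counts)
        lengths = genes.set_index("gene_id")["length_bp"]
        fpkm = compute_fpkm(counts, lengths, factors)
        global_expr = filter_detectable(fpkm, config.min_fpkm,
                                        config.min_sample_frac,
                                        config.pseudocount, tmm_factors=factors)
        per_tissue_expr = _per_tissue_expression(counts, samples, genes,
                                                 config, factors)

        stage = "specificity"
        spec_scores: dict[int, pd.DataFrame] = {}
        if samples["tissue"].nunique() >= 2:
            for age in sorted(samples["age_weeks"].unique()):
                spec_scores[int(age)] = fractional_profile(
                    global_expr, samples, "tissue", age)

        collection = read_gmt(config.gmt_path) if config.gmt_path else None
        lnc_universe = set(genes.loc[genes["biotype"] == "lncRNA", "gene_id"])
        tissues: dict[str, TissueResult] = {}
        row_counts: dict[str, dict[str, int]] = {}
        for tissue in sorted(samples["tissue"].unique()):
            stage = f"{tissue}:aging"
            expr = per_tissue_expr[tissue]
            corr = aging_correlation(expr, samples, tissue,
                                     config.corr_r_min, config.corr_p_max)
            de = {age: differential_expression(expr, samples, tissue, age)
                  for age in CONTRAST_AGES
                  if age in set(samples.loc[samples["tissue"] == tissue,
                                            "age_weeks"])}
            ar = call_aging_regulated({a: de[a] for a in OLD_AGES if a in de},
                                      genes, config.fc_min, config.fdr_max)
            fc = old_young_fold_change({a: de[a] for a in OLD_AGES if a in de})
            tr = TissueResult(tissue, expr, corr, de, ar, fc)

            stage = f"{tissue}:network"
            binning, net, modules, growth = _stage_network(
                expr, samples, tissue, ar, config)
            tr.network, tr.modules, tr.growth = net, modules, growth

            stage = f"{tissue}:partners"
            mrna_all = sorted(set(expr.genes)
                              & set(genes.loc[genes["biotype"] == "mRNA",
                                              "gene_id"]))
            sample_ids = list(samples.loc[samples["tissue"] == tissue,
                                          "sample_id"])
            for lnc in sorted(ar.by_biotype("lncRNA") & set(expr.genes)):
                tr.partners[lnc] = coexpressed_partners(
                    lnc, expr, mrna_all, sample_ids,
                    config.partner_r_min, config.partner_q_max)

            stage = f"{tissue}:specificity"
            lnc_det = sorted(set(expr.genes) & lnc_universe)
            ar_lnc = ar.by_biotype("lncRNA") & set(expr.genes)
            anr_lnc = set(lnc_det) - ar.members
            if spec_scores:
                youngest = min(spec_scores)
                scores = spec_scores[youngest]["score"].reindex(lnc_det).dropna()
                groups = {}
                if ar_lnc & set(scores.index):
                    groups["AR-lncRNA"] = scores.loc[sorted(ar_lnc & set(scores.index))]
                if anr_lnc & set(scores.index):
                    groups["ANR-lncRNA"] = scores.loc[sorted(anr_lnc & set(scores.index))]
                if groups:
                    tr.spec_class = classify_specific(groups, config.spec_thresholds)
                if len(scores) >= 5:
                    spec_set, ctrl_set = quantile_groups(
                        scores, config.top_frac, config.bottom_frac)
                    tr.spec_groups = (spec_set, ctrl_set)
                    tr.shift = regulation_shift(fc, spec_set, ctrl_set, ar.members)
            tr.age_profile = fractional_profile(expr, samples, "age", tissue)
            if ar_lnc and anr_lnc:
                tr.features = compare_gene_features(genes, ar_lnc, anr_lnc, expr)
            ar_mrna = ar.by_biotype("mRNA") & set(expr.genes)
            if ar_lnc and ar_mrna:
                try:
                    tr.matched = abundance_matched_subsets(
                        sorted(ar_lnc), sorted(ar_mrna), expr,
                        seed=config.seed)
                except LncageError as exc:
                    log.warning("tissue %s: abundance matching skipped (%s)",
                                tissue, exc)

            stage = f"{tissue}:enrichment"
            if collection is not None:
                background = set(expr.genes)
                for label, direction in (("up", "up"), ("down", "down")):
                    query = set(ar.table.loc[
                        (ar.table["biotype"] == "mRNA")
                        & (ar.table["direction"] == direction), "gene_id"])
                    tr.enrichment[f"ar_mrna_{label}"] = enrich(
                        query & background, background, collection,
                        config.enrich_min_term, config.enrich_max_term,
                        config.enrich_min_query, config.enrich_fdr_max)
                partner_union = set().union(
                    *(set(t.loc[t["partner"], "mrna_id"])
                      for t in tr.partners.values())) if tr.partners else set()
                tr.enrichment["ar_lnc_partners"] = enrich(
                    partner_union & background, background, collection,
                    config.enrich_min_term, config.enrich_max_term,
                    config.enrich_min_query, config.enrich_fdr_max)
            tissues[tissue] = tr
            row_counts[tissue] = {
                "detectable": int(expr.detectable.sum()),
                "aging_correlated": int(corr["called"].sum()),
                "ar_genes": len(ar.table),
                "network_edges": 0 if net is None else net.n_edges,
                "modules": 0 if modules is None else len(modules.module_ids),
            }

        # ---- cross-tissue stages -----------------------------------------
        stage = "sharing"
        ar_sets = [tissues[t].ar for t in sorted(tissues)]
        sharing = cross_tissue_overlap(ar_sets) if len(ar_sets) >= 2 else None
        stage = "similarity"
        sim = {bt: pairwise_similarity(ar_sets, bt)
               for bt in ("lncRNA", "mRNA")} if len(ar_sets) >= 2 else {}

        stage = "recurrence"
        recurrence: dict[str, pd.DataFrame] = {}
        if collection is not None and len(tissues) >= 2:
            for key in ("ar_mrna_up", "ar_mrna_down", "ar_lnc_partners"):
                tables = {t: tissues[t].enrichment[key] for t in tissues
                          if key in tissues[t].enrichment}
                if len(tables) >= 2:
                    recurrence[key] = recurrent_terms(
                        tables, config.recurrence_min_tissues)

        stage = "recovery"
        recovery = None
        if truth is not None:
            recovery = recovery_report(tissues, spec_scores, truth,
                                       samples, config)

        stage = "write"
        _write_outputs(outdir, config, tissues, sharing, sim, spec_scores,
                       recurrence, recovery, row_counts, truth)
    except LncageError as exc:
        raise LncageError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return RunResult(config, tissues, sharing, sim, spec_scores, recurrence,
                     recovery, outdir, truth)


def recovery_report(tissues: dict[str, TissueResult],
                    spec_scores: dict[int, pd.DataFrame],
                    truth: SyntheticTruth, samples: pd.DataFrame,
                    config: PipelineConfig) -> pd.DataFrame:
    """Compare pipeline calls with the planted truth.

    Reports per-tissue AR sensitivity and false-discovery proportion, the
    planted fraction of the top specificity-score decile (youngest age),
    and per planted module the best Jaccard against detected modules plus
    the per-stage within-module mean |r| trend.
    """
    rows = []
    for tissue in sorted(tissues):
        tr = tissues[tissue]
        planted = truth.aging_genes(tissue) & set(tr.expr.genes)
        called = tr.ar.members
        tp = len(called & planted)
        sens = tp / len(planted) if planted else np.nan
        fdp = (len(called) - tp) / len(called) if called else 0.0
        rows.append(("ar_sensitivity", tissue, sens))
        rows.append(("ar_fdp", tissue, fdp))
    if spec_scores:
        youngest = min(spec_scores)
        scores = spec_scores[youngest]["score"]
        n_top = max(1, len(scores) // 10)
        top = set(scores.sort_values(ascending=False).index[:n_top])
        planted_spec = set(truth.specific["gene_id"])
        rows.append(("specific_top_decile_purity", f"age{youngest}",
                     len(top & planted_spec) / n_top))
    if truth.module_tissue in tissues and len(truth.coupling):
        tr = tissues[truth.module_tissue]
        binning = bin_stages(samples, truth.module_tissue)
        for mid in sorted(truth.coupling):
            members = truth.module_members(mid) & set(tr.expr.genes)
            best = 0.0
            if tr.modules is not None and len(tr.modules.table):
                for det in tr.modules.module_ids:
                    d = tr.modules.members(det)
                    j = len(d & members) / len(d | members)
                    best = max(best, j)
            rows.append((f"module_jaccard_{mid}", truth.module_tissue, best))
            lnc = sorted(members & tr.ar.by_biotype("lncRNA"))
            mrna = sorted(members & tr.ar.by_biotype("mRNA"))
            if lnc and mrna:
                means = module_stage_mean_abs_r(tr.expr, lnc, mrna, binning)
                for s, m in enumerate(means, start=1):
                    rows.append((f"module_{mid}_stage{s}_mean_abs_r",
                                 truth.module_tissue, m))
                rows.append((f"module_{mid}_monotone", truth.module_tissue,
                             float(np.all(np.diff(means) > 0))))
    return pd.DataFrame(rows, columns=["metric", "context", "value"])


def _write_outputs(outdir: Path, config: PipelineConfig, tissues, sharing,
                   sim, spec_scores, recurrence, recovery, row_counts,
                   truth) -> None:
    thr = {"min_fpkm": config.min_fpkm, "min_sample_frac": config.min_sample_frac,
           "corr_r_min": config.corr_r_min, "corr_p_max": config.corr_p_max,
           "fc_min": config.fc_min, "fdr_max": config.fdr_max,
           "edge_r_min": config.edge_r_min, "edge_q_max": config.edge_q_max,
           "partner_r_min": config.partner_r_min,
           "partner_q_max": config.partner_q_max,
           "walktrap_steps": config.walktrap_steps,
           "module_min_size": config.module_min_size}
    for tissue in sorted(tissues):
        tr = tissues[tissue]
        d = outdir / tissue
        write_tsv(tr.correlation, d / "aging_correlated.tsv", thr)
        for age, table in tr.de_tables.items():
            write_tsv(table, d / f"de_{age:03d}w_vs_008w.tsv", thr)
        write_tsv(tr.ar.table, d / "ar_genes.tsv", thr)
        det = tr.expr.detectable[tr.expr.detectable].index.to_frame(index=False)
        write_tsv(det, d / "detectable_genes.tsv", thr)
        if tr.network is not None:
            write_tsv(tr.network.edges, d / "network_edges.tsv", thr)
            if not tr.network.edges.empty:
                export_graphml(tr.network, d / "network.graphml")
            write_tsv(tr.modules.table, d / "modules.tsv", thr)
            write_tsv(tr.growth, d / "network_growth.tsv", thr)
        if tr.partners:
            allp = pd.concat([t.assign(lnc_id=l) for l, t in tr.partners.items()])
            write_tsv(allp[allp["partner"]], d / "lnc_partners.tsv", thr)
        if tr.age_profile is not None:
            write_tsv(tr.age_profile, d / "age_specificity.tsv", thr, index=True)
        if tr.spec_groups is not None:
            spec_set, ctrl_set = tr.spec_groups
            groups = pd.DataFrame({
                "gene_id": sorted(spec_set) + sorted(ctrl_set),
                "group": ["tissue_specific"] * len(spec_set)
                         + ["control"] * len(ctrl_set)})
            write_tsv(groups, d / "specificity_groups.tsv", thr)
        if tr.spec_class is not None:
            write_tsv(tr.spec_class, d / "specificity_classification.tsv", thr)
        if tr.shift is not None:
            summary = pd.DataFrame([
                ("mannwhitney_p_abs_fc", tr.shift.mannwhitney_p),
                ("mannwhitney_p_signed_fc", tr.shift.mannwhitney_p_signed),
                ("ar_rate_specific_pct", tr.shift.ar_rate_specific),
                ("ar_rate_control_pct", tr.shift.ar_rate_control),
            ], columns=["metric", "value"])
            write_tsv(summary, d / "regulation_shift.tsv", thr)
            ecdf = pd.concat([tr.shift.ecdf_specific.assign(group="specific"),
                              tr.shift.ecdf_control.assign(group="control")])
            write_tsv(ecdf, d / "regulation_shift_ecdf.tsv", thr)
        if tr.features is not None:
            write_tsv(tr.features, d / "feature_comparison.tsv", thr)
        if tr.matched is not None:
            lnc_m, mrna_m = tr.matched
            matched = pd.DataFrame({
                "gene_id": list(lnc_m) + list(mrna_m),
                "biotype": ["lncRNA"] * len(lnc_m) + ["mRNA"] * len(mrna_m)})
            write_tsv(matched, d / "abundance_matched.tsv", thr)
        for key, table in tr.enrichment.items():
            write_tsv(table, d / f"enrichment_{key}.tsv", thr)
    if sharing is not None:
        write_tsv(sharing[0], outdir / "ar_sharing_per_gene.tsv", thr)
        write_tsv(sharing[1], outdir / "ar_sharing_summary.tsv", thr)
    for bt, matrix in sim.items():
        write_tsv(matrix, outdir / f"tissue_similarity_{bt}.tsv", thr, index=True)
    for age, prof in spec_scores.items():
        write_tsv(prof, outdir / f"tissue_specificity_age{age:03d}w.tsv", thr,
                  index=True)
    for key, table in recurrence.items():
        write_tsv(table, outdir / f"recurrent_terms_{key}.tsv", thr)
    if recovery is not None:
        write_tsv(recovery, outdir / "recovery_report.tsv", thr)
    manifest = {
        "lncage_version": __version__,
        "seed": config.seed,
        "thresholds": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in thr.items()},
        "row_counts": row_counts,
        "synthetic": config.synthetic is not None,
    }
    with open(outdir / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
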