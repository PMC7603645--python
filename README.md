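# lncage

Multi-tissue aging transcriptome analysis for bulk RNA-seq: from a
gene-level count matrix to aging-regulated (AR) mRNA/lncRNA calls,
tissue- and age-specificity scores, tissue-similarity matrices,
stage-binned AR-lncRNA~AR-mRNA co-expression networks with module
detection and growth metrics, and local gene-set enrichment.

The package targets studies that profile many organs at several ages
across a lifespan — the canonical design being 11 mouse tissues sampled
at 8, 26, 60, 78 and 104 weeks with 5 animals per tissue × age (275
samples) — and asks how long non-coding RNAs are regulated during aging:
which are induced or repressed, how tissue-restricted they are, and how
their co-expression with coding genes reorganizes across life stages.
Because raw multi-terabyte sequencing data are rarely at hand, `lncage`
ships a first-class synthetic-study generator that plants known aging
genes, tissue-specific genes and co-expression modules, so that every
stage of the pipeline can be validated end to end against ground truth.

## The statistics at the core

* **Normalization** — TMM (trimmed mean of M-values, Robinson–Oshlack)
  factors, FPKM, log2 transform; a gene is *detectable* when
  FPKM > 0.5 in at least 20 % of samples.
* **Aging-correlated genes** — Pearson r between log2 expression and
  log2(age weeks); called at |r| > 0.9, p < 0.05 (t-transform).
* **Aging-regulated (AR) genes** — Welch-t differential expression of
  each older group vs the 8-week group with BH FDR per
  (tissue, contrast); AR iff |log2FC| > 0.75 and FDR < 0.1 in the
  78w-vs-8w or 104w-vs-8w contrast. log2FC(old/young) is the
  larger-magnitude signed FC of the two old contrasts.
* **Specificity** — fractional expression: for gene *i* and category *j*
  (tissue at fixed age, or age at fixed tissue),
  `f_ij = m_ij / Σ_j m_ij` on linear-scale replicate means; the score is
  max_j f_ij (1 = exclusive, 1/k = uniform).
* **Tissue similarity** — `0.8·J(A,B) + 0.2·O(A,B)` where J is the
  Jaccard index and O the overlap coefficient of two tissues' AR sets.
* **Networks** — samples binned into four stages (8&26, 26&60, 60&78,
  78&104 weeks); per stage, Pearson r over every AR-lncRNA × AR-mRNA
  pair with BH FDR; edges at r > 0.9, q < 0.05; consensus = union of
  young- and old-stage edges with per-stage weights retained; walktrap
  (10 steps) communities with > 30 genes are modules; per-lncRNA partner
  lists (r > 0.8, q < 0.05 over all the tissue's samples) feed
  guilt-by-association annotation.
* **Enrichment** — hypergeometric upper tail against a GMT collection
  over an explicit background, terms restricted to 10–400 background
  members, overlap ≥ 5, BH FDR < 0.1; term recurrence across tissues.

## Worked example

```bash
lncage run --synthetic --outdir out --seed 1 --n-tissues 3 --n-genes 2000
```

runs the full pipeline on a generated 3-tissue study and prints:

```
brain   detectable=2000 AR=169  edges=389
hypothalamus    detectable=2000 AR=124  edges=17
lung    detectable=2000 AR=125  edges=20
outputs written to out
```

`brain` here hosts the planted 40-gene module, hence the larger AR set
(planted aging genes + the late-life-activated module program) and the
dense edge set; the other tissues carry only the 120 planted aging genes
each, and their few edges are young-stage co-aging correlations. Because
the study is synthetic, `out/recovery_report.tsv` compares every call
against the planted truth:

```
lncage recover --rundir out
```

```
                     metric      context    value
             ar_sensitivity        brain 0.993750
                     ar_fdp        brain 0.059172
             ar_sensitivity hypothalamus 0.983333
                     ar_fdp hypothalamus 0.048387
             ar_sensitivity         lung 1.000000
                     ar_fdp         lung 0.040000
 specific_top_decile_purity         age8 1.000000
          module_jaccard_M1        brain 1.000000
module_M1_stage1_mean_abs_r        brain 0.640650
module_M1_stage2_mean_abs_r        brain 0.784848
module_M1_stage3_mean_abs_r        brain 0.870915
module_M1_stage4_mean_abs_r        brain 0.976235
         module_M1_monotone        brain 1.000000
```

Reading: ≥ 98 % of the planted aging genes are recovered as AR with a
false-discovery proportion under 6 %; the top decile of tissue-specificity
scores is occupied entirely by planted tissue-specific genes; the planted
module is recovered exactly (Jaccard 1.0); and its mean within-module
|r| grows strictly across the four life stages (0.64 → 0.98),
reproducing the programmed coupling schedule (0.1, 0.3, 0.6, 0.9).

Per-tissue outputs land under `out/<tissue>/` (aging correlations, DE
tables, AR sets, network edge table + GraphML, modules, growth metrics,
partner lists, specificity classification, regulation-shift ECDFs,
feature comparisons); cross-tissue outputs (AR sharing, similarity
matrices, per-age specificity scores, recurrent terms) sit at the top
level next to `run_manifest.yaml`.

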