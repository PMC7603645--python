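# Methods

This note documents the models and procedures implemented in `lncage`,
the design choices made where the design was genuinely open, and what
the synthetic validation does and does not establish.

## Normalization and detectability

Counts are normalized with TMM (trimmed mean of M-values): the reference
sample is the one whose upper quartile of counts-per-million is closest
to the mean upper quartile; each sample's factor is the doubly trimmed
(30 % on M-values, 5 % on A-values), inverse-asymptotic-variance-weighted
mean of log2 ratios against the reference, computed over genes positive
in both samples; factors are rescaled to geometric mean 1. The
implementation follows the edgeR convention in every detail and is
cross-checked against `edgeR::calcNormFactors` (via Rscript) in the test
suite to 1e-6.

FPKM is count / (gene length in kb × effective library in millions),
with effective library = raw library size × TMM factor. Genes with
missing or non-positive lengths are rejected, never silently dropped.

Detectability: FPKM strictly greater than 0.5 in at least
ceil(0.2 × n_samples) samples. Both inequalities at the boundary are
deliberate and pinned by tests (0.5 exactly fails; a single qualifying
sample out of five suffices). The filter is applied per tissue by
default (`detect_per_tissue=False` switches to one global filter across
all samples); per-tissue filtering matches the per-tissue nature of
every downstream stage. Log transform uses log2(FPKM + 1); the
pseudocount is configurable.

## Aging-correlated and aging-regulated genes

Aging correlation is Pearson r between log2 expression and log2(age in
weeks) over all replicate samples of a tissue (a per-age-mean mode is
available); p-values come from the t-transform t = r·√((n−2)/(1−r²))
with n−2 df, validated against permutation nulls. Zero-variance genes
are excluded and flagged, not errors.

Differential expression is a Welch t-test on log2(FPKM+1) per
(tissue, contrast), BH-adjusted within that family. This is a simple,
transparent test whose thresholds (|log2FC| > 0.75, FDR < 0.1) carry the
AR definition; it deliberately forgoes empirical-Bayes variance
moderation — at 5 replicates per group and the planted effect sizes the
simple test already recovers ≥ 97 % of planted genes, and the threshold
semantics stay exactly interpretable.

A gene is aging-regulated (AR) when it passes both thresholds in the
78-week or the 104-week contrast against 8 weeks. Its summary
log2FC(old/young) is the signed fold change of **larger magnitude**
among the two old contrasts — magnitude, not value, so that strongly
downregulated genes keep their negative sign. Genes qualifying in both
contrasts with opposite signs are kept and labelled `discordant`.
Strict inequalities throughout; boundary genes are excluded.

## Specificity scores

Fractional expression: per gene, the mean linear-scale FPKM per category
(tissues at a fixed age, or ages within a fixed tissue) divided by the
sum over categories. Linear scale is required — log-scale values can be
negative and break the sum-to-one normalization. The specificity score
is the maximum fraction; on the age axis the sd of the five fractions is
reported as well. Genes with zero total expression in the profile are
excluded and logged.

Threshold classification (scores > 0.25 … 0.5) and top/bottom-20 %
quantile grouping use strict inequalities and deterministic gene-id
tie-breaking, so set sizes are exactly floor(frac × n) and runs are
byte-reproducible. The regulation-shift analysis compares |log2FC(old/
young)| ECDFs of the tissue-specific vs control (bottom-quantile) groups
with a two-sided Mann-Whitney test, and reports each group's AR rate.
The pipeline ranks by the youngest-age specificity profile: at later
ages, per-tissue aging regulation itself perturbs tissue fractions, so
the young profile is the cleanest measure of constitutive specificity
(true for real data as well as the simulation).

## Tissue similarity

The similarity of two AR sets is 0.8·Jaccard + 0.2·overlap-coefficient —
the enrichment-map-style combined set-similarity measure: bounded in
[0, 1], symmetric, 1 iff equal, 0 iff disjoint, monotone under shared
additions. A raw-cardinality variant (0.8·|A∪B| + 0.2·|A∩B|) is kept
behind `raw=True` for auditability; it is unbounded and not used by the
pipeline. Abundance matching for fair lncRNA-vs-mRNA comparisons bins
pooled mean log2 expression into 10 quantile bins and samples equal
numbers per biotype per bin without replacement, seeded.

## Co-expression networks

Samples of one tissue are merged into four overlapping life stages
(8&26, 26&60, 60&78, 78&104 weeks; 10 samples per stage at 5
replicates). Within each stage every AR-lncRNA × AR-mRNA pair is scored
by Pearson r on per-gene z-scored values (z-scoring is cosmetic for
Pearson and asserted so by test); BH spans all pairs of one
tissue × stage; an edge requires **signed** r > 0.9 and q < 0.05. The
signed rule follows the convention that co-expression modules are
positively co-regulated; an absolute-value mode is available.

The consensus network is the **union** of edges significant in the
youngest or the oldest stage, each edge carrying r and q at all four
stages. Union rather than intersection: the biology of interest is
network *growth* — edges that emerge only late in life would be
discarded by an intersection rule. Intersection is available via
configuration.

Modules are walktrap communities (10-step random walks) on the
unweighted consensus graph, retaining communities with strictly more
than 30 genes; weighting by |r| at a chosen stage is available. On
disconnected graphs walktrap reduces to connected components, which the
tests use as an oracle.

Growth metrics report, per stage, the mean |r| over all AR pairs, the
count of pairs above the edge threshold, and per-module mean |r|; the
monotone flag records a strict increase from stage 1 to 4. Note that on
real and simulated data alike, stage 1 spans the widest log2-age range
(8→26 weeks is 1.7 octaves), so strongly age-trending genes correlate
appreciably in the *young* stage; the growth signal of a module must
beat that baseline.

Per-lncRNA partner lists scan all detectable mRNAs over all of the
tissue's samples at r > 0.8 with BH q < 0.05, and feed
guilt-by-association enrichment of the partner union per tissue.

## Enrichment

Hypergeometric upper tail P(X ≥ overlap) of a query against an explicit
background — the detectable genes of the tissue, not the whole genome,
since only detectable genes could have been called. Terms are
intersected with the background and kept when 10 ≤ size ≤ 400; a term is
reported when its query overlap is ≥ 5; BH FDR < 0.1 marks significance.
The conservative EASE variant (overlap − 1) is available via `ease=True`.
Recurrence tables count, per term, the tissues where it is significant.

## The synthetic-study generator

The generator emulates the full design — 11 tissues × 5 ages
(8, 26, 60, 78, 104 weeks) × 5 replicates = 275 samples — at a
configurable gene count (default 2000, ~30 % lncRNA). Counts are
negative-binomial (dispersion 0.1) on a log-normal baseline (natural-log
mean 6.0, sd 0.8, ≈ 400 mean counts for mRNAs); lncRNA baselines are
4-fold lower, which makes the abundance-matched comparisons meaningful.

Planted structure:

* **Aging genes** (60 up + 60 down per tissue, drawn independently per
  tissue): log-linear trend in log2(weeks) on the log2-mean scale
  reaching ±2.0 log2 units at 104 vs 8 weeks — the axis the correlation
  stage assumes.
* **Tissue-specific genes** (250): baseline ×8 in one target tissue at
  all ages. Optionally (`specific_aging_effect`) they also age upward in
  that tissue, which the regulation-shift tests exploit.
* **Modules** (default one of 40 genes, 40 % lncRNA, coupling schedule
  0.1/0.3/0.6/0.9 per stage, acting in one tissue): a shared latent
  factor per module. The per-age coupling is the schedule value at the
  end ages and the mean of adjacent stages at interior ages. The latent
  draw is standardized within each age group (exact zero mean, unit
  variance across the replicates of one age), so group means — and hence
  every fold change — are untouched by the coupling, and the realized
  stage-wise shared variance is deterministic rather than subject to
  latent sampling noise; this is what makes the strict stage-monotonicity
  of within-module correlation a reliable property rather than a coin
  flip. Module genes are modelled as a late-life-activated program:
  baseline ×4, and a joint +5 log2 induction at the oldest age. The
  induction puts them solidly into the AR sets (network nodes are AR
  genes by construction, so a module whose members fail AR calling would
  be invisible to the network stage no matter how well it is detected),
  and it reinforces precisely the old-stage correlation the coupling
  schedule prescribes, while leaving stages 1–3 to the latent factor
  (σ = 1.5 log2 at coupling 1). With these defaults the programmed
  stage-wise mean within-module |r| runs ≈ 0.6 → 0.78 → 0.87 → 0.98.

What the generator does **not** emulate: batch effects, library-size or
GC biases beyond what TMM absorbs, isoform-level structure, count
overdispersion heterogeneity across genes, or correlated nulls. Passing
the recovery tests therefore demonstrates that the pipeline's statistics
do what they claim under their own assumptions — not that those
assumptions hold for any particular real dataset.

## Numerical choices and degenerate inputs

* Sample-size floors: ≥ 3 distinct ages for correlation, ≥ 2 replicates
  per DE group, ≥ 4 samples per stage for edge scans, ≥ 5 genes for
  quantile groups.
* Zero-variance genes: excluded and flagged in correlation and edge
  scans; in DE, equal constant groups get p = 1, unequal constant groups
  p = 0.
* Ties: Mann-Whitney uses the scipy tie-corrected implementation;
  quantile ranks break ties by gene id; BH is the standard step-up with
  monotonicity enforcement.
* Determinism: one integer seed governs the generator and every sampling
  step (abundance matching); two runs with the same seed produce
  byte-identical TSVs.

## Problem sizes used in validation

The recovery suite runs the scaled study (3 tissues × 2000 genes × 5
ages × 5 replicates) over three seeds; calibration uses ten pure-noise
single-tissue studies (300 genes; ≈ 250 000 tested pairs in total) and
1e5-shuffle permutation oracles for the correlation and Mann-Whitney
p-values. These sizes give Monte-Carlo standard errors comfortably
below the margins asserted by the tests.

## Known limitations

* Welch-t DE without variance moderation loses power below ~3 replicates
  per group; the pipeline refuses rather than guesses.
* The per-pair false-edge rate is the calibration quantity for the edge
  scan; with only a handful of discoveries the classical FDP
  (false/discovered) is a 0/1 variable and is not a stable target at
  small seed counts.
* The consensus-union rule admits young-stage co-aging edges between
  strongly trending genes; the module size filter (> 30) keeps them out
  of module calls, but edge counts per tissue include them.
* Enrichment treats terms as flat sets — no GO-DAG propagation or
  semantic collapsing.
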