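"""Tissue-similarity scores between aging-regulated gene sets.

The similarity of two tissues' AR gene sets is a weighted combination of
the Jaccard index and the overlap coefficient:

    similarity(A, B) = 0.8 * |A∩B| / |A∪B|  +  0.2 * |A∩B| / min(|A|, |B|)

the Enrichment-Map-style combined set-similarity measure: bounded in
[0, 1], symmetric, 1 iff the sets are equal, 0 iff disjoint. A raw
union/intersection-cardinality variant is available via ``raw=True`` for
auditability but is not bounded and not used by the pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .aging import ARGeneSet
from .errors import AnalysisError
from .expression import ExpressionMatrix


def similarity_score(set_a: set[str], set_b: set[str], weight_u: float = 0.8,
                     weight_i: float = 0.2, raw: bool = False) -> float:
    """Weighted Jaccard/overlap similarity of two gene sets."""
    if not set_a and not set_b:
        raise AnalysisError("similarity of two empty sets is undefined")
    inter = len(set_a & set_b)
    if raw:
        return weight_u * len(set_a | set_b) + weight_i * inter
    if inter == 0:
        return 0.0
    if set_a == set_b:
        return 1.0
    union = len(set_a | set_b)
    smaller = min(len(set_a), len(set_b))
    s = weight_u * inter / union + weight_i * inter / smaller
    return min(max(s, 0.0), 1.0)


def pairwise_similarity(ar_sets: list[ARGeneSet], biotype: str,
                        weight_u: float = 0.8, weight_i: float = 0.2) -> pd.DataFrame:
    """Symmetric tissue-by-tissue similarity matrix for one biotype.

    A tissue with an empty AR set of the requested biotype scores 0 against
    every other tissue (and NaN on its own diagonal would be misleading, so
    the diagonal is 1 only for non-empty sets).
    """
    if len(ar_sets) < 2:
        raise AnalysisError("need >= 2 tissues")
    tissues = [s.tissue for s in ar_sets]
    sets = {s.tissue: s.by_biotype(biotype) for s in ar_sets}
    n = len(tissues)
    values = np.zeros((n, n))
    for i, ti in enumerate(tissues):
        values[i, i] = 1.0 if sets[ti] else 0.0
        for j in range(i + 1, n):
            tj = tissues[j]
            if not sets[ti] and not sets[tj]:
                score = 0.0
            else:
                score = similarity_score(sets[ti], sets[tj], weight_u, weight_i) \
                    if (sets[ti] or sets[tj]) else 0.0
            values[i, j] = values[j, i] = score
    return pd.DataFrame(values, index=tissues, columns=tissues)


def abundance_matched_subsets(lnc_ids: list[str], mrna_ids: list[str],
                              expr: ExpressionMatrix, n_bins: int = 10,
                              seed: int = 0) -> tuple[list[str], list[str]]:
    """Abundance-matched lncRNA and mRNA subsets.

    Mean log2 expression is binned into ``n_bins`` quantile bins of the
    pooled distribution; within each bin, min(count_lnc, count_mrna) genes
    are sampled without replacement from each biotype. Deterministic for a
    fixed seed. Raises when no bin holds both biotypes.
    """
    if not lnc_ids or not mrna_ids:
        raise AnalysisError("both gene lists must be non-empty")
    lnc_ids, mrna_ids = sorted(set(lnc_ids)), sorted(set(mrna_ids))
    mean_expr = expr.log2.mean(axis=1)
    missing = (set(lnc_ids) | set(mrna_ids)) - set(mean_expr.index)
    if missing:
        raise AnalysisError(f"genes not in expression matrix: {sorted(missing)[:10]}")
    pooled = mean_expr.loc[lnc_ids + mrna_ids]
    edges = np.unique(np.quantile(pooled, np.linspace(0, 1, n_bins + 1)))
    bins = pd.cut(pooled, bins=edges, include_lowest=True, labels=False)
    rng = np.random.default_rng(seed)
    out_lnc: list[str] = []
    out_mrna: list[str] = []
    matched_any = False
    for b in range(len(edges) - 1):
        in_bin = bins.index[bins == b]
        lnc_b = [g for g in lnc_ids if g in set(in_bin)]
        mrna_b = [g for g in mrna_ids if g in set(in_bin)]
        k = min(len(lnc_b), len(mrna_b))
        if k == 0:
            continue
        matched_any = True
        out_lnc += list(rng.choice(lnc_b, size=k, replace=False))
        out_mrna += list(rng.choice(mrna_b, size=k, replace=False))
    if not matched_any:
        raise AnalysisError("no abundance bin contains both biotypes")
    return sorted(out_lnc), sorted(out_mrna)


def abundance_gap(lnc_ids: list[str], mrna_ids: list[str],
                  expr: ExpressionMatrix) -> float:
    """Two-sample Kolmogorov-Smirnov statistic between the mean-abundance
    distributions of two gene lists (matching diagnostic)."""
    mean_expr = expr.log2.mean(axis=1)
    return float(stats.ks_2samp(mean_expr.loc[sorted(set(lnc_ids))],
                                mean_expr.loc[sorted(set(mrna_ids))]).statistic)
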