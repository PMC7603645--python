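"""Fractional-expression specificity scores over tissues and ages.

For gene *i*, the tissue fraction at a fixed age is T_ij / sum_j T_ij
where T_ij is the gene's mean linear FPKM in tissue *j*; the gene's
tissue-specificity score is its highest fraction (1 = exclusive to one
tissue, 1/k = uniform over k tissues). The age fraction within a fixed
tissue is defined the same way over the five age points, with the standard
deviation of the five fractions reported as a variability measure.

Fractions are computed on linear-scale FPKM replicate means: log-scale
values can be negative and would break the sum-to-one normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .expression import ExpressionMatrix


def fractional_profile(expr: ExpressionMatrix, meta: pd.DataFrame, axis: str,
                       fixed_level) -> pd.DataFrame:
    """Fractional expression of every detectable gene along one axis.

    axis="tissue": fractions over tissues at the fixed age point.
    axis="age": fractions over age points within the fixed tissue.

    Returns a DataFrame indexed by gene_id with one fraction column per
    category, plus ``score`` (max fraction) and, on the age axis,
    ``sd_fractions``. Genes with zero total expression are excluded.
    """
    if axis == "tissue":
        sub = meta[meta["age_weeks"] == fixed_level]
        group_col = "tissue"
        if sub.empty:
            raise AnalysisError(f"no samples at age {fixed_level} weeks")
    elif axis == "age":
        sub = meta[meta["tissue"] == fixed_level]
        group_col = "age_weeks"
        if sub.empty:
            raise AnalysisError(f"no samples for tissue {fixed_level!r}")
    else:
        raise AnalysisError(f"axis must be 'tissue' or 'age', got {axis!r}")
    detectable = expr.detectable[expr.detectable].index
    fpkm = expr.fpkm.loc[detectable]
    categories = sorted(sub[group_col].unique())
    means = pd.DataFrame({
        c: fpkm[sub.loc[sub[group_col] == c, "sample_id"]].mean(axis=1)
        for c in categories
    })
    total = means.sum(axis=1)
    kept = total > 0
    fractions = means.loc[kept].div(total[kept], axis=0)
    out = fractions.copy()
    out.columns = [str(c) for c in categories]
    out["score"] = fractions.max(axis=1)
    if axis == "age":
        out["sd_fractions"] = fractions.std(axis=1, ddof=1)
    out.index.name = "gene_id"
    return out


def classify_specific(score_groups: dict[str, pd.Series],
                      thresholds: tuple[float, ...] = (0.25, 0.3, 0.35, 0.4,
                                                       0.45, 0.5)) -> pd.DataFrame:
    """Percent of each gene group whose specificity score exceeds each
    threshold (strict >).

    ``score_groups`` maps a group label (e.g. "AR-lncRNA", "ANR-lncRNA") to
    a Series of scores. Returns (group, threshold, n_specific, percent).
    """
    rows = []
    for group in sorted(score_groups):
        scores = score_groups[group]
        if len(scores) == 0:
            raise AnalysisError(f"empty gene group {group!r}")
        for thr in thresholds:
            n = int((scores > thr).sum())
            rows.append((group, thr, n, 100.0 * n / len(scores)))
    return pd.DataFrame(rows, columns=["group", "threshold", "n_specific", "percent"])


def quantile_groups(scores: pd.Series, top_frac: float = 0.2,
                    bottom_frac: float = 0.2) -> tuple[set[str], set[str]]:
    """Top- and bottom-quantile gene sets by specificity score.

    Genes are ranked by score descending with ties broken by gene id
    (ascending), so set sizes are exactly floor(frac * n) and runs are
    reproducible. Returns (specific_set, control_set).
    """
    if top_frac + bottom_frac > 1.0:
        raise AnalysisError("overlapping quantiles: top_frac + bottom_frac > 1")
    n = len(scores)
    if n < 5:
        raise AnalysisError("need >= 5 genes for quantile grouping")
    order = scores.to_frame("score").reset_index()
    order.columns = ["gene_id", "score"]
    order = order.sort_values(["score", "gene_id"], ascending=[False, True])
    n_top, n_bot = int(np.floor(top_frac * n)), int(np.floor(bottom_frac * n))
    specific = set(order["gene_id"].iloc[:n_top])
    control = set(order["gene_id"].iloc[n - n_bot:]) if n_bot else set()
    return specific, control


@dataclass
class RegulationShift:
    """Old/young fold-change comparison of tissue-specific vs control genes."""

    ecdf_specific: pd.DataFrame  # columns: value, ecdf (over |log2FC|)
    ecdf_control: pd.DataFrame
    mannwhitney_p: float
    mannwhitney_p_signed: float
    ar_rate_specific: float  # percent of the specific group that is AR
    ar_rate_control: float


def _ecdf_frame(values: np.ndarray) -> pd.DataFrame:
    x = np.sort(values)
    return pd.DataFrame({"value": x, "ecdf": np.arange(1, x.size + 1) / x.size})


def regulation_shift(fold_changes: pd.Series, specific: set[str], control: set[str],
                     ar_members: set[str]) -> RegulationShift:
    """Compare aging regulation between tissue-specific and control genes.

    ``fold_changes`` maps gene_id -> signed log2FC(old/young). Produces
    ECDFs over |log2FC|, two-sided Mann-Whitney p-values on |log2FC| and on
    the signed values, and the percentage of each group present in
    ``ar_members``.
    """
    if not specific or not control:
        raise AnalysisError("both groups must be non-empty")
    missing = (specific | control) - set(fold_changes.index)
    if missing:
        raise AnalysisError(f"fold changes missing for: {sorted(missing)[:10]}")
    fc_s = fold_changes.loc[sorted(specific)].to_numpy(dtype=float)
    fc_c = fold_changes.loc[sorted(control)].to_numpy(dtype=float)
    p_abs = float(stats.mannwhitneyu(np.abs(fc_s), np.abs(fc_c),
                                     alternative="two-sided").pvalue)
    p_signed = float(stats.mannwhitneyu(fc_s, fc_c, alternative="two-sided").pvalue)
    return RegulationShift(
        ecdf_specific=_ecdf_frame(np.abs(fc_s)),
        ecdf_control=_ecdf_frame(np.abs(fc_c)),
        mannwhitney_p=p_abs,
        mannwhitney_p_signed=p_signed,
        ar_rate_specific=100.0 * len(specific & ar_members) / len(specific),
        ar_rate_control=100.0 * len(control & ar_members) / len(control),
    )
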