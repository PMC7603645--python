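"""Count normalization: TMM factors, FPKM, log2 transform, detectability.

TMM (trimmed mean of M-values) follows the Robinson-Oshlack procedure as
implemented in edgeR: the reference sample is the one whose upper quartile
of counts-per-million is closest to the mean upper quartile; per sample, a
doubly trimmed (30% on M, 5% on A), inverse-variance-weighted mean of
log-ratios against the reference gives the factor; factors are rescaled to
geometric mean 1.

FPKM[g, s] = count[g, s] / (length_kb[g] * effective_library_millions[s])
with effective library = library size * TMM factor. A gene is detectable
when FPKM exceeds ``min_fpkm`` (strictly) in at least
ceil(min_sample_frac * n_samples) samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, InputError


@dataclass
class ExpressionMatrix:
    """Normalized expression for one sample set.

    Attributes
    ----------
    log2 : DataFrame, detectable genes x samples, log2(FPKM + pseudocount).
    fpkm : DataFrame, all genes x samples, linear FPKM.
    detectable : boolean Series over all genes.
    tmm_factors : per-sample normalization factors (geometric mean 1).
    pseudocount : offset used in the log transform.
    """

    log2: pd.DataFrame
    fpkm: pd.DataFrame
    detectable: pd.Series
    tmm_factors: pd.Series | None = None
    pseudocount: float = 1.0

    @property
    def genes(self) -> pd.Index:
        return self.log2.index

    @property
    def samples(self) -> pd.Index:
        return self.log2.columns

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        f = None if self.tmm_factors is None else self.tmm_factors.loc[sample_ids]
        return ExpressionMatrix(self.log2[sample_ids], self.fpkm[sample_ids],
                                self.detectable, f, self.pseudocount)


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise InputError("empty count matrix")
    if (counts.to_numpy() < 0).any():
        raise InputError("count matrix contains negative entries")
    if counts.index.has_duplicates or counts.columns.has_duplicates:
        raise InputError("duplicate gene or sample ids in count matrix")


def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
                     trim_m: float, trim_a: float) -> float:
    """TMM factor of one sample against the reference (edgeR's trimmed,
    weighted mean of M-values)."""
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep] / lib_obs, ref[keep] / lib_ref
    if o.size == 0:
        return 1.0
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # delta-method asymptotic variance of M
    w = (lib_obs - obs[keep]) / (lib_obs * obs[keep]) \
        + (lib_ref - ref[keep]) / (lib_ref * ref[keep])
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not sel.any() or not np.isfinite(w[sel]).all():
        return 1.0
    f = np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_normalization_factors(counts: pd.DataFrame, trim_m: float = 0.3,
                              trim_a: float = 0.05) -> pd.Series:
    """Per-sample TMM normalization factors, rescaled to geometric mean 1.

    Raises on a single-sample matrix or an all-zero sample (named).
    """
    _check_counts(counts)
    if counts.shape[1] < 2:
        raise AnalysisError("TMM needs at least two samples")
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise AnalysisError(f"all-zero sample(s): {list(counts.columns[zero])}")
    f75 = np.quantile(x / lib, 0.75, axis=0)
    ref_j = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = x[:, ref_j]
    factors = np.array([
        1.0 if j == ref_j else
        _tmm_pair_factor(x[:, j], ref, lib[j], lib[ref_j], trim_m, trim_a)
        for j in range(x.shape[1])
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def compute_fpkm(counts: pd.DataFrame, gene_lengths_bp: pd.Series,
                 factors: pd.Series | None = None) -> pd.DataFrame:
    """FPKM matrix from counts, gene lengths (bp) and optional TMM factors."""
    _check_counts(counts)
    missing = counts.index.difference(gene_lengths_bp.index)
    if len(missing):
        raise InputError(f"missing gene lengths for: {list(missing[:10])}")
    lengths = gene_lengths_bp.loc[counts.index].astype(float)
    if (lengths <= 0).any():
        bad = list(lengths.index[lengths <= 0][:10])
        raise InputError(f"non-positive gene length for: {bad}")
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors.loc[counts.columns]
    if (lib <= 0).any():
        raise AnalysisError(f"non-positive effective library: "
                            f"{list(lib.index[lib <= 0])}")
    fpkm = counts.div(lengths / 1e3, axis=0).div(lib / 1e6, axis=1)
    return fpkm


def filter_detectable(fpkm: pd.DataFrame, min_fpkm: float = 0.5,
                      min_sample_frac: float = 0.2, pseudocount: float = 1.0,
                      tmm_factors: pd.Series | None = None) -> ExpressionMatrix:
    """Apply the detectability rule and the log2 transform.

    A gene is kept iff FPKM > ``min_fpkm`` (strict) in at least
    ceil(``min_sample_frac`` * n_samples) samples. ``log2`` holds
    log2(FPKM + pseudocount) for kept genes only.
    """
    if fpkm.shape[0] == 0 or fpkm.shape[1] == 0:
        raise InputError("empty FPKM matrix")
    if (fpkm.to_numpy() < 0).any():
        raise InputError("FPKM matrix contains negative values")
    if pseudocount <= 0:
        raise InputError("pseudocount must be positive")
    need = math.ceil(min_sample_frac * fpkm.shape[1])
    hits = (fpkm > min_fpkm).sum(axis=1)
    detectable = hits >= need
    log2 = np.log2(fpkm.loc[detectable] + pseudocount)
    return ExpressionMatrix(log2=log2, fpkm=fpkm, detectable=detectable,
                            tmm_factors=tmm_factors, pseudocount=pseudocount)


def normalize_study(counts: pd.DataFrame, gene_lengths_bp: pd.Series,
                    min_fpkm: float = 0.5, min_sample_frac: float = 0.2,
                    pseudocount: float = 1.0, trim_m: float = 0.3,
                    trim_a: float = 0.05) -> ExpressionMatrix:
    """TMM -> FPKM -> detectability filter -> log2, in one call."""
    factors = tmm_normalization_factors(counts, trim_m=trim_m, trim_a=trim_a)
    fpkm = compute_fpkm(counts, gene_lengths_bp, factors)
    return filter_detectable(fpkm, min_fpkm=min_fpkm,
                             min_sample_frac=min_sample_frac,
                             pseudocount=pseudocount, tmm_factors=factors)
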