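"""Validated input loading and TSV output helpers."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

VALID_BIOTYPES = ("lncRNA", "mRNA")
SAMPLE_COLUMNS = ("sample_id", "tissue", "age_weeks", "replicate")
GENE_COLUMNS = ("gene_id", "biotype", "length_bp", "n_exons", "n_isoforms")


def _require_columns(frame: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise InputError(f"{what} is missing columns: {missing}")


def read_counts(path) -> pd.DataFrame:
    """Read a gene x sample count TSV (first column = gene_id)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"counts file not found: {path}")
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index.name = "gene_id"
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise InputError("counts must be numeric")
    if (values < 0).any():
        raise InputError("counts contain negative entries")
    if np.any(values != np.floor(values)):
        raise InputError("counts must be integers")
    return counts.astype(np.int64)


def read_counts_mtx(mtx_path, rows_path, cols_path) -> pd.DataFrame:
    """Read a MatrixMarket triplet + row/col name files."""
    from scipy import io as spio
    mat = spio.mmread(str(mtx_path)).toarray()
    rows = Path(rows_path).read_text().split()
    cols = Path(cols_path).read_text().split()
    counts = pd.DataFrame(mat, index=pd.Index(rows, name="gene_id"), columns=cols)
    if (counts.to_numpy() < 0).any():
        raise InputError("counts contain negative entries")
    return counts.astype(np.int64)


def load_inputs(counts_path, samples_path, genes_path, lenient: bool = True):
    """Load and cross-validate counts, sample metadata and gene annotation.

    Every count column must have a metadata row and every count row an
    annotation row. Genes with a biotype outside {lncRNA, mRNA} are dropped
    with a warning under lenient mode, rejected otherwise.

    Returns (counts, samples, genes, report) where report lists dropped /
    unknown records.
    """
    counts = read_counts(counts_path)
    samples = pd.read_csv(samples_path, sep="\t")
    genes = pd.read_csv(genes_path, sep="\t")
    _require_columns(samples, SAMPLE_COLUMNS, "sample table")
    _require_columns(genes, GENE_COLUMNS, "gene table")
    if samples["sample_id"].duplicated().any():
        raise InputError("duplicate sample ids in metadata")
    if genes["gene_id"].duplicated().any():
        raise InputError("duplicate gene ids in annotation")

    report: dict[str, list[str]] = {"dropped_genes": [], "warnings": []}
    orphan_samples = [s for s in counts.columns if s not in set(samples["sample_id"])]
    if orphan_samples:
        raise InputError(f"count columns without metadata: {orphan_samples[:10]}")
    orphan_genes = [g for g in counts.index if g not in set(genes["gene_id"])]
    if orphan_genes:
        raise InputError(f"count rows without annotation: {orphan_genes[:10]}")

    bad_bt = genes[~genes["biotype"].isin(VALID_BIOTYPES)]
    if len(bad_bt):
        if not lenient:
            raise InputError(f"unknown biotypes: "
                             f"{sorted(bad_bt['biotype'].unique())}")
        report["dropped_genes"] = list(bad_bt["gene_id"])
        report["warnings"].append(
            f"dropped {len(bad_bt)} gene(s) with unknown biotype "
            f"{sorted(bad_bt['biotype'].unique())}")
        genes = genes[genes["biotype"].isin(VALID_BIOTYPES)].reset_index(drop=True)
        counts = counts.loc[counts.index.isin(set(genes["gene_id"]))]
    if (genes["length_bp"] <= 0).any():
        raise InputError("gene annotation contains non-positive lengths")
    samples = samples[samples["sample_id"].isin(counts.columns)].reset_index(drop=True)
    samples["age_weeks"] = samples["age_weeks"].astype(int)
    return counts, samples, genes, report


def write_tsv(frame: pd.DataFrame, path, thresholds: dict | None = None,
              index: bool = False) -> Path:
    """Write a result table, prefixed by a header comment line declaring
    the thresholds that generated it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if thresholds:
            items = " ".join(f"{k}={v}" for k, v in sorted(thresholds.items()))
            fh.write(f"# lncage thresholds: {items}\n")
        frame.to_csv(fh, sep="\t", index=index)
    return path


def read_result_tsv(path) -> pd.DataFrame:
    """Read a table written by :func:`write_tsv` (skips the comment line)."""
    return pd.read_csv(path, sep="\t", comment="#")
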