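"""Local gene-set enrichment: GMT parsing, hypergeometric tests, BH FDR.

A drop-in replacement for web-service enrichment: terms from a GMT
collection are tested against a query set over an explicit background
(typically the detectable genes of a tissue) with the hypergeometric upper
tail. Terms are restricted to 10..400 background members, results are
reported for overlaps >= 5, and significance is BH FDR < 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError, InputError


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise AnalysisError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GeneSetCollection:
    """A named collection of gene sets (term id -> members)."""

    terms: dict[str, set[str]]
    names: dict[str, str]

    def __len__(self) -> int:
        return len(self.terms)


def read_gmt(path) -> GeneSetCollection:
    """Parse a tab-separated GMT file (term, description, members...)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"GMT file not found: {path}")
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            term, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise InputError(f"{path}:{lineno}: term {term!r} has no members")
            if term in terms:
                raise InputError(f"{path}:{lineno}: duplicate term id {term!r}")
            terms[term] = set(members)
            names[term] = desc
    if not terms:
        raise InputError(f"empty GMT file: {path}")
    return GeneSetCollection(terms=terms, names=names)


def hypergeom_enrichment_p(overlap: int, query: int, term: int, background: int,
                           ease: bool = False) -> float:
    """Upper-tail hypergeometric P(X >= overlap).

    With ``ease`` the overlap is decremented by one before testing (the
    conservative EASE variant of the Fisher score).
    """
    k = overlap - 1 if ease else overlap
    return float(stats.hypergeom.sf(k - 1, background, term, query))


def enrich(query: set[str], background: set[str], collection: GeneSetCollection,
           min_term: int = 10, max_term: int = 400, min_query: int = 5,
           fdr_max: float = 0.1, ease: bool = False) -> pd.DataFrame:
    """Hypergeometric enrichment of ``query`` against ``background``.

    Term membership is intersected with the background; terms with
    background size outside [min_term, max_term] are skipped; a term is
    reported only when its overlap with the query is >= ``min_query``.
    BH adjustment spans the reported terms; ``significant`` is q < fdr_max.

    Returns a DataFrame sorted by p: (term, name, overlap, query_size,
    term_size, background_size, p, q, significant).
    """
    stray = query - background
    if stray:
        raise AnalysisError(f"query genes missing from background: "
                            f"{sorted(stray)[:10]}")
    n_bg, n_q = len(background), len(query)
    rows = []
    for term_id in sorted(collection.terms):
        members = collection.terms[term_id] & background
        if not (min_term <= len(members) <= max_term):
            continue
        overlap = len(members & query)
        if overlap < min_query:
            continue
        p = hypergeom_enrichment_p(overlap, n_q, len(members), n_bg, ease=ease)
        rows.append((term_id, collection.names.get(term_id, ""), overlap,
                     n_q, len(members), n_bg, p))
    out = pd.DataFrame(rows, columns=["term", "name", "overlap", "query_size",
                                      "term_size", "background_size", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["significant"] = out["q"] < fdr_max if len(out) else []
    return out.sort_values(["p", "term"]).reset_index(drop=True)


def recurrent_terms(per_tissue: dict[str, pd.DataFrame],
                    min_tissues: int = 2) -> pd.DataFrame:
    """Terms significantly enriched in at least ``min_tissues`` tissues.

    ``per_tissue`` maps tissue -> enrichment table (as from :func:`enrich`).
    Returns (term, name, n_tissues, tissues) sorted by recurrence.
    """
    if len(per_tissue) < 2:
        raise AnalysisError("need >= 2 tissues for recurrence analysis")
    hits: dict[str, list[str]] = {}
    names: dict[str, str] = {}
    for tissue in sorted(per_tissue):
        table = per_tissue[tissue]
        sig = table[table["significant"]] if len(table) else table
        for r in sig.itertuples(index=False):
            hits.setdefault(r.term, []).append(tissue)
            names[r.term] = r.name
    rows = [(t, names[t], len(ts), ",".join(ts)) for t, ts in hits.items()
            if len(ts) >= min_tissues]
    out = pd.DataFrame(rows, columns=["term", "name", "n_tissues", "tissues"])
    return out.sort_values(["n_tissues", "term"],
                           ascending=[False, True]).reset_index(drop=True)
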