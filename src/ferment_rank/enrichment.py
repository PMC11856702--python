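"""Overrepresentation (enrichment) analysis over gene → term annotations.

For a query gene set of size n drawn from a background universe of size N,
a term annotating K background genes and k query genes is scored by

* fold enrichment (k/n) / (K/N),
* the upper-tail hypergeometric p-value P(X ≥ k), X ~ Hypergeom(N, K, n),
* Benjamini–Hochberg step-up FDR across the tested terms.

Only overrepresentation (the upper tail) is reported. Terms with k = 0 are
excluded from the output and from the FDR family by default, mirroring how
overrepresentation-test web tools report results; pass
``include_zero_overlap=True`` to keep every term in the family.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class AnnotationTable:
    """Term → gene-set mapping over an explicit background universe."""

    terms: Mapping[str, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        terms = {str(t): frozenset(g) for t, g in self.terms.items()}
        background = frozenset(self.background)
        empty = [t for t, g in terms.items() if not g]
        if empty:
            raise ValueError(f"term(s) with no annotated genes: {empty}")
        stray = {t: g - background for t, g in terms.items() if g - background}
        if stray:
            raise ValueError(
                f"annotated gene(s) outside the background universe: "
                f"{ {t: sorted(g) for t, g in stray.items()} }"
            )
        object.__setattr__(self, "terms", terms)
        object.__setattr__(self, "background", background)

    @property
    def n_background(self) -> int:
        return len(self.background)


def read_annotation_table(
    path: str | Path, background: Iterable[str] | None = None
) -> AnnotationTable:
    """Read a two-column TSV (gene, term). The background defaults to the
    union of all annotated genes; pass an explicit universe to widen it."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], dtype=str, comment="#")
    terms: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"], df["term"]):
        terms.setdefault(term, set()).add(gene)
    bg = set(df["gene"]) if background is None else set(background) | set(df["gene"])
    return AnnotationTable(terms={t: frozenset(g) for t, g in terms.items()}, background=frozenset(bg))


def _check_counts(k: int, n: int, K: int, N: int) -> None:
    if min(k, n, K, N) < 0:
        raise ValueError("counts must be non-negative")
    if n == 0 or K == 0 or N == 0:
        raise ValueError("n, K and N must be positive")
    if k > min(n, K) or n > N or K > N:
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """(k/n) / (K/N): observed over expected query fraction for a term."""
    _check_counts(k, n, K, N)
    return (k / n) / (K / N)


def hypergeometric_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X ≥ k) for X ~ Hypergeometric(N, K, n), evaluated in
    log space for numerical stability at extreme counts."""
    _check_counts(k, n, K, N)
    if k == 0:
        return 1.0
    logp = stats.hypergeom.logsf(k - 1, N, K, n)
    return float(min(1.0, np.exp(logp)))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} m * p_(j) / j, clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def overrepresentation_test(
    query: Iterable[str],
    annot: AnnotationTable,
    include_zero_overlap: bool = False,
) -> pd.DataFrame:
    """One row per term with query overlap, sorted by ascending p-value.

    Query genes outside the background are reported via the DataFrame's
    ``attrs['n_dropped']`` and dropped. Columns: term, K, n, k,
    fold_enrichment, p_value, fdr.
    """
    query = set(query)
    dropped = query - annot.background
    query &= annot.background
    if not query:
        raise ValueError("query is empty after intersecting with the background universe")
    N = annot.n_background
    n = len(query)
    rows = []
    for term, genes in sorted(annot.terms.items()):
        K = len(genes)
        k = len(query & genes)
        if k == 0 and not include_zero_overlap:
            continue
        rows.append(
            {
                "term": term,
                "K": K,
                "n": n,
                "k": k,
                "fold_enrichment": fold_enrichment(k, n, K, N) if k else 0.0,
                "p_value": hypergeometric_pvalue(k, n, K, N),
            }
        )
    df = pd.DataFrame(rows, columns=["term", "K", "n", "k", "fold_enrichment", "p_value"])
    if len(df):
        df["fdr"] = bh_fdr(df["p_value"].to_numpy())
        df = df.sort_values(["p_value", "term"], kind="stable").reset_index(drop=True)
    else:
        df["fdr"] = pd.Series(dtype=float)
    df.attrs["n_dropped"] = len(dropped)
    df.attrs["N"] = N
    return df
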