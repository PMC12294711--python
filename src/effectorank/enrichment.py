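"""Hypergeometric over-representation analysis of a gene set against a library.

For a universe of ``N`` genes of which ``K`` belong to a term, and a
query of ``n`` genes of which ``k`` hit the term, the enrichment
p-value is the upper tail ``P(X >= k)`` of the hypergeometric
distribution — the probability of observing k or more term genes in the
query by chance.  P-values are corrected per library with Bonferroni
and Benjamini-Hochberg, and records are ranked by ascending p
(equivalently descending -log10 p).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from effectorank.geneset_io import GeneSet, GeneSetLibrary, ValidationError

_TINY = np.finfo(float).tiny


@dataclass
class EnrichmentRecord:
    """One term's hypergeometric test and corrected p-values."""

    term: str
    N: int
    K: int
    n: int
    k: int
    p: float
    p_bonferroni: float
    p_bh: float
    neglog10_p: float
    overlap_genes: tuple[str, ...] = ()


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability ``P(X >= k)``.

    Computed with the survival function at ``k - 1`` for numerical
    stability; the result is clamped into ``(0, 1]``.
    """
    for label, value in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(value) != value or value < 0:
            raise ValidationError(f"{label} must be a non-negative integer, got {value}")
    if K > N or n > N:
        raise ValidationError(f"require K <= N and n <= N, got N={N}, K={K}, n={n}")
    if k > min(K, n):
        raise ValidationError(f"k={k} exceeds min(K, n)={min(K, n)}")
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(1.0, max(p, _TINY))


def adjust_pvalues(
    ps: Sequence[float], method: Literal["bonferroni", "bh"]
) -> list[float]:
    """Multiple-testing correction: Bonferroni or Benjamini-Hochberg step-up.

    Output preserves input order; values are capped at 1.  BH adjusted
    values are monotone in the raw-p ranking.
    """
    if len(ps) == 0:
        return []
    arr = np.asarray(ps, dtype=float)
    if np.any(arr <= 0) or np.any(arr > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    if method == "bonferroni":
        return list(np.minimum(1.0, arr * len(arr)))
    if method == "bh":
        return list(multipletests(arr, method="fdr_bh")[1])
    raise ValidationError(f"unknown correction method {method!r}")


def enrich_library(
    query: GeneSet,
    library: GeneSetLibrary,
    universe_size: int | None = None,
) -> list[EnrichmentRecord]:
    """Test every library term for over-representation in the query.

    Universe precedence: explicit argument, then the library's
    ``universe_size`` field.  Records are sorted by ascending p with
    ties broken by descending k then term identifier.
    """
    if len(query) == 0:
        raise ValidationError("query gene set is empty")
    if len(library) == 0:
        raise ValidationError(f"library {library.name!r} has no terms")
    N = universe_size if universe_size is not None else library.universe_size
    n = len(query)
    if n > N:
        raise ValidationError(f"query size {n} exceeds universe size {N}")
    raw: list[tuple[str, int, int, tuple[str, ...]]] = []
    for term, members in library.terms.items():
        overlap = tuple(sorted(query.genes & members.genes))
        raw.append((term, len(members), len(overlap), overlap))
    if all(k == 0 for _, _, k, _ in raw):
        warnings.warn(
            f"query {query.name!r} shares no genes with library {library.name!r}"
        )
    ps = [hypergeom_pvalue(N, K, n, k) for _, K, k, _ in raw]
    bonf = adjust_pvalues(ps, "bonferroni")
    bh = adjust_pvalues(ps, "bh")
    records = [
        EnrichmentRecord(
            term=term,
            N=N,
            K=K,
            n=n,
            k=k,
            p=p,
            p_bonferroni=pb,
            p_bh=pq,
            neglog10_p=-math.log10(p),
            overlap_genes=overlap,
        )
        for (term, K, k, overlap), p, pb, pq in zip(raw, ps, bonf, bh)
    ]
    records.sort(key=lambda r: (r.p, -r.k, r.term))
    return records
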