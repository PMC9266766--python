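"""Hypergeometric overlap enrichment and FDR-corrected term enrichment.

The core statistic is the one-sided upper-tail hypergeometric test: drawing
``n`` genes from a universe of ``N`` that contains ``K`` marked genes, the
p-value is ``P(X >= k)`` for the observed overlap ``k``.  The tail sum is
evaluated entirely in log-space through log-gamma, so p-values far below
float underflow (overlaps of strongly enriched disease modules easily reach
p < 1e-300) are still reported exactly on the ``log10_p`` scale.

``term_enrichment`` applies the same test per annotation term, optionally
with the conservative EASE variant (tail computed at ``k - 1``), and adjusts
across terms with Benjamini–Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .model import (
    GeneNetwork,
    NetworkValidationError,
    TermAnnotationMap,
    normalize_symbol,
    project_simple,
)

__all__ = [
    "EnrichmentResult",
    "TermEnrichmentRecord",
    "log_hypergeom_sf",
    "hypergeom_overlap_p",
    "interactor_enrichment",
    "benjamini_hochberg",
    "term_enrichment",
]

_LOG10_E = np.log10(np.e)


@dataclass(frozen=True, slots=True)
class EnrichmentResult:
    """One-sided hypergeometric overlap test result.

    ``p_value`` is the linear-scale tail probability (may underflow to 0.0
    for extreme overlaps); ``log10_p`` is always finite and is the reporting
    scale of choice for tiny p.
    """

    universe_size: int
    category_size: int
    sample_size: int
    overlap: int
    p_value: float
    log10_p: float


@dataclass(frozen=True, slots=True)
class TermEnrichmentRecord:
    term: str
    category_size: int
    sample_size: int
    overlap: int
    p_value: float
    q_value: float
    significant: bool


def _validate_counts(N: int, K: int, n: int, k: int) -> None:
    for label, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(v) != v or v < 0:
            raise NetworkValidationError(f"{label} must be a non-negative integer, got {v}")
    if K > N:
        raise NetworkValidationError(f"K ({K}) exceeds universe N ({N})")
    if n > N:
        raise NetworkValidationError(f"n ({n}) exceeds universe N ({N})")
    if k > min(K, n):
        raise NetworkValidationError(f"k ({k}) exceeds min(K, n) = {min(K, n)}")


def _log_binom(a: int, b) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def log_hypergeom_sf(N: int, K: int, n: int, k: int) -> float:
    """Natural-log of ``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``.

    The support sum runs from ``k`` to ``min(K, n)``; ``k = 0`` returns
    ``log(1) = 0`` exactly.  Evaluated via log-gamma and logsumexp, finite
    for every valid input.
    """
    _validate_counts(N, K, n, k)
    if k == 0:
        return 0.0
    top = min(K, n)
    j = np.arange(k, top + 1)
    log_terms = _log_binom(K, j) + _log_binom(N - K, n - j) - _log_binom(N, n)
    return float(min(logsumexp(log_terms), 0.0))


def hypergeom_overlap_p(N: int, K: int, n: int, k: int) -> EnrichmentResult:
    """One-sided overlap test: probability of ``>= k`` shared genes."""
    log_p = log_hypergeom_sf(N, K, n, k)
    return EnrichmentResult(
        universe_size=N,
        category_size=K,
        sample_size=n,
        overlap=k,
        p_value=float(np.exp(log_p)),
        log10_p=log_p * _LOG10_E,
    )


def interactor_enrichment(
    disease: GeneNetwork,
    target: str,
    global_g: GeneNetwork,
    universe_size: int | str = "from_global",
) -> EnrichmentResult:
    """Is the disease network enriched with direct interactors of ``target``?

    ``K`` is the neighbor count of ``target`` in the global simple
    projection, ``n`` the disease node count excluding the target itself,
    ``k`` their overlap, and ``N`` either an explicit universe size or the
    global network's node count.  Reconstructed-interactome universes are
    rarely published, so ``universe_size`` should be set explicitly whenever
    it is known.
    """
    tgt = normalize_symbol(target)
    if tgt not in global_g.nodes:
        raise NetworkValidationError(f"target {tgt} absent from global network")
    interactors = project_simple(global_g).neighbors(tgt)
    disease_nodes = disease.nodes - {tgt}
    K = len(interactors)
    n = len(disease_nodes)
    k = len(interactors & disease_nodes)
    if universe_size == "from_global":
        N = global_g.n_nodes
    else:
        N = int(universe_size)
        if N < max(K, n):
            raise NetworkValidationError(
                f"universe ({N}) smaller than max(K={K}, n={n})"
            )
    return hypergeom_overlap_p(N, K, n, k)


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    Returned in the input order; monotone non-decreasing when the inputs are
    sorted ascending, and invariant under duplicate insertion.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise NetworkValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q.tolist()


def term_enrichment(
    genes: Iterable[str],
    annot: TermAnnotationMap,
    method: str = "hypergeometric",
    fdr_threshold: float = 0.05,
) -> list[TermEnrichmentRecord]:
    """Per-term overlap enrichment of a query gene set with BH correction.

    ``method="ease"`` computes the tail at ``k - 1`` (floored at 0), the
    conservative variant used by DAVID-style tools; the default is the plain
    hypergeometric.  Records are returned sorted by (q, p, term).
    """
    if method not in ("hypergeometric", "ease"):
        raise ValueError(f"unknown method {method!r}")
    query = frozenset(normalize_symbol(g) for g in genes)
    stray = query - annot.universe
    if stray:
        raise NetworkValidationError(
            f"query genes outside annotation universe: {sorted(stray)}"
        )
    if not annot.terms:
        raise NetworkValidationError("annotation map has no terms")
    N = len(annot.universe)
    n = len(query)
    rows = []
    for term in sorted(annot.terms):
        term_genes = annot.terms[term]
        K = len(term_genes)
        k = len(term_genes & query)
        k_eff = max(k - 1, 0) if method == "ease" else k
        log_p = log_hypergeom_sf(N, K, n, k_eff)
        rows.append((term, K, k, float(np.exp(log_p))))
    q_values = benjamini_hochberg([r[3] for r in rows])
    records = [
        TermEnrichmentRecord(
            term=term,
            category_size=K,
            sample_size=n,
            overlap=k,
            p_value=p,
            q_value=q,
            significant=q < fdr_threshold,
        )
        for (term, K, k, p), q in zip(rows, q_values)
    ]
    records.sort(key=lambda r: (r.q_value, r.p_value, r.term))
    return records
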