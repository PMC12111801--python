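"""Pathway over-representation: hypergeometric test, BH-FDR and strength.

Given a selected gene set and pathway annotations (GMT), each pathway is
tested for over-representation with the one-sided (upper tail) hypergeometric
test, p-values are corrected with Benjamini-Hochberg, and the effect size is
reported as the enrichment strength log10(observed/expected) together with the
discovery rate -log10(p) for volcano-style plots.

The upper-tail probability is evaluated in log space (log-binomials via
``gammaln`` combined with ``logsumexp``) so that tiny tail probabilities for
large universes do not underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests


class InvalidCountsError(ValueError):
    pass


@dataclass(frozen=True)
class PathwayAnnotation:
    pathway_id: str
    pathway_name: str
    genes: frozenset[str]


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    pathway_name: str
    k: int  # selected genes in the pathway
    K: int  # pathway size (within the universe)
    n: int  # selected-set size
    N: int  # universe size
    p_value: float
    fdr: float
    strength: float | None  # log10(observed/expected); None when k == 0
    discovery_rate: float  # -log10(p)
    significant: bool


def _log_comb(a: float, b: np.ndarray) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def _validate(k: int, K: int, n: int, N: int) -> None:
    ints = all(int(x) == x for x in (k, K, n, N))
    if not ints or k < 0 or K < 0 or n < 0 or N < 1:
        raise InvalidCountsError(f"invalid counts k={k} K={K} n={n} N={N}")
    if K > N or n > N or k > min(K, n):
        raise InvalidCountsError(f"inconsistent counts k={k} K={K} n={n} N={N}")


def hypergeometric_pvalue(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), upper tail, log-space.

    ``k`` successes among ``n`` draws from a universe of ``N`` containing
    ``K`` marked elements.
    """
    _validate(k, K, n, N)
    if k == 0:
        return 1.0
    hi = min(K, n)
    lo = max(k, n - (N - K))  # support lower bound: n - x cannot exceed N - K
    xs = np.arange(lo, hi + 1)
    if xs.size == 0:
        return 0.0
    log_terms = _log_comb(K, xs) + _log_comb(N - K, n - xs) - _log_comb(N, np.array([n]))
    return float(min(1.0, math.exp(logsumexp(log_terms))))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = list(p_values)
    if not p:
        return []
    if any(x < 0 or x > 1 for x in p):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def enrichment_strength(k: int, K: int, n: int, N: int) -> float | None:
    """log10(observed/expected); ``None`` when nothing was observed."""
    _validate(k, K, n, N)
    expected = n * K / N
    if expected == 0:
        raise InvalidCountsError("expected count is zero")
    if k == 0:
        return None
    return math.log10(k / expected)


def run_enrichment(
    selected: Iterable[str],
    annotation: Sequence[PathwayAnnotation],
    universe: Iterable[str] | None = None,
    alpha: float = 0.05,
    filter_on: str = "fdr",
) -> list[EnrichmentResult]:
    """Test every pathway for over-representation of ``selected``.

    The universe defaults to the union of all annotated genes. Results are
    sorted by ascending p (ties broken by pathway_id); ``significant`` flags
    ``fdr <= alpha`` (or raw ``p <= alpha`` with ``filter_on="p"``).
    """
    if filter_on not in ("fdr", "p"):
        raise ValueError(f"filter_on must be 'fdr' or 'p', got {filter_on!r}")
    sel = set(selected)
    if universe is None:
        uni: set[str] = set()
        for ann in annotation:
            uni |= ann.genes
    else:
        uni = set(universe)
    stray = sel - uni
    if stray:
        raise ValueError(f"selected genes outside the universe: {sorted(stray)}")
    n, N = len(sel), len(uni)
    rows = []
    for ann in sorted(annotation, key=lambda a: a.pathway_id):
        genes = ann.genes & uni
        K = len(genes)
        k = len(sel & genes)
        p = hypergeometric_pvalue(k, K, n, N) if K else 1.0
        strength = enrichment_strength(k, K, n, N) if K and n else None
        rows.append((ann, k, K, p, strength))
    fdrs = bh_fdr([r[3] for r in rows])
    results = [
        EnrichmentResult(
            pathway_id=ann.pathway_id,
            pathway_name=ann.pathway_name,
            k=k,
            K=K,
            n=n,
            N=N,
            p_value=p,
            fdr=q,
            strength=strength,
            discovery_rate=-math.log10(p) if p > 0 else math.inf,
            significant=(q if filter_on == "fdr" else p) <= alpha,
        )
        for (ann, k, K, p, strength), q in zip(rows, fdrs)
    ]
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    return results
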