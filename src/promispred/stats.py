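"""Significance tests for prediction/experiment overlap and reciprocity.

The overlap of a predicted replacer set with an experimentally determined
multicopy-suppression set is scored with an upper-tail hypergeometric test;
the chance that a collection of pairs is entirely reciprocal is scored with
a closed-form independence model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Set

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom


@dataclass(frozen=True)
class OverlapTest:
    """A hypergeometric draw: n predictions against K positives out of N."""

    population_size: int
    experimental_positives: int
    predictions: int
    overlap: int
    p_value: float


def hypergeometric_overlap_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Summed in log space for numerical safety far in the tail.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require K,n <= N; got N={N}, K={K}, n={n}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"require 0 <= k <= min(n,K); got k={k}")
    if k == 0:
        return 1.0
    support = np.arange(k, min(n, K) + 1)
    logp = hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def overlap_test(
    predicted: Set,
    experimental: Set,
    population_size: int,
) -> OverlapTest:
    """Overlap significance of two item sets drawn from one population.

    Items may be genes or (target, replacer) pairs; the caller fixes the
    unit and the corresponding population size.
    """
    k = len(predicted & experimental)
    p = hypergeometric_overlap_pvalue(
        population_size, len(experimental), len(predicted), k
    )
    return OverlapTest(
        population_size=population_size,
        experimental_positives=len(experimental),
        predictions=len(predicted),
        overlap=k,
        p_value=p,
    )


def reciprocal_fraction(pairs: Iterable) -> float:
    """Fraction of ordered (target, replacer) pairs whose reverse is present."""
    ordered = {(p.target_gene, p.replacer_gene) for p in pairs}
    if not ordered:
        return 0.0
    n_recip = sum(1 for (a, b) in ordered if (b, a) in ordered and a != b)
    return n_recip / len(ordered)


def reciprocity_pvalue(
    m: int,
    baseline_rate: Optional[float] = None,
    pairs: Optional[Iterable] = None,
) -> float:
    """P(all m independent pairs reciprocal) = r ** m.

    ``baseline_rate`` r is the per-pair reciprocity probability; when not
    supplied it is estimated as the reciprocal fraction of the full
    prediction set ``pairs``.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    if baseline_rate is None:
        if pairs is None:
            raise ValueError("supply baseline_rate or a prediction set")
        baseline_rate = reciprocal_fraction(pairs)
    if not 0.0 < baseline_rate <= 1.0:
        raise ValueError(f"baseline rate must be in (0,1], got {baseline_rate}")
    return float(baseline_rate ** m)
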