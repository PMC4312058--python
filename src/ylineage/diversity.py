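"""Diversity and variability statistics for haplogroups and Y-STR haplotypes.

All haplotype-level statistics operate on the analysis-locus allele vectors
(15 loci for the Yfiler panel). Conventions follow the standard
population-genetics estimators:

* haplotype/haplogroup diversity — Nei's unbiased gene diversity
  ``H = n/(n-1) (1 - sum p_i^2)`` with Nei's sampling variance;
* MPD — mean number of loci at which two haplotypes differ, over all
  ``n(n-1)/2`` pairs, with Tajima's total (sampling + stochastic) variance;
* Vp — intra-population variance: the across-loci mean of the per-locus
  sample variance (n-1 divisor) of repeat counts.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
from scipy import stats

from .types import STRHaplotype

__all__ = [
    "DiversityEstimate",
    "MPDEstimate",
    "VpEstimate",
    "haplotype_diversity",
    "mean_pairwise_difference",
    "intra_population_variance",
    "count_distinct_haplotypes",
    "fisher_exact_2x2",
    "analysis_matrix",
]


@dataclass(frozen=True)
class DiversityEstimate:
    n: int
    k: int
    value: float
    se: float


@dataclass(frozen=True)
class MPDEstimate:
    mean: float
    sd: float


@dataclass(frozen=True)
class VpEstimate:
    value: float


def analysis_matrix(haps: Sequence[STRHaplotype], loci: Sequence[str]) -> np.ndarray:
    """Stack haplotypes into an (n, L) float array of repeat counts.

    Raises if any haplotype is incomplete on ``loci``.
    """
    return np.array([[float(v) for v in h.vector(loci)] for h in haps], dtype=float)


def haplotype_diversity(items: Sequence[Hashable]) -> DiversityEstimate:
    """Nei's unbiased diversity of a list of discrete types.

    Types may be haplogroup labels or hashable haplotype objects. Equals 1
    exactly when all items are distinct.
    """
    n = len(items)
    if n < 2:
        raise ValueError("diversity needs at least two items")
    counts = np.array(list(Counter(items).values()), dtype=float)
    p = counts / n
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    h = n / (n - 1) * (1.0 - s2)
    # Nei (1987) eq. 8.12: sampling variance of the unbiased estimator
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (s3 - s2**2) + s2 - s2**2)
    return DiversityEstimate(n=n, k=len(counts), value=h, se=math.sqrt(max(var, 0.0)))


def mean_pairwise_difference(
    haps: Sequence[STRHaplotype], loci: Sequence[str]
) -> MPDEstimate:
    """Mean number of analysis loci at which two haplotypes differ.

    The ± term is Tajima's total variance for the mean pairwise difference,
    combining sampling and the stochastic variance of the coalescent:
    ``V = (3n(n+1) pi + 2(n^2+n+3) pi^2) / (11(n^2 - 7n + 6))``. The
    denominator vanishes for n <= 6, where the per-term form
    ``V = (n+1)/(3(n-1)) pi + 2(n^2+n+3)/(9n(n-1)) pi^2`` is used instead.
    """
    X = analysis_matrix(haps, loci)
    n = X.shape[0]
    if n < 2:
        raise ValueError("MPD needs at least two haplotypes")
    diff = (X[:, None, :] != X[None, :, :]).sum(axis=2)
    iu = np.triu_indices(n, k=1)
    pi = float(diff[iu].mean())
    if pi == 0.0:
        return MPDEstimate(mean=0.0, sd=0.0)
    if n > 6:
        var = (3 * n * (n + 1) * pi + 2 * (n**2 + n + 3) * pi**2) / (
            11 * (n**2 - 7 * n + 6)
        )
    else:
        var = (n + 1) / (3 * (n - 1)) * pi + 2 * (n**2 + n + 3) / (9 * n * (n - 1)) * pi**2
    return MPDEstimate(mean=pi, sd=math.sqrt(max(var, 0.0)))


def intra_population_variance(
    haps: Sequence[STRHaplotype], loci: Sequence[str]
) -> VpEstimate:
    """Across-loci mean of the per-locus sample variance of repeat counts."""
    X = analysis_matrix(haps, loci)
    if X.shape[0] < 2:
        raise ValueError("Vp needs at least two haplotypes")
    return VpEstimate(value=float(X.var(axis=0, ddof=1).mean()))


def count_distinct_haplotypes(
    haps: Sequence[STRHaplotype], loci: Sequence[str]
) -> int:
    """Number of distinct analysis-locus allele vectors."""
    return len({h.vector(loci) for h in haps})


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table.

    Sums hypergeometric probabilities of all tables (with the observed
    margins) at most as probable as the observed one. A zero margin gives
    p = 1 by convention.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("expected a 2x2 table of non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])
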