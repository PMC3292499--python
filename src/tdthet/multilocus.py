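"""Multi-locus sum statistic and correlated mating-type frequencies.

The per-locus heterogeneity LRT values are combined by their plain sum
(``SumStat``).  Its null distribution is obtained by summing, for each
permutation index, the per-locus permuted statistics — valid because the
permutation redraws all loci at the same index jointly under the null.  A
Bonferroni helper covers grouping loci by chromosome.

The simulation construction for correlated loci chains mating-type
frequency vectors: row 1 comes from HWE at the given allele frequency, and
each subsequent locus blends the previous row with uniform noise,
``Y[l][i] = rho * MT[l-1][i] + (1 - rho) * X_i``, then renormalizes.
``rho = 1`` copies the row exactly; ``rho = 0`` produces independent
normalized uniform rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genetic_model import hwe_mating_freqs
from .permutation import PermutationSet

__all__ = [
    "MultiLocusConfig",
    "sumstat",
    "sumstat_pvalue",
    "bonferroni_min_p",
    "correlated_mating_freqs",
]


@dataclass(frozen=True)
class MultiLocusConfig:
    """Layout of a correlated multi-locus simulation.

    ``n_loci`` markers share one linked/unlinked trio label; their
    mating-type frequency rows are chained with blending weight ``rho``.
    """

    n_loci: int = 4
    rho: float = 0.8
    shared_x: bool = False

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")


def sumstat(stats) -> float:
    """Arithmetic sum of per-locus statistics."""
    stats = np.asarray(stats, dtype=float)
    if stats.size < 1:
        raise ValueError("need at least one locus")
    return float(stats.sum())


def sumstat_pvalue(perms_by_locus: list[PermutationSet], observed: float | None = None) -> float:
    """Permutation p-value of the summed statistic.

    Per permutation index j, the null sum is ``sum_k stats_k[j]``; the
    p-value is the proportion of null sums >= the observed sum.  Requires
    index-aligned permutation sets of equal size.
    """
    sizes = {p.n_perms for p in perms_by_locus}
    if len(sizes) != 1:
        raise ValueError("all loci must have the same number of permutations")
    if observed is None:
        observed = sumstat([p.observed for p in perms_by_locus])
    null_sums = np.vstack([p.stats for p in perms_by_locus]).sum(axis=0)
    return float(np.mean(null_sums >= observed))


def bonferroni_min_p(pvalues, n_tests: int) -> float:
    """``min(1, n_tests * min(pvalues))``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size < 1:
        raise ValueError("need at least one p-value")
    return float(min(1.0, n_tests * pvalues.min()))


def correlated_mating_freqs(
    p: float,
    n_loci: int,
    rho: float,
    rng: np.random.Generator,
    shared_x: bool = False,
) -> np.ndarray:
    """Chain of mating-type frequency rows for correlated loci.

    Parameters
    ----------
    p : allele frequency determining the HWE frequencies of locus 1.
    n_loci : number of loci L >= 1.
    rho : blending weight in [0, 1] between consecutive rows.
    shared_x : draw a single uniform noise value per locus instead of one
        per mating-type cell.  The default (per-cell noise) is what makes
        the ``rho = 0`` rows genuinely random frequency vectors.

    Returns
    -------
    (L, 6) matrix; every row sums to 1.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    rows = np.empty((n_loci, 6))
    rows[0] = hwe_mating_freqs(p)
    for locus in range(1, n_loci):
        x = rng.uniform() if shared_x else rng.uniform(size=6)
        y = rho * rows[locus - 1] + (1.0 - rho) * x
        rows[locus] = y / y.sum()
    return rows
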