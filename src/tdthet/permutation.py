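"""Permutation null distribution for the trio statistics.

The null hypothesis fixes ``t = 1/2``; parental mating types are ancillary,
so the exact conditional null is generated by redrawing each child genotype
from the Mendelian kernel given its parental mating type — equivalently,
every heterozygous parent independently re-transmits M with probability
1/2.  Mating-type totals are preserved exactly; trio types without a
heterozygous parent are untouched.

Point-wise p-values are plain exceedance proportions ``#{perm >= obs} / B``
(ties count as exceedance, conservative), with an optional add-one
correction ``(#{>=} + 1) / (B + 1)``.  Family-wise significance across loci
uses the per-permutation maximum statistic (max-T).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classic_tdt import tdt_statistics
from .em_mixture import EMSettings, TrioCounts, tdt_het_statistics

__all__ = [
    "PermutationSet",
    "permute_counts",
    "permute_counts_batch",
    "pointwise_pvalue",
    "maxT_pvalue",
    "permutation_test",
]

# child redistribution within mating types, canonical cell order
# 000 100 101 110 111 112 201 211 212 222
_MT2_CELLS = (8, 7)        # MM x MN -> 212 / 211
_MT4_CELLS = (3, 4, 5)     # MN x MN -> 110 / 111 / 112
_MT5_CELLS = (2, 1)        # MN x NN -> 101 / 100
_MT4_PROBS = (0.25, 0.5, 0.25)


def permute_counts_batch(
    counts: TrioCounts, n_perms: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_perms`` null count vectors conditional on mating types.

    Returns an (n_perms, 10) integer matrix; every row has the same six
    mating-type totals as the input.
    """
    n = counts.counts
    out = np.tile(n, (n_perms, 1))
    n2 = int(n[_MT2_CELLS[0]] + n[_MT2_CELLS[1]])
    n4 = int(n[_MT4_CELLS[0]] + n[_MT4_CELLS[1]] + n[_MT4_CELLS[2]])
    n5 = int(n[_MT5_CELLS[0]] + n[_MT5_CELLS[1]])
    if n2:
        x = rng.binomial(n2, 0.5, size=n_perms)
        out[:, _MT2_CELLS[0]] = x
        out[:, _MT2_CELLS[1]] = n2 - x
    if n4:
        z = rng.multinomial(n4, _MT4_PROBS, size=n_perms)
        out[:, _MT4_CELLS[0]] = z[:, 0]
        out[:, _MT4_CELLS[1]] = z[:, 1]
        out[:, _MT4_CELLS[2]] = z[:, 2]
    if n5:
        y = rng.binomial(n5, 0.5, size=n_perms)
        out[:, _MT5_CELLS[0]] = y
        out[:, _MT5_CELLS[1]] = n5 - y
    return out


def permute_counts(counts: TrioCounts, rng: np.random.Generator) -> TrioCounts:
    """One null redraw of the child genotypes given parental mating types."""
    return TrioCounts(permute_counts_batch(counts, 1, rng)[0])


@dataclass(frozen=True)
class PermutationSet:
    """Observed statistic plus its B permutation replicates at one locus."""

    observed: float
    stats: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        stats = np.asarray(self.stats, dtype=float)
        if stats.ndim != 1 or stats.size < 1:
            raise ValueError("stats must be a non-empty 1-d array")
        object.__setattr__(self, "stats", stats)

    @property
    def n_perms(self) -> int:
        return self.stats.size


def pointwise_pvalue(perm: PermutationSet, add_one: bool = False) -> float:
    """Exceedance proportion of the observed statistic.

    Default is the plain proportion ``#{perm >= obs} / B`` (can be 0);
    ``add_one`` applies the ``(k + 1) / (B + 1)`` correction.
    """
    k = int(np.sum(perm.stats >= perm.observed))
    if add_one:
        return (k + 1) / (perm.n_perms + 1)
    return k / perm.n_perms


def maxT_pvalue(perms_by_locus: list[PermutationSet], locus: int) -> float:
    """Family-wise p-value for one locus via the per-permutation maximum.

    All loci must share the same number of aligned permutations.
    """
    sizes = {p.n_perms for p in perms_by_locus}
    if len(sizes) != 1:
        raise ValueError("all loci must have the same number of permutations")
    stack = np.vstack([p.stats for p in perms_by_locus])
    return float(np.mean(stack.max(axis=0) >= perms_by_locus[locus].observed))


def permutation_test(
    counts: TrioCounts,
    settings: EMSettings | None = None,
    n_perms: int = 500,
    rng: np.random.Generator | None = None,
    statistics: tuple[str, ...] = ("tdt_het", "tdt"),
) -> dict[str, PermutationSet]:
    """Observed and permuted statistics at one locus.

    Both statistics are evaluated on the same permuted count vectors, so
    their p-values are directly comparable.  The heterogeneity LRT re-fits
    the full multi-start EM on every permutation.
    """
    settings = settings or EMSettings()
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    if n_perms < 1:
        raise ValueError("need at least one permutation")
    matrix = np.vstack([counts.counts[None, :], permute_counts_batch(counts, n_perms, rng)])
    out: dict[str, PermutationSet] = {}
    if "tdt_het" in statistics:
        stats = tdt_het_statistics(matrix, settings, rng)
        out["tdt_het"] = PermutationSet(observed=float(stats[0]), stats=stats[1:])
    if "tdt" in statistics:
        stats = tdt_statistics(matrix)
        out["tdt"] = PermutationSet(observed=float(stats[0]), stats=stats[1:])
    return out
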