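"""The classic transmission disequilibrium test.

Counts transmissions of the tracked allele M from heterozygous parents to
affected children: ``b`` transmissions of M, ``c`` of N.  The statistic
``(b - c)^2 / (b + c)`` is asymptotically chi-squared(1) under Mendelian
transmission; here it serves as the head-to-head comparator for the
heterogeneity LRT, with significance taken from the same permutation
scheme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .em_mixture import TrioCounts
from .genetic_model import HET_PARENTS, M_TRANSMISSIONS

__all__ = ["TransmissionCounts", "bc_from_counts", "tdt_statistic", "tdt_statistics"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TransmissionCounts:
    """M/N transmission counts from heterozygous parents."""

    b: int
    c: int

    def __post_init__(self) -> None:
        if self.b < 0 or self.c < 0:
            raise ValueError("transmission counts must be non-negative")


def bc_from_counts(counts: TrioCounts) -> TransmissionCounts:
    """Transmission counts implied by the ten trio-type cells.

    b = n_212 + 2*n_112 + n_111 + n_101 (M transmissions);
    c = n_211 + n_111 + 2*n_110 + n_100 (N transmissions).
    """
    n = counts.counts
    b = int(np.sum(n * M_TRANSMISSIONS))
    c = int(np.sum(n * (HET_PARENTS - M_TRANSMISSIONS)))
    return TransmissionCounts(b=b, c=c)


def tdt_statistic(tc: TransmissionCounts) -> float:
    """``(b - c)^2 / (b + c)``; defined as 0 for b + c = 0."""
    total = tc.b + tc.c
    if total == 0:
        logger.warning("no heterozygous parents: TDT statistic set to 0")
        return 0.0
    return (tc.b - tc.c) ** 2 / total


def tdt_statistics(counts_matrix: np.ndarray) -> np.ndarray:
    """Vectorized classic TDT over rows of a (M, 10) count matrix."""
    cm = np.asarray(counts_matrix, dtype=float)
    b = cm @ M_TRANSMISSIONS
    c = cm @ (HET_PARENTS - M_TRANSMISSIONS)
    total = b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(total > 0, (b - c) ** 2 / np.where(total > 0, total, 1), 0.0)
    return stat
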