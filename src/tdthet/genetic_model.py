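"""Trio types, mating types and the single-locus genetic model.

A di-allelic locus carries alleles M (the tracked / putative risk allele)
and N.  A case-parent trio is coded ``x_abc`` where ``a``, ``b`` and ``c``
are the numbers of M alleles carried by parent 1, parent 2 and the affected
child.  Parental order is irrelevant, so codes are stored with ``a >= b``;
this leaves exactly ten Mendelian-consistent trio types, grouped into six
parental mating types (MM x MM, MM x MN, MM x NN, MN x MN, MN x NN,
NN x NN).

The central probabilistic object is the transmission kernel
``g_abc(t)`` = Pr(child genotype | mating type) when every heterozygous
parent transmits M with probability ``t`` independently.  ``t = 1/2`` is
Mendelian transmission (the no-linkage null); the linked component of the
heterogeneity mixture uses a free ``t``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TRIO_LABELS",
    "TRIO_CODES",
    "TRIO_INDEX",
    "MATING_TYPE_OF_TRIO",
    "HET_PARENTS",
    "M_TRANSMISSIONS",
    "MIRROR_PERM",
    "MATING_LABELS",
    "GeneticModel",
    "kernel_g",
    "hwe_mating_freqs",
    "mating_freqs_of_trios",
    "penetrances",
    "linked_trio_distribution",
    "unlinked_trio_distribution",
    "implied_transmission",
]

#: Canonical order of the ten trio types (lexicographic in the code string).
TRIO_LABELS: tuple[str, ...] = (
    "000", "100", "101", "110", "111", "112", "201", "211", "212", "222",
)

#: Codes (a, b, c) with a >= b.
TRIO_CODES: tuple[tuple[int, int, int], ...] = tuple(
    (int(s[0]), int(s[1]), int(s[2])) for s in TRIO_LABELS
)

#: Map from (a, b, c) (a >= b) to position in canonical order.
TRIO_INDEX: dict[tuple[int, int, int], int] = {
    code: i for i, code in enumerate(TRIO_CODES)
}

#: Mating-type index 1..6 of each trio type
#: (MMxMM=1, MMxMN=2, MMxNN=3, MNxMN=4, MNxNN=5, NNxNN=6).
MATING_TYPE_OF_TRIO = np.array([6, 5, 5, 4, 4, 4, 3, 2, 2, 1])

MATING_LABELS: tuple[str, ...] = (
    "MMxMM", "MMxMN", "MMxNN", "MNxMN", "MNxNN", "NNxNN",
)

#: Number of heterozygous parents in each trio type.
HET_PARENTS = np.array([0, 1, 1, 2, 2, 2, 0, 1, 1, 0])

#: Number of M alleles transmitted by heterozygous parents in each trio type.
M_TRANSMISSIONS = np.array([0, 0, 1, 0, 1, 2, 0, 0, 1, 0])

#: Permutation realizing the allele relabeling M <-> N: abc -> (2-a, 2-b, 2-c).
MIRROR_PERM = np.array([9, 8, 7, 5, 4, 3, 6, 2, 1, 0])

#: Cells with no heterozygous parent (000, 201, 222): uninformative for t.
HOM_CELLS = np.array([0, 6, 9])
#: Cells with at least one heterozygous parent, canonical order.
HET_CELLS = np.array([1, 2, 3, 4, 5, 7, 8])


def kernel_g(t):
    """Transmission kernel g_abc(t) over the ten trio types.

    Parameters
    ----------
    t : float or ndarray
        Probability that a heterozygous parent transmits M to the affected
        child; must lie in [0, 1].

    Returns
    -------
    ndarray with shape ``t.shape + (10,)``: Pr(child | mating type) for each
    trio type in canonical order.  Within every mating type the entries sum
    to 1 for any ``t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any((t < 0) | (t > 1)):
        raise ValueError("transmission probability t must lie in [0, 1]")
    u = 1.0 - t
    one = np.ones_like(t)
    # order: 000, 100, 101, 110, 111, 112, 201, 211, 212, 222
    return np.stack(
        [one, u, t, u * u, 2 * t * u, t * t, one, u, t, one], axis=-1
    )


def hwe_mating_freqs(p: float) -> np.ndarray:
    """Mating-type frequencies under random mating and Hardy-Weinberg.

    The six unordered parental genotype-pair probabilities, e.g. the
    MN x NN frequency is 2 * (2pq) * q^2 = 4pq^3.

    Parameters
    ----------
    p : allele frequency of M, strictly inside (0, 1).

    Returns
    -------
    ndarray of 6 frequencies (MMxMM, MMxMN, MMxNN, MNxMN, MNxNN, NNxNN),
    summing to 1.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"allele frequency must be in (0, 1), got {p}")
    q = 1.0 - p
    return np.array(
        [p**4, 4 * p**3 * q, 2 * p**2 * q**2, 4 * p**2 * q**2, 4 * p * q**3, q**4]
    )


def mating_freqs_of_trios(mu) -> np.ndarray:
    """Expand 6 mating-type frequencies to the 10 trio-type cells."""
    mu = np.asarray(mu, dtype=float)
    if mu.shape[-1] != 6:
        raise ValueError("expected 6 mating-type frequencies")
    return mu[..., MATING_TYPE_OF_TRIO - 1]


def _validate_mu(mu) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if mu.shape != (6,):
        raise ValueError("mu must have 6 entries")
    if np.any(mu < 0) or abs(mu.sum() - 1.0) > 1e-12:
        raise ValueError("mating-type frequencies must be >= 0 and sum to 1")
    return mu


@dataclass(frozen=True)
class GeneticModel:
    """Penetrance model for a single di-allelic disease locus.

    Parameters
    ----------
    phi : disease prevalence, in (0, 1).
    p : disease (risk) allele frequency, in (0, 1).
    moi : mode of inheritance: ``"dominant"`` (R1 = R2), ``"recessive"``
        (R1 = 1) or ``"multiplicative"`` (R1^2 = R2).
    r2 : genotype relative risk of the MM homozygote, f2 / f0, >= 0.

    Penetrances are recovered from the prevalence identity
    ``f0 * (q^2 + 2pq*R1 + p^2*R2) = phi``; a configuration implying a
    penetrance above 1 is rejected rather than clamped.
    """

    phi: float
    p: float
    moi: str
    r2: float

    _MOIS = ("dominant", "recessive", "multiplicative")

    def __post_init__(self) -> None:
        if not 0.0 < self.phi < 1.0:
            raise ValueError(f"prevalence must be in (0, 1), got {self.phi}")
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"allele frequency must be in (0, 1), got {self.p}")
        if self.moi not in self._MOIS:
            raise ValueError(f"moi must be one of {self._MOIS}, got {self.moi!r}")
        if self.r2 < 0:
            raise ValueError("genotype relative risk r2 must be >= 0")
        self.penetrances()  # validate f_i <= 1 eagerly

    @property
    def q(self) -> float:
        return 1.0 - self.p

    @property
    def r1(self) -> float:
        """Heterozygote genotype relative risk implied by the MOI."""
        if self.moi == "dominant":
            return self.r2
        if self.moi == "recessive":
            return 1.0
        return float(np.sqrt(self.r2))

    def penetrances(self) -> tuple[float, float, float]:
        """(f0, f1, f2) solving the prevalence identity under HWE."""
        r1 = self.r1
        denom = self.q**2 + 2 * self.p * self.q * r1 + self.p**2 * self.r2
        f0 = self.phi / denom
        f = (f0, r1 * f0, self.r2 * f0)
        if max(f) > 1.0:
            raise ValueError(
                f"model implies penetrance above 1: f={f}; "
                "reduce prevalence or relative risk"
            )
        return f


def penetrances(model: GeneticModel) -> tuple[float, float, float]:
    """Functional alias for :meth:`GeneticModel.penetrances`."""
    return model.penetrances()


def unlinked_trio_distribution(mu) -> np.ndarray:
    """Trio-type distribution in the unlinked population (t = 1/2).

    ``Pr(x_abc) = mu_i(abc) * g_abc(1/2)``; sums to 1 by construction.
    """
    mu = _validate_mu(mu)
    return mating_freqs_of_trios(mu) * kernel_g(0.5)


def linked_trio_distribution(model: GeneticModel, mu) -> np.ndarray:
    """Trio-type distribution among linked trios ascertained through an
    affected child.

    Bayes' rule through the affected child:
    ``Pr(x_abc | child affected) ∝ mu_i(abc) * g_abc(1/2) * f_c(abc)``,
    normalized over the ten trio types.  Mendelian transmission appears as
    the prior; the distortion toward over-transmission of M comes entirely
    from the child penetrance weight.
    """
    mu = _validate_mu(mu)
    f = np.asarray(model.penetrances())
    child = np.array([c for _, _, c in TRIO_CODES])
    w = mating_freqs_of_trios(mu) * kernel_g(0.5) * f[child]
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate model: trio distribution has zero mass")
    return w / total


def implied_transmission(model: GeneticModel) -> float:
    """Heterozygous-parent M-transmission probability among linked trios.

    Equals ``R1 / (R1 + 1)``.  Under a multiplicative MOI this is exact:
    the ascertained trio distribution factorizes as mating-type weights
    times ``kernel_g(t*)`` with ``t* = R1/(R1+1)``.  For other MOIs it is
    the expected transmission ratio only approximately.
    """
    r1 = model.r1
    return r1 / (r1 + 1.0)
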