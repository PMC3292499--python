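"""Likelihood-ratio test for transmission disequilibrium under locus
heterogeneity.

The sample of case-parent trios is modeled as a two-component mixture: a
proportion ``pi1`` of trios is linked to the tested locus and transmits the
tracked allele M from heterozygous parents with a common free probability
``t``, while the remaining trios are unlinked (``t = 1/2``).  Both
components share one set of parental mating-type frequencies ``mu``, so the
trio-type probability is

    Pr(x_abc) = mu_i(abc) * [ pi1 * g_abc(t) + (1 - pi1) * g_abc(1/2) ].

Because ``mu`` is shared, its maximum-likelihood estimate is the observed
mating-type relative frequencies under both hypotheses, and it cancels from
the likelihood ratio.  The statistic

    LRT = max(0, 2 * (llmax_H1 - ll_H0)),     H0: t = 1/2

is maximized by multi-start EM over (t, pi1); it does not follow a central
chi-squared(1) distribution under the null, so p-values are obtained by
permutation (see :mod:`tdthet.permutation`).

A small penalty ``C`` enters the EM updates as symmetric pseudo-counts,
equivalently MAP estimation under Beta(1 + C, 1 + C) priors on ``t`` and
``pi1``; it keeps estimates off the boundary and is negligible at the
default ``C = 0.001``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genetic_model import (
    HET_CELLS,
    HET_PARENTS,
    HOM_CELLS,
    M_TRANSMISSIONS,
    MATING_TYPE_OF_TRIO,
    MIRROR_PERM,
    TRIO_INDEX,
    TRIO_LABELS,
    kernel_g,
    mating_freqs_of_trios,
)

__all__ = [
    "TrioCounts",
    "MixtureParams",
    "EMSettings",
    "FitResult",
    "loglik",
    "e_step",
    "m_step",
    "fit_h0",
    "fit_h1",
    "tdt_het",
    "tdt_het_statistics",
    "linked_decision",
]

logger = logging.getLogger(__name__)

_G0 = kernel_g(0.5)                       # Mendelian kernel, 10 cells
_G0_HET = _G0[HET_CELLS]                  # 7 informative cells
_M7 = M_TRANSMISSIONS[HET_CELLS].astype(float)
_H7 = HET_PARENTS[HET_CELLS].astype(float)
_LOG_G0_HET = np.log(_G0_HET)
_TINY = 1e-300


@dataclass(frozen=True)
class TrioCounts:
    """Counts of the ten coded trio types at one locus.

    ``counts[i]`` is the number of trios of the i-th type in canonical
    order (000, 100, 101, 110, 111, 112, 201, 211, 212, 222).
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (10,):
            raise ValueError("TrioCounts needs exactly 10 cells")
        if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
            if np.any(arr != np.floor(arr)) or np.any(arr < 0):
                raise ValueError("counts must be non-negative integers")
            arr = arr.astype(np.int64)
        object.__setattr__(self, "counts", arr.astype(np.int64))

    @property
    def n(self) -> int:
        """Total number of trios."""
        return int(self.counts.sum())

    @classmethod
    def from_dict(cls, d: dict) -> "TrioCounts":
        """Build from a mapping like ``{"212": 30, "211": 10}``.

        Keys may be label strings or (a, b, c) tuples; parent codes are
        reordered so that a >= b.
        """
        arr = np.zeros(10, dtype=np.int64)
        for key, value in d.items():
            if isinstance(key, str):
                a, b, c = (int(ch) for ch in key)
            else:
                a, b, c = key
            a, b = max(a, b), min(a, b)
            arr[TRIO_INDEX[(a, b, c)]] += int(value)
        return cls(arr)

    def to_dict(self) -> dict[str, int]:
        return {lab: int(v) for lab, v in zip(TRIO_LABELS, self.counts)}

    def mating_counts(self) -> np.ndarray:
        """Counts of the six parental mating types."""
        out = np.zeros(6, dtype=np.int64)
        np.add.at(out, MATING_TYPE_OF_TRIO - 1, self.counts)
        return out

    def mirror(self) -> "TrioCounts":
        """Counts under the allele relabeling M <-> N."""
        return TrioCounts(self.counts[MIRROR_PERM])


@dataclass(frozen=True)
class MixtureParams:
    """Parameters of the two-component transmission mixture."""

    t: float
    pi1: float
    mu: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.t <= 1.0:
            raise ValueError("t must lie in [0, 1]")
        if not 0.0 <= self.pi1 <= 1.0:
            raise ValueError("pi1 must lie in [0, 1]")
        mu = np.asarray(self.mu, dtype=float)
        if mu.shape != (6,) or np.any(mu < 0) or abs(mu.sum() - 1) > 1e-12:
            raise ValueError("mu must be 6 non-negative frequencies summing to 1")
        object.__setattr__(self, "mu", mu)

    @property
    def pi2(self) -> float:
        return 1.0 - self.pi1


@dataclass(frozen=True)
class EMSettings:
    """Knobs of the multi-start EM maximization.

    Defaults follow the reference analysis protocol: 200 random starting
    points, at most 100 EM steps each, absolute log-likelihood convergence
    tolerance 1e-6, boundary penalty C = 0.001.
    """

    n_starts: int = 200
    max_steps: int = 100
    epsilon: float = 1e-6
    penalty_c: float = 0.001
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.penalty_c < 0:
            raise ValueError("penalty_c must be >= 0")


@dataclass(frozen=True)
class FitResult:
    """Outcome of the likelihood-ratio fit at one locus."""

    ll_h1: float
    ll_h0: float
    statistic: float
    t_hat: float
    pi1_hat: float
    mu_hat: np.ndarray
    tau1: np.ndarray
    converged: bool
    n_iterations: int
    start_index: int


def loglik(counts: TrioCounts, params: MixtureParams) -> float:
    """Mixture log-likelihood of the observed trio-type counts.

    Cells with zero count contribute nothing even if their model
    probability is zero; a positive count on a zero-probability cell yields
    ``-inf``.
    """
    g1 = kernel_g(params.t)
    prob = mating_freqs_of_trios(params.mu) * (
        params.pi1 * g1 + (1.0 - params.pi1) * _G0
    )
    n = counts.counts
    mask = n > 0
    if np.any(prob[mask] <= 0):
        return -np.inf
    return float(np.sum(n[mask] * np.log(prob[mask])))


def e_step(counts: TrioCounts, params: MixtureParams) -> np.ndarray:
    """Posterior probabilities that each trio type belongs to the linked
    component.

    The shared ``mu`` cancels, so
    ``tau_abc = pi1*g_abc(t) / [pi1*g_abc(t) + (1-pi1)*g_abc(1/2)]``.
    Trio types without a heterozygous parent (000, 201, 222) have identical
    component densities and get ``tau = pi1`` exactly.
    """
    g1 = kernel_g(params.t)
    num = params.pi1 * g1
    den = num + (1.0 - params.pi1) * _G0
    tau = np.empty(10)
    zero = den <= 0.0
    if np.any(zero):
        logger.warning(
            "both component densities are zero for %s; using tau = pi1",
            [TRIO_LABELS[i] for i in np.flatnonzero(zero)],
        )
        tau[zero] = params.pi1
    nz = ~zero
    tau[nz] = num[nz] / den[nz]
    tau[HOM_CELLS] = params.pi1  # exact, avoids rounding in the ratio
    return tau


def m_step(
    counts: TrioCounts, tau1: np.ndarray, settings: EMSettings | None = None
) -> MixtureParams:
    """Penalized maximization step given linked-component responsibilities.

    ``pi1 <- (sum n*tau + C) / (n + 2C)``;
    ``t   <- (sum n*tau*m + C) / (sum n*tau*h + 2C)`` where ``m`` counts M
    alleles transmitted by heterozygous parents and ``h`` counts
    heterozygous parents per trio type.  ``mu`` has the closed-form solution
    observed mating-type relative frequencies (shared across components, so
    independent of ``tau``).
    """
    settings = settings or EMSettings()
    tau1 = np.asarray(tau1, dtype=float)
    if tau1.shape != (10,) or np.any((tau1 < 0) | (tau1 > 1)):
        raise ValueError("tau1 must be 10 probabilities in [0, 1]")
    c = settings.penalty_c
    n = counts.counts.astype(float)
    w = float(np.sum(n * tau1))
    pi1 = (w + c) / (counts.n + 2 * c)
    tm = float(np.sum(n * tau1 * M_TRANSMISSIONS))
    th = float(np.sum(n * tau1 * HET_PARENTS))
    if th + 2 * c > 0:
        t = (tm + c) / (th + 2 * c)
    else:
        logger.warning("no heterozygous-parent mass; t fixed at 0.5")
        t = 0.5
    mc = counts.mating_counts()
    mu = mc / mc.sum() if counts.n else np.full(6, 1 / 6)
    return MixtureParams(t=t, pi1=pi1, mu=mu)


def fit_h0(counts: TrioCounts) -> float:
    """Maximized log-likelihood under H0: t = 1/2.

    Closed form: at ``t = 1/2`` the two components coincide, ``pi1`` is
    unidentifiable and drops out, and the MLE of the shared ``mu`` is the
    observed mating-type relative frequencies.
    """
    if counts.n < 1:
        raise ValueError("need at least one trio")
    mc = counts.mating_counts()
    mu_hat = mc / counts.n
    prob = mating_freqs_of_trios(mu_hat) * _G0
    n = counts.counts
    mask = n > 0
    return float(np.sum(n[mask] * np.log(prob[mask])))


# ---------------------------------------------------------------------------
# Vectorized multi-start EM engine
# ---------------------------------------------------------------------------
#
# The likelihood depends on the data only through the 7 trio types with a
# heterozygous parent (the other three have identical component densities
# and a mu-only factor common to H0 and H1).  The engine therefore works on
# the mu-free partial log-likelihood
#     ll_mix = sum_{7 cells} n_c * log(pi1*g_c(t) + (1-pi1)*g_c(1/2)),
# runs every (problem, start) chain as one flat vector, and compacts the
# active set as chains converge.  When numba is importable the chain loop
# is JIT-compiled instead, which is considerably faster for the large
# batches produced by permutation and replicate studies.

try:  # optional acceleration
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(fn):
            return fn

        return deco


@_njit(cache=False)
def _em_chain_kernel(n7, nhom, ntot, t0, pi0, g0, m7, h7, c, eps, max_steps):
    k_chains = t0.shape[0]
    out_t = np.empty(k_chains)
    out_pi = np.empty(k_chains)
    out_ll = np.empty(k_chains)
    out_pen = np.empty(k_chains)
    out_iter = np.zeros(k_chains, dtype=np.int64)
    out_conv = np.zeros(k_chains, dtype=np.bool_)
    for k in range(k_chains):
        t = t0[k]
        pi = pi0[k]
        prev = -np.inf
        for step in range(1, max_steps + 1):
            u = 1.0 - t
            ll = 0.0
            w = 0.0
            tm = 0.0
            th = 0.0
            # cells: 100, 101, 110, 111, 112, 211, 212
            for j in range(7):
                if j == 0 or j == 5:
                    g = u
                elif j == 1 or j == 6:
                    g = t
                elif j == 2:
                    g = u * u
                elif j == 3:
                    g = 2.0 * t * u
                else:
                    g = t * t
                num = pi * g
                mix = num + (1.0 - pi) * g0[j]
                if mix < _TINY:
                    mix = _TINY
                nj = n7[k, j]
                if nj > 0.0:
                    ll += nj * np.log(mix)
                    tau = num / mix
                    w += nj * tau
                    tm += nj * tau * m7[j]
                    th += nj * tau * h7[j]
            if c > 0.0:
                pen = ll + c * (np.log(t) + np.log(u) + np.log(pi) + np.log(1.0 - pi))
            else:
                pen = ll
            conv = abs(pen - prev) < eps
            if conv or step == max_steps:
                out_t[k] = t
                out_pi[k] = pi
                out_ll[k] = ll
                out_pen[k] = pen
                out_iter[k] = step
                out_conv[k] = conv
                break
            prev = pen
            w += nhom[k] * pi
            pi = (w + c) / (ntot[k] + 2.0 * c)
            den = th + 2.0 * c
            if den > 0.0:
                t = (tm + c) / den
            else:
                t = 0.5
            if t < 1e-12:
                t = 1e-12
            elif t > 1.0 - 1e-12:
                t = 1.0 - 1e-12
            if pi < 1e-12:
                pi = 1e-12
            elif pi > 1.0 - 1e-12:
                pi = 1.0 - 1e-12
    return out_t, out_pi, out_ll, out_pen, out_iter, out_conv


def _fit_h1_batch(
    counts_matrix: np.ndarray,
    settings: EMSettings,
    rng: np.random.Generator | None = None,
    init: tuple[np.ndarray, np.ndarray] | None = None,
):
    """Multi-start EM on a batch of count vectors.

    Parameters
    ----------
    counts_matrix : (M, 10) integer array, one problem per row.
    init : optional pair of (M * n_starts,) arrays of starting (t, pi1)
        values, replacing the uniform random draws (used for testing).

    Returns
    -------
    dict of per-problem arrays: ``t``, ``pi1``, ``ll_mix`` (mu-free H1
    log-likelihood), ``pen_ll``, ``n_iterations``, ``converged``,
    ``start_index``.
    """
    counts_matrix = np.asarray(counts_matrix)
    if counts_matrix.ndim != 2 or counts_matrix.shape[1] != 10:
        raise ValueError("counts_matrix must have shape (M, 10)")
    if np.any(counts_matrix.sum(axis=1) < 1):
        raise ValueError("every problem needs at least one trio")
    m_problems = counts_matrix.shape[0]
    s = settings.n_starts
    c = settings.penalty_c
    eps = settings.epsilon

    n7_all = counts_matrix[:, HET_CELLS].astype(float)
    nhom_all = counts_matrix[:, HOM_CELLS].sum(axis=1).astype(float)
    ntot_all = counts_matrix.sum(axis=1).astype(float)

    k0 = m_problems * s
    problem = np.repeat(np.arange(m_problems), s)
    if init is None:
        if rng is None:
            raise ValueError("need an rng when no explicit starting values are given")
        t = rng.uniform(size=k0)
        pi = rng.uniform(size=k0)
    else:
        t, pi = (np.array(v, dtype=float) for v in init)
        if t.shape != (k0,) or pi.shape != (k0,):
            raise ValueError(f"init arrays must have shape ({k0},)")
    np.clip(t, 1e-12, 1 - 1e-12, out=t)
    np.clip(pi, 1e-12, 1 - 1e-12, out=pi)

    if _HAVE_NUMBA:
        fin_t, fin_pi, fin_ll, fin_pen, fin_iter, fin_conv = _em_chain_kernel(
            n7_all[problem],
            nhom_all[problem],
            ntot_all[problem],
            t,
            pi,
            _G0_HET,
            _M7,
            _H7,
            float(c),
            float(eps),
            int(settings.max_steps),
        )
        return _select_best(fin_t, fin_pi, fin_ll, fin_pen, fin_iter, fin_conv, m_problems, s)

    # final per-chain results
    fin_t = np.empty(k0)
    fin_pi = np.empty(k0)
    fin_ll = np.empty(k0)
    fin_pen = np.empty(k0)
    fin_iter = np.zeros(k0, dtype=np.int64)
    fin_conv = np.zeros(k0, dtype=bool)

    chain = np.arange(k0)           # ids of active chains
    n7 = n7_all[problem]            # gathered per-chain data
    nhom = nhom_all[problem]
    ntot = ntot_all[problem]
    prev_pen = np.full(k0, -np.inf)

    for step in range(1, settings.max_steps + 1):
        u = 1.0 - t
        # kernel over the 7 informative cells:
        # 100, 101, 110, 111, 112, 211, 212
        g = np.stack([u, t, u * u, 2 * t * u, t * t, u, t], axis=1)
        num = pi[:, None] * g
        mix = num + (1.0 - pi)[:, None] * _G0_HET[None, :]
        np.maximum(mix, _TINY, out=mix)
        ll = np.einsum("ij,ij->i", n7, np.log(mix))
        if c > 0:
            pen = ll + c * (np.log(t) + np.log(u) + np.log(pi) + np.log(1 - pi))
        else:
            pen = ll

        converged_now = np.abs(pen - prev_pen) < eps
        done = converged_now | (step == settings.max_steps)
        if np.any(done):
            ids = chain[done]
            fin_t[ids] = t[done]
            fin_pi[ids] = pi[done]
            fin_ll[ids] = ll[done]
            fin_pen[ids] = pen[done]
            fin_iter[ids] = step
            fin_conv[ids] = converged_now[done]
        keep = ~done
        if not np.all(keep):
            chain = chain[keep]
            n7 = n7[keep]
            nhom = nhom[keep]
            ntot = ntot[keep]
            t = t[keep]
            pi = pi[keep]
            num = num[keep]
            mix = mix[keep]
            pen = pen[keep]
        if chain.size == 0:
            break
        prev_pen = pen

        tau = num / mix
        w = np.einsum("ij,ij->i", n7, tau) + nhom * pi
        tm = (n7 * tau) @ _M7
        th = (n7 * tau) @ _H7
        pi = (w + c) / (ntot + 2 * c)
        den = th + 2 * c
        t = np.where(den > 0, (tm + c) / np.where(den > 0, den, 1.0), 0.5)
        np.clip(t, 1e-12, 1 - 1e-12, out=t)
        np.clip(pi, 1e-12, 1 - 1e-12, out=pi)

    return _select_best(fin_t, fin_pi, fin_ll, fin_pen, fin_iter, fin_conv, m_problems, s)


def _select_best(fin_t, fin_pi, fin_ll, fin_pen, fin_iter, fin_conv, m_problems, s):
    # pick the best start per problem by penalized log-likelihood;
    # exact ties resolve to the lowest start index (argmax convention)
    pen_by_problem = fin_pen.reshape(m_problems, s)
    best = pen_by_problem.argmax(axis=1)
    flat = np.arange(m_problems) * s + best
    return {
        "t": fin_t[flat],
        "pi1": fin_pi[flat],
        "ll_mix": fin_ll[flat],
        "pen_ll": fin_pen[flat],
        "n_iterations": fin_iter[flat],
        "converged": fin_conv[flat],
        "start_index": best,
    }


def _ll_mix_h0(counts_matrix: np.ndarray) -> np.ndarray:
    """Mu-free part of the H0 log-likelihood (t = 1/2) per problem row."""
    n7 = np.asarray(counts_matrix)[:, HET_CELLS].astype(float)
    return n7 @ _LOG_G0_HET


def tdt_het_statistics(
    counts_matrix: np.ndarray,
    settings: EMSettings | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Likelihood-ratio statistics for a batch of count vectors.

    Vectorized across problems and EM starts; the shared mating-type
    frequencies cancel from the ratio, so only transmission-informative
    cells enter.  Returns an array of ``max(0, 2*(ll_H1 - ll_H0))``.
    """
    settings = settings or EMSettings()
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    res = _fit_h1_batch(np.asarray(counts_matrix), settings, rng)
    stat = 2.0 * (res["ll_mix"] - _ll_mix_h0(counts_matrix))
    return np.maximum(stat, 0.0)


def fit_h1(
    counts: TrioCounts,
    settings: EMSettings | None = None,
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Maximize the H1 likelihood by multi-start EM.

    Starting values ``t, pi1 ~ U(0, 1)`` independently per start; ``mu`` is
    set to its closed-form MLE (observed mating-type frequencies).  Each
    start runs until the penalized log-likelihood changes by less than
    ``epsilon`` or ``max_steps`` is reached; the start with the highest
    penalized log-likelihood wins and posteriors are recomputed at its
    parameters.
    """
    settings = settings or EMSettings()
    if counts.n < 1:
        raise ValueError("need at least one trio")
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    res = _fit_h1_batch(counts.counts[None, :], settings, rng)
    mc = counts.mating_counts()
    mu_hat = mc / counts.n
    params = MixtureParams(t=float(res["t"][0]), pi1=float(res["pi1"][0]), mu=mu_hat)
    tau1 = e_step(counts, params)
    ll_h0 = fit_h0(counts)
    # add the mu term (common to H0 and H1) back for reporting
    ll_h1 = float(res["ll_mix"][0]) + (ll_h0 - float(_ll_mix_h0(counts.counts[None, :])[0]))
    statistic = max(0.0, 2.0 * (ll_h1 - ll_h0))
    return FitResult(
        ll_h1=ll_h1,
        ll_h0=ll_h0,
        statistic=statistic,
        t_hat=params.t,
        pi1_hat=params.pi1,
        mu_hat=mu_hat,
        tau1=tau1,
        converged=bool(res["converged"][0]),
        n_iterations=int(res["n_iterations"][0]),
        start_index=int(res["start_index"][0]),
    )


def tdt_het(
    counts: TrioCounts,
    settings: EMSettings | None = None,
    rng: np.random.Generator | None = None,
) -> FitResult:
    """The heterogeneity-aware transmission disequilibrium LRT at one locus.

    Returns the full fit; no analytic p-value is attached because the
    statistic is not chi-squared(1) under the null — use the permutation
    machinery for significance.
    """
    if counts.counts[HET_CELLS].sum() == 0:
        logger.warning(
            "no trios with heterozygous parents: t is unidentified and the "
            "statistic is 0"
        )
    return fit_h1(counts, settings, rng)


def linked_decision(fit: FitResult, require_het_parent: bool = False):
    """Trio types classified as linked by the posterior cutoff rule.

    Rule (i): types with ``tau1 >= pi1_hat`` (ties included — types without
    a heterozygous parent sit exactly at equality).  Rule (ii), enabled by
    ``require_het_parent``, additionally demands at least one heterozygous
    parent.
    """
    sel = fit.tau1 >= fit.pi1_hat
    if require_het_parent:
        sel &= HET_PARENTS > 0
    return [TRIO_LABELS[i] for i in np.flatnonzero(sel)]
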