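"""Simulation of ascertained case-parent trios under locus heterogeneity,
and the type-I-error / power experiment driver.

Each trio is linked with probability ``pi1``.  Linked trios are drawn from
the ascertained trio-type distribution implied by the genetic model (Bayes
through the affected child); unlinked trios follow Mendelian transmission
with the same mating-type frequencies.  In multi-locus runs the linked /
unlinked label is drawn once per trio and shared across loci (linkage is a
property of the family), mating-type frequency rows are chained with
correlation weight ``rho``, and linked children are generated with the
transmission kernel at ``t* = R1/(R1+1)`` — exact for the multiplicative
mode of inheritance.

Experiments report empirical rejection proportions of the permutation
tests at each nominal level, with exact (Clopper-Pearson) binomial 95%
confidence intervals.  Replicates are seeded independently by replicate
index, so results do not depend on execution order or chunking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .classic_tdt import tdt_statistics
from .em_mixture import EMSettings, TrioCounts, _fit_h1_batch, _ll_mix_h0
from .genetic_model import (
    GeneticModel,
    hwe_mating_freqs,
    implied_transmission,
    kernel_g,
    linked_trio_distribution,
    mating_freqs_of_trios,
    unlinked_trio_distribution,
)
from .multilocus import MultiLocusConfig, correlated_mating_freqs
from .permutation import permute_counts_batch

__all__ = [
    "SimulationDesign",
    "SimulatedSample",
    "simulate_single_locus",
    "simulate_multilocus",
    "run_experiment",
    "rejection_rates",
]

#: cap on simultaneously active EM chains when batching replicates
_MAX_CHAINS = 1_200_000


@dataclass(frozen=True)
class SimulationDesign:
    """Complete specification of one simulation experiment."""

    model: GeneticModel
    pi1: float
    n_trios: int = 1000
    n_replicates: int = 250
    alphas: tuple[float, ...] = (0.05, 0.01)
    em: EMSettings = field(default_factory=EMSettings)
    n_perms: int = 500
    seed: int | None = None
    multilocus: MultiLocusConfig | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi1 <= 1.0:
            raise ValueError("pi1 must lie in [0, 1]")
        if self.n_trios < 1 or self.n_replicates < 1 or self.n_perms < 1:
            raise ValueError("counts must be positive")
        if any(not 0.0 < a < 1.0 for a in self.alphas):
            raise ValueError("significance levels must lie in (0, 1)")


@dataclass(frozen=True)
class SimulatedSample:
    """One simulated trio sample, possibly spanning several loci.

    ``codes`` holds the trio-type index (0..9, canonical order) per trio
    and locus; ``z`` flags the trios belonging to the linked component;
    ``mating_freqs`` echoes the frequency row used per locus.
    """

    codes: np.ndarray          # (n_trios, n_loci) int8
    z: np.ndarray              # (n_trios,) bool
    mating_freqs: np.ndarray   # (n_loci, 6)

    @property
    def n_trios(self) -> int:
        return self.codes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.codes.shape[1]

    @property
    def n_linked(self) -> int:
        return int(self.z.sum())

    def trio_counts(self, locus: int = 0) -> TrioCounts:
        """Aggregate the per-trio codes of one locus to 10-cell counts."""
        return TrioCounts(np.bincount(self.codes[:, locus], minlength=10))


def _single_locus_cell_probs(model: GeneticModel, pi1: float):
    mu = hwe_mating_freqs(model.p)
    return (
        linked_trio_distribution(model, mu),
        unlinked_trio_distribution(mu),
        mu,
    )


def simulate_single_locus(
    model: GeneticModel,
    pi1: float,
    n_trios: int,
    rng: np.random.Generator,
) -> SimulatedSample:
    """Draw one ascertained sample at a single locus under the mixture."""
    p_link, p_unlink, mu = _single_locus_cell_probs(model, pi1)
    z = rng.random(n_trios) < pi1
    codes = np.empty(n_trios, dtype=np.int8)
    n1 = int(z.sum())
    codes[z] = rng.choice(10, size=n1, p=p_link)
    codes[~z] = rng.choice(10, size=n_trios - n1, p=p_unlink)
    return SimulatedSample(
        codes=codes[:, None], z=z, mating_freqs=mu[None, :]
    )


def simulate_multilocus(
    model: GeneticModel,
    pi1: float,
    n_trios: int,
    config: MultiLocusConfig,
    rng: np.random.Generator,
) -> SimulatedSample:
    """Draw one sample across correlated loci sharing the linked label.

    Per locus, mating types come from that locus's chained frequency row;
    linked children are generated at ``t* = R1/(R1+1)`` and unlinked
    children at 1/2.  Loci are conditionally independent given the label
    and the mating types.
    """
    mt = correlated_mating_freqs(
        model.p, config.n_loci, config.rho, rng, shared_x=config.shared_x
    )
    t_star = implied_transmission(model)
    z = rng.random(n_trios) < pi1
    n1 = int(z.sum())
    codes = np.empty((n_trios, config.n_loci), dtype=np.int8)
    g_link = kernel_g(t_star)
    g_null = kernel_g(0.5)
    for locus in range(config.n_loci):
        mu_cells = mating_freqs_of_trios(mt[locus])
        codes[z, locus] = rng.choice(10, size=n1, p=mu_cells * g_link)
        codes[~z, locus] = rng.choice(10, size=n_trios - n1, p=mu_cells * g_null)
    return SimulatedSample(codes=codes, z=z, mating_freqs=mt)


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------


def _simulate_counts(model, pi1, n_trios, rng) -> np.ndarray:
    """Fast counts-only draw of one single-locus replicate."""
    p_link, p_unlink, _ = _single_locus_cell_probs(model, pi1)
    n1 = rng.binomial(n_trios, pi1)
    return rng.multinomial(n1, p_link) + rng.multinomial(n_trios - n1, p_unlink)


def _simulate_counts_multilocus(model, pi1, n_trios, config, rng) -> np.ndarray:
    """Counts-only draw of one multi-locus replicate: (L, 10) matrix."""
    mt = correlated_mating_freqs(
        model.p, config.n_loci, config.rho, rng, shared_x=config.shared_x
    )
    t_star = implied_transmission(model)
    g_link = kernel_g(t_star)
    g_null = kernel_g(0.5)
    n1 = rng.binomial(n_trios, pi1)
    out = np.empty((config.n_loci, 10), dtype=np.int64)
    for locus in range(config.n_loci):
        mu_cells = mating_freqs_of_trios(mt[locus])
        out[locus] = rng.multinomial(n1, mu_cells * g_link) + rng.multinomial(
            n_trios - n1, mu_cells * g_null
        )
    return out


def _replicate_rngs(seed, n_replicates):
    root = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in root.spawn(n_replicates)]


def _batched_pvalues(design: SimulationDesign) -> pd.DataFrame:
    """Per-replicate permutation p-values for both statistics.

    Simulates all replicates, then evaluates the heterogeneity LRT on the
    observed and permuted count vectors in large vectorized EM batches.
    Returns one row per replicate with columns ``p_tdt_het`` and ``p_tdt``
    (for multi-locus designs, the SumStat p-values).
    """
    n_loci = design.multilocus.n_loci if design.multilocus else 1
    b = design.n_perms
    s = design.em.n_starts
    rows_per_rep = n_loci * (b + 1)
    chunk_reps = max(1, _MAX_CHAINS // (rows_per_rep * s))
    rngs = _replicate_rngs(design.seed, design.n_replicates)

    p_het = np.empty(design.n_replicates)
    p_tdt = np.empty(design.n_replicates)
    for lo in range(0, design.n_replicates, chunk_reps):
        hi = min(lo + chunk_reps, design.n_replicates)
        blocks, inits_t, inits_pi = [], [], []
        for r in range(lo, hi):
            rng = rngs[r]
            if design.multilocus:
                obs = _simulate_counts_multilocus(
                    design.model, design.pi1, design.n_trios, design.multilocus, rng
                )
            else:
                obs = _simulate_counts(design.model, design.pi1, design.n_trios, rng)[None, :]
            for locus in range(n_loci):
                block = np.vstack(
                    [obs[locus][None, :], permute_counts_batch(TrioCounts(obs[locus]), b, rng)]
                )
                blocks.append(block)
            inits_t.append(rng.uniform(size=rows_per_rep * s))
            inits_pi.append(rng.uniform(size=rows_per_rep * s))
        matrix = np.vstack(blocks)
        init = (np.concatenate(inits_t), np.concatenate(inits_pi))
        res = _fit_h1_batch(matrix, design.em, init=init)
        het = np.maximum(2.0 * (res["ll_mix"] - _ll_mix_h0(matrix)), 0.0)
        tdt = tdt_statistics(matrix)
        for name, stat, target in (("het", het, p_het), ("tdt", tdt, p_tdt)):
            arr = stat.reshape(hi - lo, n_loci, b + 1).sum(axis=1)
            target[lo:hi] = np.mean(arr[:, 1:] >= arr[:, :1], axis=1)
    return pd.DataFrame({"p_tdt_het": p_het, "p_tdt": p_tdt})


def rejection_rates(design: SimulationDesign) -> pd.DataFrame:
    """Empirical rejection proportions with exact binomial 95% CIs.

    One row per (statistic, alpha).  For multi-locus designs the
    statistics are the per-replicate sums across loci.
    """
    pvals = _batched_pvalues(design)
    suffix = "_sumstat" if design.multilocus else ""
    rows = []
    for stat, col in (("tdt_het", "p_tdt_het"), ("tdt", "p_tdt")):
        for alpha in design.alphas:
            k = int(np.sum(pvals[col] <= alpha))
            ci = binomtest(k, design.n_replicates).proportion_ci(
                confidence_level=0.95, method="exact"
            )
            rows.append(
                {
                    "statistic": stat + suffix,
                    "alpha": alpha,
                    "rejections": k,
                    "replicates": design.n_replicates,
                    "power": k / design.n_replicates,
                    "ci_low": ci.low,
                    "ci_high": ci.high,
                }
            )
    return pd.DataFrame(rows)


def run_experiment(design: SimulationDesign) -> pd.DataFrame:
    """Run the full replicate study for one design.

    Returns the rejection-rate table annotated with the design setting.
    """
    table = rejection_rates(design)
    table.insert(0, "moi", design.model.moi)
    table.insert(1, "phi", design.model.phi)
    table.insert(2, "p", design.model.p)
    table.insert(3, "r2", design.model.r2)
    table.insert(4, "pi1", design.pi1)
    return table
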